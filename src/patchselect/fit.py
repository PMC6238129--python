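"""Likelihood, maximum-likelihood estimation and profile confidence intervals.

Egg counts are modelled per replicate (one fly) as a multinomial draw over
the design's substrates with cell probabilities given by the two-scale
forward model.  With two resource types this is the natural generalisation of
a binomial likelihood to the eight-substrate layout.  The multinomial
coefficient is constant in the parameters and omitted throughout, so
log-likelihood values are comparable only within a dataset.

Because replicates are iid multinomials sharing one probability vector per
treatment, pooling counts across replicates leaves the likelihood (up to the
omitted constant) unchanged; internally all computation runs on counts pooled
per (treatment, patch, resource) cell, which also makes grid evaluation cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .model import (
    DomainError,
    ExperimentDesign,
    PatchSelectError,
    SelectionParams,
)

__all__ = [
    "DataValidationError",
    "NoDataError",
    "FitError",
    "EggCountDataset",
    "FitResult",
    "log_likelihood",
    "fit_mle",
    "profile_ci",
    "brute_force_grid",
]

logger = logging.getLogger(__name__)

#: Column order of the long-format egg-count table.
COLUMNS = ("replicate_id", "strain", "treatment", "patch_id", "substrate_id", "resource", "eggs")

PARAM_NAMES = ("s_wa", "s_pa")

# Probability floor used inside logs by the optimizer only; the public
# log-likelihood keeps the exact -inf sentinel for zero-probability events.
_CLAMP = 1e-12
# Logit-scale box for the unconstrained search; expit(16) ~ 1 - 1e-7.
_LOGIT_BOUND = 16.0
_BOUNDARY_TOL = 1e-4
_FLAT_TOL = 1e-6


class DataValidationError(PatchSelectError, ValueError):
    """An egg-count table violates the long-format contract or its designs."""


class NoDataError(PatchSelectError, ValueError):
    """No replicate carries any eggs, so the likelihood is uninformative."""


class FitError(PatchSelectError, RuntimeError):
    """The optimizer failed from every starting value."""


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------


@dataclass
class EggCountDataset:
    """Long-format egg counts: one row per replicate x substrate.

    Wraps a :class:`pandas.DataFrame` with columns ``replicate_id, strain,
    treatment, patch_id, substrate_id, resource, eggs``.  Construction checks
    the schema; :meth:`validate_against` checks consistency with a design
    registry.  Replicates whose total egg count is zero are kept (they are
    real observations) but flagged, and excluded from likelihoods only at fit
    time.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.frame.columns]
        if missing:
            raise DataValidationError(f"missing required columns: {missing}")
        df = self.frame.loc[:, list(COLUMNS)].copy()
        eggs = df["eggs"]
        bad = df.index[
            ~np.isfinite(pd.to_numeric(eggs, errors="coerce"))
            | (pd.to_numeric(eggs, errors="coerce") % 1 != 0)
            | (pd.to_numeric(eggs, errors="coerce") < 0)
        ]
        if len(bad):
            raise DataValidationError(
                f"eggs must be non-negative integers; offending rows (0-based): "
                f"{list(bad[:10])}"
            )
        df["eggs"] = eggs.astype(np.int64)
        for c in COLUMNS[:-1]:
            df[c] = df[c].astype(str)
        dupes = df.duplicated(subset=["replicate_id", "substrate_id"])
        if dupes.any():
            raise DataValidationError(
                f"duplicate (replicate_id, substrate_id) rows: "
                f"{list(df.index[dupes][:10])}"
            )
        self.frame = df

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def strains(self) -> list[str]:
        return sorted(self.frame["strain"].unique())

    @property
    def treatments(self) -> list[str]:
        return sorted(self.frame["treatment"].unique())

    @property
    def n_replicates(self) -> int:
        return self.frame["replicate_id"].nunique()

    @property
    def n_eggs(self) -> int:
        return int(self.frame["eggs"].sum())

    def for_strain(self, strain: str) -> "EggCountDataset":
        sub = self.frame[self.frame["strain"] == str(strain)]
        if sub.empty:
            raise DataValidationError(f"no rows for strain {strain!r}")
        return EggCountDataset(sub.reset_index(drop=True))

    def zero_total_replicates(self) -> list[str]:
        """Replicate ids whose eggs sum to zero (uninformative for fitting)."""
        totals = self.frame.groupby("replicate_id")["eggs"].sum()
        return sorted(totals.index[totals == 0])

    def validate_against(self, designs: Mapping[str, ExperimentDesign]) -> None:
        """Check every row resolves against the named design registry."""
        problems: list[str] = []
        for t, sub in self.frame.groupby("treatment"):
            if t not in designs:
                problems.append(f"unknown treatment {t!r}")
                continue
            design = designs[t]
            lookup = {s.substrate_id: s for s in design.substrates}
            for idx, row in sub.iterrows():
                s = lookup.get(row["substrate_id"])
                if s is None:
                    problems.append(
                        f"row {idx}: substrate {row['substrate_id']!r} not in "
                        f"design {t!r}"
                    )
                elif s.patch_id != row["patch_id"] or s.resource != row["resource"]:
                    problems.append(
                        f"row {idx}: substrate {row['substrate_id']!r} metadata "
                        f"disagrees with design {t!r}"
                    )
        if problems:
            raise DataValidationError("; ".join(problems[:20]))


# ---------------------------------------------------------------------------
# Compiled likelihood kernel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _TreatmentCounts:
    """Pooled egg counts for one treatment, aligned to its design's patches."""

    label: str
    n_a: np.ndarray  # A-substrate count per patch
    n_b: np.ndarray
    e_a: np.ndarray  # pooled eggs on A-substrates per patch
    e_b: np.ndarray


def _compile(
    data: EggCountDataset, designs: Mapping[str, ExperimentDesign]
) -> list[_TreatmentCounts]:
    data.validate_against(designs)
    out = []
    for t, sub in data.frame.groupby("treatment"):
        design = designs[t]
        pooled = sub.groupby(["patch_id", "resource"])["eggs"].sum()
        n_a, n_b, e_a, e_b = [], [], [], []
        for p in design.patches:
            n_a.append(p.n_a)
            n_b.append(p.n_b)
            e_a.append(pooled.get((p.patch_id, "A"), 0))
            e_b.append(pooled.get((p.patch_id, "B"), 0))
        out.append(
            _TreatmentCounts(
                t,
                np.asarray(n_a, float),
                np.asarray(n_b, float),
                np.asarray(e_a, float),
                np.asarray(e_b, float),
            )
        )
    return out


def _loglik_kernel(
    s_wa: np.ndarray,
    s_pa: np.ndarray,
    compiled: Sequence[_TreatmentCounts],
    clamp: float | None = None,
) -> np.ndarray:
    """Vectorised pooled log-likelihood on broadcastable parameter arrays.

    With ``clamp`` set, per-substrate probabilities are floored before the
    log (optimizer mode); without it, zero-probability cells with eggs yield
    exactly ``-inf``.
    """
    s_wa = np.asarray(s_wa, float)
    s_pa = np.asarray(s_pa, float)
    total = np.zeros(np.broadcast_shapes(s_wa.shape, s_pa.shape))
    sw = s_wa[..., None]
    sp = s_pa[..., None]
    for tc in compiled:
        with np.errstate(divide="ignore", invalid="ignore"):
            num_w = sw * tc.n_a
            den_w = num_w + (1.0 - sw) * tc.n_b
            w = np.where(
                tc.n_b == 0,
                1.0,
                np.where(tc.n_a == 0, 0.0, num_w / np.where(den_w > 0, den_w, 1.0)),
            )
            num_p = sp * tc.n_a + (1.0 - sp) * tc.n_b
            den_p = num_p.sum(axis=-1, keepdims=True)
            p = num_p / np.where(den_p > 0, den_p, 1.0)
            t_a = w * p
            t_b = (1.0 - w) * p
            na_safe = np.where(tc.n_a > 0, tc.n_a, 1.0)
            nb_safe = np.where(tc.n_b > 0, tc.n_b, 1.0)
            if clamp is not None:
                lp_a = np.log(np.maximum(t_a / na_safe, clamp))
                lp_b = np.log(np.maximum(t_b / nb_safe, clamp))
            else:
                lp_a = np.log(t_a / na_safe)
                lp_b = np.log(t_b / nb_safe)
            contrib = np.where(tc.e_a > 0, tc.e_a * lp_a, 0.0) + np.where(
                tc.e_b > 0, tc.e_b * lp_b, 0.0
            )
            # a design with zero total weight at this s_pa cannot produce data
            contrib = np.where(den_p[..., 0] > 0, contrib.sum(axis=-1), -np.inf)
        total = total + contrib
    return total


def log_likelihood(
    params: SelectionParams,
    data: EggCountDataset,
    designs: Mapping[str, ExperimentDesign],
) -> float:
    """Multinomial log-likelihood of the egg counts (constant omitted).

    Returns exactly ``-inf`` when any substrate holding eggs has probability
    zero under ``params`` (e.g. eggs on a B-substrate with ``s_wa = 1``).
    """
    compiled = _compile(data, designs)
    return float(_loglik_kernel(np.float64(params.s_wa), np.float64(params.s_pa), compiled))


# ---------------------------------------------------------------------------
# Maximum likelihood
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit of the two selection coefficients."""

    estimate: SelectionParams
    log_likelihood: float
    ci_wa: tuple[float, float]
    ci_pa: tuple[float, float]
    level: float
    n_replicates_used: int
    n_eggs: int
    boundary_flags: dict[str, bool]
    identifiability_flags: dict[str, bool]
    starts_tried: int
    converged: bool
    seed: int | None = None
    strain: str | None = None

    def to_dict(self) -> dict:
        return {
            "estimate": {"s_wa": self.estimate.s_wa, "s_pa": self.estimate.s_pa},
            "log_likelihood": self.log_likelihood,
            "ci": {"s_wa": list(self.ci_wa), "s_pa": list(self.ci_pa)},
            "level": self.level,
            "n_replicates_used": self.n_replicates_used,
            "n_eggs": self.n_eggs,
            "boundary_flags": dict(self.boundary_flags),
            "identifiability_flags": dict(self.identifiability_flags),
            "starts_tried": self.starts_tried,
            "converged": self.converged,
            "seed": self.seed,
            "strain": self.strain,
        }


def _informative_subset(data: EggCountDataset) -> tuple[EggCountDataset, int]:
    """Drop zero-total replicates (no likelihood information); count the rest."""
    empty = data.zero_total_replicates()
    if empty:
        logger.warning(
            "excluding %d zero-egg replicate(s) from the fit: %s",
            len(empty),
            empty[:5],
        )
        keep = ~data.frame["replicate_id"].isin(empty)
        data = EggCountDataset(data.frame[keep].reset_index(drop=True))
    if data.frame.empty or data.n_eggs == 0:
        raise NoDataError("no replicate carries any eggs; nothing to fit")
    return data, data.n_replicates


def _flat_directions(compiled: Sequence[_TreatmentCounts], at: SelectionParams) -> dict[str, bool]:
    """Detect parameters along which the likelihood is numerically flat.

    Each parameter is scanned on a 21-point grid with the other held at the
    fitted value; a likelihood range below 1e-6 marks it unidentifiable
    (e.g. s_pa when every patch has the same composition).
    """
    grid = np.linspace(0.0, 1.0, 21)
    lw = _loglik_kernel(grid, np.full_like(grid, at.s_pa), compiled, clamp=_CLAMP)
    lp = _loglik_kernel(np.full_like(grid, at.s_wa), grid, compiled, clamp=_CLAMP)
    return {
        "s_wa": bool(np.ptp(lw) < _FLAT_TOL),
        "s_pa": bool(np.ptp(lp) < _FLAT_TOL),
    }


def fit_mle(
    data: EggCountDataset,
    designs: Mapping[str, ExperimentDesign],
    level: float = 0.95,
    starts: int = 5,
    seed: int | None = None,
    strain: str | None = None,
    compute_ci: bool = True,
) -> FitResult:
    """Maximum-likelihood estimate of ``(s_wa, s_pa)`` with profile CIs.

    The search runs unconstrained on the logit scale from a ``starts x
    starts`` uniform grid of starting values and keeps the best optimum (ties
    broken by grid order).  Estimates within numerical reach of 0 or 1 are
    snapped to the boundary and flagged.  Parameters whose likelihood profile
    is flat are flagged unidentifiable and given the full interval [0, 1].

    Parameters
    ----------
    strain
        Fit only this strain's rows.  Datasets holding several strains must
        be subset (fits are always per strain).
    compute_ci
        Skip the profile-interval computation when False (the intervals are
        then the uninformative (0, 1) placeholders, flags still set).
    """
    if strain is not None:
        data = data.for_strain(strain)
    elif len(data.strains) > 1:
        raise DataValidationError(
            f"dataset holds several strains {data.strains}; pass strain= to "
            f"select one (fits are per-strain)"
        )
    data, n_used = _informative_subset(data)
    compiled = _compile(data, designs)

    def nll(z: np.ndarray) -> float:
        return -float(_loglik_kernel(expit(z[0]), expit(z[1]), compiled, clamp=_CLAMP))

    start_vals = logit(np.linspace(0.1, 0.9, starts))
    best = None
    n_tried = 0
    for zw in start_vals:
        for zp in start_vals:
            n_tried += 1
            res = optimize.minimize(
                nll,
                x0=np.array([zw, zp]),
                method="L-BFGS-B",
                bounds=[(-_LOGIT_BOUND, _LOGIT_BOUND)] * 2,
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("optimization failed from every start")

    s_hat = expit(best.x)
    # snap numerically-boundary solutions to the exact boundary when that does
    # not cost likelihood (the clamped objective cannot distinguish them)
    snapped = s_hat.copy()
    for k in range(2):
        if s_hat[k] < _BOUNDARY_TOL:
            snapped[k] = 0.0
        elif s_hat[k] > 1.0 - _BOUNDARY_TOL:
            snapped[k] = 1.0
    ll_raw = float(_loglik_kernel(s_hat[0], s_hat[1], compiled))
    ll_snap = float(_loglik_kernel(snapped[0], snapped[1], compiled))
    if ll_snap >= ll_raw - 1e-9:
        s_hat = snapped
        ll_hat = ll_snap
    else:
        ll_hat = ll_raw
    estimate = SelectionParams(float(s_hat[0]), float(s_hat[1]))

    boundary = {
        name: bool(val <= _BOUNDARY_TOL or val >= 1.0 - _BOUNDARY_TOL)
        for name, val in zip(PARAM_NAMES, s_hat)
    }
    ident = _flat_directions(compiled, estimate)

    result = FitResult(
        estimate=estimate,
        log_likelihood=ll_hat,
        ci_wa=(0.0, 1.0),
        ci_pa=(0.0, 1.0),
        level=level,
        n_replicates_used=n_used,
        n_eggs=data.n_eggs,
        boundary_flags=boundary,
        identifiability_flags=ident,  # True = profile flat, not identifiable
        starts_tried=n_tried,
        converged=True,
        seed=seed,
        strain=strain if strain is not None else (data.strains[0] if data.strains else None),
    )
    if compute_ci:
        result.ci_wa = profile_ci(data, designs, result, "s_wa", level)
        result.ci_pa = profile_ci(data, designs, result, "s_pa", level)
    return result


# ---------------------------------------------------------------------------
# Profile-likelihood confidence intervals
# ---------------------------------------------------------------------------


def _profile_value(
    theta: float,
    parameter: str,
    compiled: Sequence[_TreatmentCounts],
    other_start: float,
) -> float:
    """Max log-likelihood with one coefficient fixed at ``theta``."""

    def neg(other: float) -> float:
        if parameter == "s_wa":
            return -float(_loglik_kernel(theta, other, compiled, clamp=_CLAMP))
        return -float(_loglik_kernel(other, theta, compiled, clamp=_CLAMP))

    res = optimize.minimize_scalar(neg, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": 1e-8})
    # the bounded search can miss a boundary optimum; check the edges and the
    # unconstrained optimum explicitly
    best = min(res.fun, neg(0.0), neg(1.0), neg(float(np.clip(other_start, 0, 1))))
    return -best


def profile_ci(
    data: EggCountDataset,
    designs: Mapping[str, ExperimentDesign],
    fit: FitResult,
    parameter: str,
    level: float | None = None,
) -> tuple[float, float]:
    """Profile-likelihood confidence interval for one selection coefficient.

    The interval is the set of values whose deviance ``2*(logL_max -
    profile_logL)`` does not exceed the chi-square(1) quantile at ``level``;
    interior endpoints are located by root bisection to 1e-6.  Endpoints are
    reported as 0 or 1 when the boundary lies inside the set; a flat profile
    yields the full interval (0, 1).
    """
    if parameter not in PARAM_NAMES:
        raise DomainError(f"unknown parameter {parameter!r}; expected one of {PARAM_NAMES}")
    if level is None:
        level = fit.level
    if fit.identifiability_flags.get(parameter):
        return (0.0, 1.0)
    data, _ = _informative_subset(data)
    compiled = _compile(data, designs)
    cutoff = stats.chi2.ppf(level, df=1)
    hat = getattr(fit.estimate, parameter)
    other = fit.estimate.s_pa if parameter == "s_wa" else fit.estimate.s_wa
    ll_max = float(
        _loglik_kernel(fit.estimate.s_wa, fit.estimate.s_pa, compiled, clamp=_CLAMP)
    )

    def deviance(theta: float) -> float:
        return max(0.0, 2.0 * (ll_max - _profile_value(theta, parameter, compiled, other)))

    def endpoint(edge: float) -> float:
        if deviance(edge) <= cutoff:
            return edge
        lo, hi = (edge, hat) if edge < hat else (hat, edge)
        return float(
            optimize.brentq(lambda t: deviance(t) - cutoff, lo, hi, xtol=1e-6)
        )

    lower = endpoint(0.0)
    upper = endpoint(1.0)
    return (lower, upper)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


def brute_force_grid(
    data: EggCountDataset,
    designs: Mapping[str, ExperimentDesign],
    resolution: int = 101,
) -> tuple[SelectionParams, float]:
    """Exhaustive log-likelihood maximisation on a uniform lattice.

    Evaluates the exact (unclamped) log-likelihood on a ``resolution x
    resolution`` grid over [0, 1]^2 and returns the argmax and its value;
    ties break toward the first lattice point in row-major order.  Intended
    as a slow, transparent cross-check of :func:`fit_mle`.
    """
    if resolution < 2:
        raise DomainError(f"resolution must be at least 2, got {resolution}")
    data, _ = _informative_subset(data)
    compiled = _compile(data, designs)
    grid = np.linspace(0.0, 1.0, resolution)
    ll = _loglik_kernel(grid[:, None], grid[None, :], compiled)
    flat = np.argmax(ll)  # first max in row-major order
    i, j = np.unravel_index(flat, ll.shape)
    return SelectionParams(float(grid[i]), float(grid[j])), float(ll[i, j])
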