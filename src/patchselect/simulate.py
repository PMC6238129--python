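"""Synthetic oviposition experiments: the generative twin of the fitted model.

Each simulated replicate is one fly released into a two-patch arena.  Its
total egg count is drawn from a negative-binomial (or held fixed), then the
eggs are allocated across the eight substrates by a multinomial whose cell
probabilities come from the two-scale forward model; an optional
Dirichlet-multinomial layer adds fly-to-fly overdispersion in the allocation
while preserving its mean.  One master seed derives an independent stream per
(design, replicate), so any subset of the experiment is reproducible on its
own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    DomainError,
    ExperimentDesign,
    SelectionParams,
    standard_designs,
    substrate_probabilities,
)
from .fit import EggCountDataset, FitError, fit_mle

__all__ = [
    "EggTotalModel",
    "SimulationConfig",
    "simulate_experiment",
    "recovery_study",
    "standard_designs",
]


@dataclass(frozen=True)
class EggTotalModel:
    """Distribution of a fly's total egg output over the 48-h assay.

    ``negative-binomial`` with mean ``mean`` and dispersion ``dispersion``
    (variance mean + mean^2/dispersion) by default; ``fixed`` gives every
    replicate exactly ``round(mean)`` eggs, handy for exact tests.
    """

    family: str = "negative-binomial"
    mean: float = 30.0
    dispersion: float = 5.0

    def __post_init__(self) -> None:
        if self.family not in ("negative-binomial", "fixed"):
            raise DomainError(f"unknown egg-total family {self.family!r}")
        if self.mean <= 0:
            raise DomainError("egg-total mean must be positive")
        if self.family == "negative-binomial" and self.dispersion <= 0:
            raise DomainError("negative-binomial dispersion must be positive")

    def draw(self, rng: np.random.Generator) -> int:
        if self.family == "fixed":
            return int(round(self.mean))
        p = self.dispersion / (self.dispersion + self.mean)
        return int(rng.negative_binomial(self.dispersion, p))


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to regenerate one synthetic experiment.

    Defaults mirror the assay layout: all seven canonical treatments,
    20 replicates (flies) per treatment, negative-binomial egg totals.
    ``overdispersion`` is a Dirichlet concentration; ``None`` keeps the
    generator an exact twin of the fitted multinomial model.
    """

    true_params: SelectionParams = field(default_factory=lambda: SelectionParams(0.5, 0.5))
    designs: Mapping[str, ExperimentDesign] | None = None
    n_replicates_per_design: int = 20
    egg_total: EggTotalModel = field(default_factory=EggTotalModel)
    overdispersion: float | None = None
    strain: str = "synthetic"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_replicates_per_design < 1:
            raise DomainError("n_replicates_per_design must be at least 1")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise DomainError("overdispersion concentration must be positive")

    def resolved_designs(self) -> Mapping[str, ExperimentDesign]:
        return self.designs if self.designs is not None else standard_designs()

    def to_dict(self) -> dict:
        d = self.resolved_designs()
        return {
            "true_params": {"s_wa": self.true_params.s_wa, "s_pa": self.true_params.s_pa},
            "designs": {k: v.composition() for k, v in d.items()},
            "n_replicates_per_design": self.n_replicates_per_design,
            "egg_total": {
                "family": self.egg_total.family,
                "mean": self.egg_total.mean,
                "dispersion": self.egg_total.dispersion,
            },
            "overdispersion": self.overdispersion,
            "strain": self.strain,
            "seed": self.seed,
        }


def _replicate_rng(seed: int | None, d_idx: int, r_idx: int) -> np.random.Generator:
    # keyed stream: subsets of the experiment regenerate identically
    entropy = 0 if seed is None else int(seed)
    return np.random.default_rng(np.random.SeedSequence(entropy, spawn_key=(d_idx, r_idx)))


def simulate_experiment(config: SimulationConfig) -> EggCountDataset:
    """Generate one full synthetic experiment as a long-format dataset.

    For every design and replicate: draw the fly's egg total, then allocate
    it over the design's substrates multinomially with probabilities from
    ``substrate_probabilities(true_params, design)`` (Dirichlet-multinomial
    around those probabilities when overdispersion is set).  Byte-identical
    output for identical configs.
    """
    designs = config.resolved_designs()
    rows = []
    for d_idx, (label, design) in enumerate(designs.items()):
        subs = design.substrates
        probs = substrate_probabilities(config.true_params, design).substrate_prob
        p = np.array([probs[s.substrate_id] for s in subs])
        for r_idx in range(config.n_replicates_per_design):
            rng = _replicate_rng(config.seed, d_idx, r_idx)
            total = config.egg_total.draw(rng)
            if config.overdispersion is not None:
                alive = p > 0
                alpha = config.overdispersion * p[alive]
                q = np.zeros_like(p)
                q[alive] = rng.dirichlet(alpha)
            else:
                q = p
            counts = rng.multinomial(total, q)
            rep_id = f"{label}-r{r_idx + 1:02d}"
            for s, e in zip(subs, counts):
                rows.append(
                    (rep_id, config.strain, label, s.patch_id, s.substrate_id, s.resource, int(e))
                )
    frame = pd.DataFrame(
        rows,
        columns=["replicate_id", "strain", "treatment", "patch_id", "substrate_id", "resource", "eggs"],
    )
    return EggCountDataset(frame)


def recovery_study(
    true_params_grid: Sequence[SelectionParams],
    n_experiments: int,
    seed: int | None = None,
    base_config: SimulationConfig | None = None,
    level: float = 0.95,
    compute_ci: bool = True,
) -> pd.DataFrame:
    """Simulate-and-refit study: bias, RMSE and CI coverage per true value.

    Runs ``n_experiments`` independent simulate -> fit cycles at each point
    of ``true_params_grid`` and aggregates per parameter.  Fit failures are
    recorded (``n_failed``) and never abort the study.

    Returns a table with one row per (true point, parameter): the true value,
    median and mean estimate, bias, RMSE, empirical coverage of the
    ``level`` profile intervals (NaN when ``compute_ci`` is False) and the
    experiment counts.
    """
    if n_experiments < 2:
        raise DomainError("n_experiments must be at least 2")
    base = base_config if base_config is not None else SimulationConfig()
    records = []
    for g_idx, truth in enumerate(true_params_grid):
        estimates: dict[str, list[float]] = {"s_wa": [], "s_pa": []}
        covered: dict[str, list[bool]] = {"s_wa": [], "s_pa": []}
        n_failed = 0
        for e_idx in range(n_experiments):
            ss = np.random.SeedSequence(
                0 if seed is None else int(seed), spawn_key=(g_idx, e_idx)
            )
            exp_seed = int(ss.generate_state(1)[0] % (2**31))
            config = replace(base, true_params=truth, seed=exp_seed)
            try:
                data = simulate_experiment(config)
                fit = fit_mle(
                    data,
                    config.resolved_designs(),
                    level=level,
                    seed=exp_seed,
                    compute_ci=compute_ci,
                )
            except FitError:
                n_failed += 1
                continue
            estimates["s_wa"].append(fit.estimate.s_wa)
            estimates["s_pa"].append(fit.estimate.s_pa)
            if compute_ci:
                covered["s_wa"].append(fit.ci_wa[0] <= truth.s_wa <= fit.ci_wa[1])
                covered["s_pa"].append(fit.ci_pa[0] <= truth.s_pa <= fit.ci_pa[1])
        for name, true_val in (("s_wa", truth.s_wa), ("s_pa", truth.s_pa)):
            est = np.asarray(estimates[name])
            records.append(
                {
                    "parameter": name,
                    "true_value": true_val,
                    "median_estimate": float(np.median(est)) if est.size else np.nan,
                    "mean_estimate": float(est.mean()) if est.size else np.nan,
                    "bias": float(est.mean() - true_val) if est.size else np.nan,
                    "rmse": float(np.sqrt(np.mean((est - true_val) ** 2))) if est.size else np.nan,
                    "coverage": float(np.mean(covered[name])) if covered[name] else np.nan,
                    "n_experiments": int(est.size),
                    "n_failed": n_failed,
                }
            )
    return pd.DataFrame.from_records(records)
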