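"""Frequency-dependent attack rates and associational-effect classification.

A resource experiences *associational susceptibility* when its per-substrate
attack (egg-laying) rate rises as the alternative resource becomes more
frequent in the arena, and *associational resistance* when that rate falls.
The statistic here is the least-squares slope of ``log(mean eggs per
substrate + 0.5)`` against the proportion of the alternative resource across
treatments, with a replicate-level bootstrap (stratified by treatment) giving
a percentile interval; the sign of an interval excluding zero decides the
classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .model import DesignError, DomainError, ExperimentDesign, RESOURCES
from .fit import EggCountDataset

__all__ = ["EffectResult", "per_substrate_rates", "associational_effect"]

#: Offset inside the log that guards zero means.
LOG_OFFSET = 0.5


class InsufficientDesignError(DesignError):
    """Fewer than two distinct frequency levels hold the focal resource."""


@dataclass(frozen=True)
class EffectResult:
    """Slope, bootstrap interval and classification for one resource."""

    resource: str
    slope: float
    ci: tuple[float, float]
    classification: str  # susceptibility | resistance | none
    n_boot: int
    seed: int | None
    n_treatments: int

    def to_dict(self) -> dict:
        return {
            "resource": self.resource,
            "slope": self.slope,
            "ci": list(self.ci),
            "classification": self.classification,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n_treatments": self.n_treatments,
        }


def per_substrate_rates(
    data: EggCountDataset, designs: Mapping[str, ExperimentDesign]
) -> pd.DataFrame:
    """Mean eggs per substrate, by treatment and resource type.

    The mean divides the total eggs laid on substrates of a resource by
    (number of such substrates x number of replicates); a resource absent
    from a treatment contributes no row.
    """
    data.validate_against(designs)
    records = []
    for t, sub in data.frame.groupby("treatment"):
        design = designs[t]
        n_reps = sub["replicate_id"].nunique()
        totals = sub.groupby("resource")["eggs"].sum()
        counts = {"A": sum(p.n_a for p in design.patches), "B": sum(p.n_b for p in design.patches)}
        for resource in RESOURCES:
            if counts[resource] == 0:
                continue
            records.append(
                {
                    "treatment": t,
                    "resource": resource,
                    "mean_eggs_per_substrate": float(totals.get(resource, 0))
                    / (counts[resource] * n_reps),
                    "n_replicates": n_reps,
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["treatment", "resource", "mean_eggs_per_substrate", "n_replicates"]
    )


def _ols_slope(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares slope of y on x; y may carry leading bootstrap axes."""
    xc = x - x.mean()
    return (y * xc).sum(axis=-1) / (xc**2).sum()


def associational_effect(
    data: EggCountDataset,
    designs: Mapping[str, ExperimentDesign],
    resource: str,
    n_boot: int = 999,
    seed: int | None = None,
    level: float = 0.95,
) -> EffectResult:
    """Classify the associational effect experienced by one resource.

    For every treatment containing the focal resource, the per-substrate mean
    egg count is regressed (after the ``log(x + 0.5)`` transform) on the
    proportion of the *alternative* resource in that treatment's layout.
    Replicates are resampled with replacement within treatment ``n_boot``
    times; the percentile interval of the bootstrap slopes at ``level``
    decides: entirely positive -> susceptibility, entirely negative ->
    resistance, otherwise none.
    """
    if resource not in RESOURCES:
        raise DomainError(f"resource must be one of {RESOURCES}, got {resource!r}")
    if n_boot < 100:
        raise DomainError("n_boot must be at least 100")
    data.validate_against(designs)

    x_vals: list[float] = []
    rep_totals: list[np.ndarray] = []  # per treatment: focal eggs per replicate
    denominators: list[float] = []  # n_focal_substrates * n_replicates
    for t, sub in data.frame.groupby("treatment"):
        design = designs[t]
        n_focal = sum(p.count(resource) for p in design.patches)
        if n_focal == 0:
            continue
        total_subs = design.n_substrates
        x_vals.append((total_subs - n_focal) / total_subs)
        focal = sub[sub["resource"] == resource]
        per_rep = focal.groupby("replicate_id")["eggs"].sum().to_numpy(float)
        rep_totals.append(per_rep)
        denominators.append(float(n_focal))
    if len(set(x_vals)) < 2:
        raise InsufficientDesignError(
            f"resource {resource!r} occurs at fewer than two distinct "
            f"alternative-resource frequencies; no slope is estimable"
        )

    x = np.asarray(x_vals)
    means = np.array([tot.sum() / (d * len(tot)) for tot, d in zip(rep_totals, denominators)])
    slope = float(_ols_slope(x, np.log(means + LOG_OFFSET)))

    rng = np.random.default_rng(seed)
    boot_means = np.empty((n_boot, len(x)))
    for k, (tot, d) in enumerate(zip(rep_totals, denominators)):
        idx = rng.integers(0, len(tot), size=(n_boot, len(tot)))
        boot_means[:, k] = tot[idx].mean(axis=1) / d
    boot_slopes = _ols_slope(x, np.log(boot_means + LOG_OFFSET))
    alpha = 1.0 - level
    lo, hi = np.quantile(boot_slopes, [alpha / 2, 1.0 - alpha / 2])

    if lo > 0:
        classification = "susceptibility"
    elif hi < 0:
        classification = "resistance"
    else:
        classification = "none"
    return EffectResult(
        resource=resource,
        slope=slope,
        ci=(float(lo), float(hi)),
        classification=classification,
        n_boot=n_boot,
        seed=seed,
        n_treatments=len(x_vals),
    )
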