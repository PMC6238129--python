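"""Deterministic two-scale resource-selection forward model.

The model extends Manly-type selectivity to two nested spatial scales.  An
assay arena holds ``n`` patches, each a cluster of discrete oviposition
substrates of one of two resource types, ``A`` (apple) and ``B`` (banana).
Two coefficients in the closed unit interval govern use:

* ``s_wa`` — within-patch selection for resource A.  Given a patch holding
  ``n_a`` A-substrates and ``n_b`` B-substrates, the relative use of A inside
  that patch is ``W_a = s_wa*n_a / (s_wa*n_a + (1 - s_wa)*n_b)``.
* ``s_pa`` — between-patch selection for resource A.  Patch ``j`` with
  composition ``(N_aj, N_bj)`` is used with probability proportional to
  ``s_pa*N_aj + (1 - s_pa)*N_bj``.

Selection at the two scales is assumed independent, so the probability mass
on resource A in patch j is ``T_aj = W_a(j) * P_j``; that mass is divided
equally among the patch's A-substrates (the unique exchangeable choice, since
same-type substrates within a patch are indistinguishable to the model).

``s = 0.5`` at either scale means no preference at that scale; above 0.5 is a
preference for A, below 0.5 a preference for B.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "RESOURCES",
    "PatchSelectError",
    "DomainError",
    "DesignError",
    "Substrate",
    "Patch",
    "ExperimentDesign",
    "SelectionParams",
    "UseDistribution",
    "within_patch_use",
    "patch_use",
    "substrate_probabilities",
    "make_design",
    "standard_designs",
]

#: The two resource types handled by the model (A = apple, B = banana).
RESOURCES: tuple[str, str] = ("A", "B")


class PatchSelectError(Exception):
    """Base class for all errors raised by this package."""


class DomainError(PatchSelectError, ValueError):
    """A parameter lies outside its mathematical domain."""


class DesignError(PatchSelectError, ValueError):
    """An experiment design is structurally invalid or degenerate."""


def _check_resource(resource: str) -> str:
    if resource not in RESOURCES:
        raise DomainError(f"resource must be one of {RESOURCES}, got {resource!r}")
    return resource


def _check_unit(value: float, name: str) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0 or np.isnan(value):
        raise DomainError(f"{name} must lie in [0, 1], got {value}")
    return value


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Substrate:
    """A discrete oviposition substrate on which eggs are counted."""

    substrate_id: str
    patch_id: str
    resource: str

    def __post_init__(self) -> None:
        _check_resource(self.resource)


@dataclass(frozen=True)
class Patch:
    """A spatial cluster of substrates; the unit of between-patch choice."""

    patch_id: str
    substrates: tuple[Substrate, ...]

    def __post_init__(self) -> None:
        if len(self.substrates) < 1:
            raise DesignError(f"patch {self.patch_id!r} has no substrates")
        for s in self.substrates:
            if s.patch_id != self.patch_id:
                raise DesignError(
                    f"substrate {s.substrate_id!r} claims patch {s.patch_id!r} "
                    f"but sits in patch {self.patch_id!r}"
                )

    def count(self, resource: str) -> int:
        """Number of substrates of the given resource type in this patch."""
        _check_resource(resource)
        return sum(1 for s in self.substrates if s.resource == resource)

    @property
    def n_a(self) -> int:
        return self.count("A")

    @property
    def n_b(self) -> int:
        return self.count("B")


@dataclass(frozen=True)
class ExperimentDesign:
    """The patch/substrate layout of one treatment.

    ``distribution_kind`` distinguishes the canonical layouts: ``even`` (both
    patches identical), ``uneven`` (one resource concentrated in a single
    patch) and ``split`` (opposite 3:1 ratios in the two patches).  Patch and
    substrate ordering is preserved for reporting but carries no meaning.
    """

    treatment_label: str
    patches: tuple[Patch, ...]
    distribution_kind: str = "even"

    def __post_init__(self) -> None:
        if len(self.patches) < 1:
            raise DesignError(f"design {self.treatment_label!r} has no patches")
        if self.distribution_kind not in ("even", "uneven", "split"):
            raise DesignError(
                f"distribution_kind must be even/uneven/split, "
                f"got {self.distribution_kind!r}"
            )
        ids = [s.substrate_id for s in self.substrates]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DesignError(
                f"design {self.treatment_label!r} has duplicate substrate ids: {dupes}"
            )
        pids = [p.patch_id for p in self.patches]
        if len(pids) != len(set(pids)):
            raise DesignError(f"design {self.treatment_label!r} has duplicate patch ids")

    @property
    def substrates(self) -> tuple[Substrate, ...]:
        return tuple(s for p in self.patches for s in p.substrates)

    @property
    def n_substrates(self) -> int:
        return len(self.substrates)

    @property
    def frequency_ratio(self) -> tuple[int, int]:
        """Total count of A-substrates : B-substrates over the whole design."""
        return (
            sum(p.n_a for p in self.patches),
            sum(p.n_b for p in self.patches),
        )

    def composition(self) -> list[tuple[int, int]]:
        """Per-patch (n_a, n_b) counts, in patch order."""
        return [(p.n_a, p.n_b) for p in self.patches]


@dataclass(frozen=True)
class SelectionParams:
    """The pair of selection coefficients, one per spatial scale.

    The complements ``s_wb = 1 - s_wa`` and ``s_pb = 1 - s_pa`` describe
    selection for resource B and are derived, never stored.
    """

    s_wa: float
    s_pa: float

    def __post_init__(self) -> None:
        _check_unit(self.s_wa, "s_wa")
        _check_unit(self.s_pa, "s_pa")

    @property
    def s_wb(self) -> float:
        return 1.0 - self.s_wa

    @property
    def s_pb(self) -> float:
        return 1.0 - self.s_pa

    def swapped(self) -> "SelectionParams":
        """Parameters under the A<->B relabeling."""
        return SelectionParams(1.0 - self.s_wa, 1.0 - self.s_pa)


@dataclass(frozen=True)
class UseDistribution:
    """Per-patch, per-resource and per-substrate use probabilities.

    ``patch_use`` maps patch_id -> P_j; ``within_use`` maps patch_id ->
    {resource -> W}; ``substrate_prob`` maps substrate_id -> probability.
    Both ``patch_use`` and ``substrate_prob`` sum to one.
    """

    patch_use: Mapping[str, float]
    within_use: Mapping[str, Mapping[str, float]]
    substrate_prob: Mapping[str, float]


# ---------------------------------------------------------------------------
# Forward-model operations
# ---------------------------------------------------------------------------


def within_patch_use(s_wa: float, n_a: int, n_b: int) -> float:
    """Relative use W_a of resource A inside one patch.

    Parameters
    ----------
    s_wa
        Within-patch selection coefficient for A, in [0, 1].
    n_a, n_b
        Counts of A- and B-substrates in the patch.

    Returns
    -------
    float
        ``W_a = s_wa*n_a / (s_wa*n_a + (1 - s_wa)*n_b)``.  A patch holding
        only one resource type yields 1 (all A) or 0 (all B) regardless of
        ``s_wa``.  ``W_b`` is ``1 - W_a``.
    """
    s_wa = _check_unit(s_wa, "s_wa")
    n_a, n_b = int(n_a), int(n_b)
    if n_a < 0 or n_b < 0:
        raise DomainError("substrate counts must be non-negative")
    if n_a + n_b == 0:
        raise DesignError("empty patch: n_a + n_b must be at least 1")
    if n_b == 0:
        return 1.0
    if n_a == 0:
        return 0.0
    num = s_wa * n_a
    return num / (num + (1.0 - s_wa) * n_b)


def patch_use(s_pa: float, design: ExperimentDesign) -> np.ndarray:
    """Relative use P_j of each patch in the design, in patch order.

    ``P_j`` is proportional to ``s_pa*N_aj + (1 - s_pa)*N_bj`` and the vector
    sums to one.  A degenerate weighting (all patch weights zero, e.g.
    ``s_pa = 1`` on a design with no A-substrates) raises ``DesignError``.
    """
    s_pa = _check_unit(s_pa, "s_pa")
    n_a = np.array([p.n_a for p in design.patches], dtype=float)
    n_b = np.array([p.n_b for p in design.patches], dtype=float)
    num = s_pa * n_a + (1.0 - s_pa) * n_b
    den = num.sum()
    if den <= 0.0:
        raise DesignError(
            f"degenerate design {design.treatment_label!r}: every patch has "
            f"zero weight at s_pa={s_pa}"
        )
    return num / den


def substrate_probabilities(
    params: SelectionParams, design: ExperimentDesign
) -> UseDistribution:
    """Full forward model: per-substrate use probabilities for one design.

    The mass on resource i in patch j is ``T_ij = W_i(j) * P_j``; it is split
    equally among patch j's substrates of type i.  All substrate
    probabilities sum to one.
    """
    p_vec = patch_use(params.s_pa, design)
    pu: dict[str, float] = {}
    wu: dict[str, dict[str, float]] = {}
    sp: dict[str, float] = {}
    for patch, p_j in zip(design.patches, p_vec):
        w_a = within_patch_use(params.s_wa, patch.n_a, patch.n_b)
        pu[patch.patch_id] = float(p_j)
        wu[patch.patch_id] = {"A": w_a, "B": 1.0 - w_a}
        mass = {"A": w_a * p_j, "B": (1.0 - w_a) * p_j}
        count = {"A": patch.n_a, "B": patch.n_b}
        for s in patch.substrates:
            sp[s.substrate_id] = float(mass[s.resource] / count[s.resource])
    return UseDistribution(patch_use=pu, within_use=wu, substrate_prob=sp)


# ---------------------------------------------------------------------------
# Design construction and the canonical layouts
# ---------------------------------------------------------------------------


def make_design(
    treatment_label: str,
    patch_compositions: Iterable[tuple[int, int]],
    distribution_kind: str = "even",
) -> ExperimentDesign:
    """Build a design from per-patch (n_a, n_b) substrate counts.

    Patch ids are ``p1, p2, ...``; substrate ids ``p1-s1 .. p1-s4`` etc., with
    A-substrates listed first within each patch.  Ordering is cosmetic.
    """
    patches = []
    for j, (n_a, n_b) in enumerate(patch_compositions, start=1):
        if n_a < 0 or n_b < 0 or n_a + n_b < 1:
            raise DesignError(f"patch {j} of {treatment_label!r}: invalid composition")
        pid = f"p{j}"
        subs = tuple(
            Substrate(f"{pid}-s{k}", pid, "A" if k <= n_a else "B")
            for k in range(1, n_a + n_b + 1)
        )
        patches.append(Patch(pid, subs))
    return ExperimentDesign(treatment_label, tuple(patches), distribution_kind)


# Canonical two-patch, eight-substrate layouts used in the oviposition assay:
# apple:banana frequencies 6:2, 4:4 and 2:6, each with the resources spread
# evenly over the two patches or with the majority resource concentrated in
# one patch ("uneven"; for 4:4 this puts each resource pure in its own patch,
# hence "uniform"), plus a 4:4 layout with opposite 3:1 / 1:3 mixes ("split").
_CANONICAL: list[tuple[str, list[tuple[int, int]], str]] = [
    ("6:2-even", [(3, 1), (3, 1)], "even"),
    ("6:2-uneven", [(4, 0), (2, 2)], "uneven"),
    ("4:4-even", [(2, 2), (2, 2)], "even"),
    ("4:4-uniform", [(4, 0), (0, 4)], "uneven"),
    ("4:4-split", [(3, 1), (1, 3)], "split"),
    ("2:6-even", [(1, 3), (1, 3)], "even"),
    ("2:6-uneven", [(2, 2), (0, 4)], "uneven"),
]


def standard_designs() -> dict[str, ExperimentDesign]:
    """The seven built-in treatment layouts, keyed by treatment label.

    Every design has 2 patches of 4 substrates each (8 substrates total).
    """
    return {
        label: make_design(label, comps, kind) for label, comps, kind in _CANONICAL
    }
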