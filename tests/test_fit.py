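"""Likelihood values, MLE behaviour, profile intervals, and the grid oracle."""

import math

import numpy as np
import pytest
from scipy import stats

from patchselect import (
    DataValidationError,
    EggCountDataset,
    NoDataError,
    SelectionParams,
    SimulationConfig,
    brute_force_grid,
    fit_mle,
    log_likelihood,
    profile_ci,
    simulate_experiment,
)

NEUTRAL = SelectionParams(0.5, 0.5)


# -- log-likelihood ----------------------------------------------------------


def test_loglik_uniform_cell_hand_value(make_dataset, designs):
    """Ten eggs on one of eight equiprobable substrates: 10*ln(1/8)."""
    data = make_dataset({"4:4-even": {"r1": {"p1-s1": 10}}})
    ll = log_likelihood(NEUTRAL, data, designs)
    assert ll == pytest.approx(10 * math.log(1 / 8), abs=1e-3)
    assert ll == pytest.approx(-20.794, abs=1e-3)


def test_loglik_zero_probability_event_is_minus_inf(make_dataset, designs):
    """Eggs on a B-substrate are impossible under total A preference."""
    data = make_dataset({"4:4-even": {"r1": {"p1-s3": 1}}})  # p1-s3 is B
    assert log_likelihood(SelectionParams(1.0, 0.4), data, designs) == -np.inf


def test_loglik_additive_over_replicates(make_dataset, designs):
    """Pooling counts across replicates leaves the log-likelihood unchanged."""
    split = make_dataset(
        {"6:2-uneven": {"r1": {"p1-s1": 3, "p2-s3": 2}, "r2": {"p1-s1": 1, "p2-s4": 4}}}
    )
    pooled = make_dataset(
        {"6:2-uneven": {"r1": {"p1-s1": 4, "p2-s3": 2, "p2-s4": 4}}}
    )
    p = SelectionParams(0.7, 0.6)
    assert log_likelihood(p, split, designs) == pytest.approx(
        log_likelihood(p, pooled, designs)
    )


def test_loglik_rejects_foreign_substrates(designs, make_dataset):
    data = make_dataset({"4:4-even": {"r1": {"p1-s1": 2}}})
    bad = data.frame.copy()
    bad.loc[0, "substrate_id"] = "p9-s9"
    with pytest.raises(DataValidationError):
        log_likelihood(NEUTRAL, EggCountDataset(bad), designs)


# -- maximum likelihood ------------------------------------------------------


def test_mle_matches_grid_oracle(preference_data, designs):
    """The optimizer's solution beats the exhaustive-grid argmax."""
    fit = fit_mle(preference_data, designs, compute_ci=False)
    grid_params, grid_ll = brute_force_grid(preference_data, designs, 101)
    assert fit.log_likelihood >= grid_ll - 1e-9
    assert abs(fit.estimate.s_wa - grid_params.s_wa) <= 0.01
    assert abs(fit.estimate.s_pa - grid_params.s_pa) <= 0.01


@pytest.mark.parametrize("seed", range(6))
def test_mle_oracle_equivalence_random_instances(designs, seed):
    """fit_mle lands within one lattice cell of the grid argmax."""
    rng = np.random.default_rng(seed)
    truth = SelectionParams(rng.uniform(0.15, 0.85), rng.uniform(0.15, 0.85))
    data = simulate_experiment(
        SimulationConfig(true_params=truth, n_replicates_per_design=5, seed=seed)
    )
    fit = fit_mle(data, designs, compute_ci=False)
    grid_params, grid_ll = brute_force_grid(data, designs, 101)
    assert fit.log_likelihood >= grid_ll - 1e-9
    assert abs(fit.estimate.s_wa - grid_params.s_wa) <= 0.01 + 1e-9
    assert abs(fit.estimate.s_pa - grid_params.s_pa) <= 0.01 + 1e-9


def test_mle_recovers_truth_at_moderate_size(preference_data, designs):
    """140 replicates of ~30 eggs pin both coefficients to within 0.05."""
    fit = fit_mle(preference_data, designs, compute_ci=False)
    assert fit.estimate.s_wa == pytest.approx(0.9, abs=0.05)
    assert fit.estimate.s_pa == pytest.approx(0.8, abs=0.05)
    assert fit.n_replicates_used == 140
    assert fit.starts_tried == 25


def test_mle_boundary_when_all_eggs_on_A(preference_data, designs):
    df = preference_data.frame.copy()
    df.loc[df["resource"] == "B", "eggs"] = 0
    fit = fit_mle(EggCountDataset(df), designs, compute_ci=False)
    assert fit.estimate.s_wa == 1.0
    assert fit.boundary_flags["s_wa"]


def test_mle_flags_unidentifiable_s_pa_on_symmetric_design(preference_data, designs):
    """4:4-even alone cannot inform between-patch selection."""
    sub = preference_data.frame[preference_data.frame["treatment"] == "4:4-even"]
    fit = fit_mle(EggCountDataset(sub.reset_index(drop=True)), designs)
    assert fit.identifiability_flags["s_pa"]
    assert not fit.identifiability_flags["s_wa"]
    assert fit.ci_pa == (0.0, 1.0)


def test_mle_requires_eggs(make_dataset, designs):
    empty = make_dataset({"4:4-even": {"r1": {}}})
    with pytest.raises(NoDataError):
        fit_mle(empty, designs)


def test_mle_rejects_mixed_strains_without_selector(neutral_data, designs):
    import pandas as pd

    other = neutral_data.frame.copy()
    other["strain"] = "other"
    other["replicate_id"] = other["replicate_id"] + "-o"
    mixed = EggCountDataset(pd.concat([neutral_data.frame, other], ignore_index=True))
    with pytest.raises(DataValidationError):
        fit_mle(mixed, designs)
    fit = fit_mle(mixed, designs, strain="other", compute_ci=False)
    assert fit.strain == "other"


def test_label_swap_equivariance(preference_data, designs):
    """Relabeling every substrate A<->B complements both estimates."""
    from patchselect import ExperimentDesign, Patch, Substrate

    flip = {"A": "B", "B": "A"}
    mirror = {
        name: ExperimentDesign(
            name,
            tuple(
                Patch(
                    p.patch_id,
                    tuple(
                        Substrate(s.substrate_id, s.patch_id, flip[s.resource])
                        for s in p.substrates
                    ),
                )
                for p in d.patches
            ),
            d.distribution_kind,
        )
        for name, d in designs.items()
    }
    swapped = preference_data.frame.copy()
    swapped["resource"] = swapped["resource"].map(flip)
    fit = fit_mle(preference_data, designs, compute_ci=False)
    fit_sw = fit_mle(EggCountDataset(swapped), mirror, compute_ci=False)
    assert fit_sw.estimate.s_wa == pytest.approx(1 - fit.estimate.s_wa, abs=1e-3)
    assert fit_sw.estimate.s_pa == pytest.approx(1 - fit.estimate.s_pa, abs=1e-3)


def test_consistency_rmse_shrinks_with_replicates(designs):
    """Estimator error decreases as the replicate count doubles."""
    truth = SelectionParams(0.8, 0.7)
    rmses = []
    for n_rep in (5, 20):
        errs = []
        for e in range(12):
            data = simulate_experiment(
                SimulationConfig(
                    true_params=truth, n_replicates_per_design=n_rep, seed=1000 + e
                )
            )
            fit = fit_mle(data, designs, compute_ci=False)
            errs.append(
                (fit.estimate.s_wa - truth.s_wa) ** 2
                + (fit.estimate.s_pa - truth.s_pa) ** 2
            )
        rmses.append(np.sqrt(np.mean(errs)))
    assert rmses[1] < rmses[0]


# -- profile confidence intervals -------------------------------------------


def test_profile_ci_contains_mle_and_truth(preference_data, designs):
    fit = fit_mle(preference_data, designs)
    lo, hi = fit.ci_wa
    assert lo <= fit.estimate.s_wa <= hi
    assert lo <= 0.9 <= hi or abs(fit.estimate.s_wa - 0.9) > 0.03  # truth usually inside
    assert hi - lo < 0.1  # 140 replicates pin the coefficient tightly


def test_profile_ci_endpoint_deviance_matches_chi2(preference_data, designs):
    """Interior interval endpoints sit exactly at the chi2(1) cutoff."""
    from patchselect.fit import _compile, _informative_subset, _loglik_kernel

    fit = fit_mle(preference_data, designs, compute_ci=False)
    lo, hi = profile_ci(preference_data, designs, fit, "s_wa", 0.95)
    data, _ = _informative_subset(preference_data)
    compiled = _compile(data, designs)

    def profile_ll(theta):
        grid = np.linspace(0, 1, 2001)
        return float(np.max(_loglik_kernel(np.float64(theta), grid, compiled, clamp=1e-12)))

    ll_max = float(
        _loglik_kernel(fit.estimate.s_wa, fit.estimate.s_pa, compiled, clamp=1e-12)
    )
    cutoff = stats.chi2.ppf(0.95, 1)
    for endpoint in (lo, hi):
        assert 0.0 < endpoint < 1.0
        dev = 2 * (ll_max - profile_ll(endpoint))
        assert dev == pytest.approx(cutoff, abs=1e-3)
    assert cutoff == pytest.approx(3.841, abs=1e-3)


def test_profile_ci_flat_profile_full_interval(preference_data, designs):
    sub = preference_data.frame[preference_data.frame["treatment"] == "4:4-even"]
    data = EggCountDataset(sub.reset_index(drop=True))
    fit = fit_mle(data, designs, compute_ci=False)
    assert profile_ci(data, designs, fit, "s_pa", 0.95) == (0.0, 1.0)


def test_profile_ci_widens_with_level(preference_data, designs):
    fit = fit_mle(preference_data, designs, compute_ci=False)
    lo90, hi90 = profile_ci(preference_data, designs, fit, "s_wa", 0.90)
    lo99, hi99 = profile_ci(preference_data, designs, fit, "s_wa", 0.99)
    assert lo99 < lo90 and hi99 > hi90


# -- brute-force oracle ------------------------------------------------------


def test_brute_force_corner_resolution(make_dataset, designs):
    """Resolution 2 evaluates exactly the four corners of the unit square."""
    data = make_dataset({"6:2-uneven": {"r1": {"p1-s1": 5, "p2-s3": 5}}})
    params, value = brute_force_grid(data, designs, 2)
    assert (params.s_wa, params.s_pa) in {(a, b) for a in (0.0, 1.0) for b in (0.0, 1.0)}
    corner_lls = [
        log_likelihood(SelectionParams(a, b), data, designs)
        for a in (0.0, 1.0)
        for b in (0.0, 1.0)
    ]
    assert value == max(corner_lls)


def test_brute_force_neutral_data_near_center(neutral_data, designs):
    params, _ = brute_force_grid(neutral_data, designs, 51)
    assert params.s_wa == pytest.approx(0.5, abs=0.06)
    assert params.s_pa == pytest.approx(0.5, abs=0.06)
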