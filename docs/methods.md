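# Methods

## The two-scale selection model

A two-patch arena holds eight oviposition substrates of two resource types,
A and B. Selection is modelled hierarchically with one coefficient per
scale, both Manly-type selectivities in the closed unit interval:

* `s_wa` — within-patch selection for A. In a patch with composition
  `(N_aj, N_bj)` the relative use of A is
  `W_a = s_wa·N_aj / (s_wa·N_aj + (1−s_wa)·N_bj)`; `W_b = 1 − W_a`.
* `s_pa` — between-patch selection for A. Patch j is used with probability
  `P_j ∝ s_pa·N_aj + (1−s_pa)·N_bj`, normalised over patches.

The scales are assumed independent, so the probability mass on resource i
in patch j is `T_ij = W_i(j)·P_j`. The model is written per resource type;
egg counts are observed per substrate, so `T_ij` is divided equally among
patch j's substrates of type i. Equal division is the unique exchangeable
choice — the model contains nothing that distinguishes same-type substrates
within a patch — and it makes the per-substrate likelihood depend on the
data only through the pooled (patch × resource) totals.

Two deliberate modelling choices:

* **One shared `s_pa`.** A patch-indexed between-patch coefficient would
  add one free parameter per patch and be unidentifiable from a single
  arena (any patch-use vector could be matched exactly). The package
  estimates one between-patch coefficient per strain; the patch index
  enters only through the compositions `N_ij`.
* **Multinomial likelihood.** Each replicate (fly) is a multinomial draw
  over the arena's substrates with probabilities from the forward model.
  With two resource types this is the natural multi-substrate form of a
  binomial likelihood. The multinomial coefficient is constant in the
  parameters and omitted, so log-likelihood values are comparable only
  within one dataset. Because replicates are iid with a shared probability
  vector per treatment, pooling counts across replicates leaves the
  likelihood unchanged up to that constant; the implementation exploits
  this (all kernels run on pooled counts), and a test asserts the
  invariance.

Boundary values 0 and 1 are legal parameters. Degenerate 0/0 cases (an
empty patch; a weighting under which every patch has zero weight) raise
errors rather than returning NaN. A patch containing only one resource
type has `W` fixed at 0/1 regardless of `s_wa` — which is why total
within-patch preference for A (`s_wa = 1`) alone does not empty the
B-substrates of a pure-B patch; only `s_pa = 1` shuts such a patch off.

## Estimation

The log-likelihood is maximised over `[0,1]²` on the logit scale
(L-BFGS-B, logits box-bounded to ±16) from a 5×5 uniform grid of starting
values (0.1 … 0.9 per axis); the best optimum wins, ties broken by grid
order. Inside the optimizer, per-substrate probabilities are floored at
1e-12 before the log for numerical stability; the public log-likelihood
keeps the exact `−inf` sentinel for zero-probability events. Estimates
within 1e-4 of a boundary are snapped to it when that costs no likelihood,
and flagged.

**Identifiability.** Some layouts carry no information about a coefficient
(with identical patch compositions, `P_j` is constant in `s_pa`). After
fitting, each coefficient is scanned on a 21-point grid with the other held
at its estimate; a likelihood range under 1e-6 flags the coefficient
unidentifiable and its interval is reported as the full `[0, 1]`.

**Profile intervals.** The interval at level `1−α` is
`{θ : 2(logL_max − profile logL(θ)) ≤ χ²₁(1−α)}` (3.841 at 95%). The
profile maximises over the other coefficient by bounded 1-D optimisation
(with explicit checks of both edges); interior endpoints are located by
bisection to 1e-6. Endpoints land at 0 or 1 when the boundary lies inside
the set. A test verifies the deviance at interior endpoints equals the χ²
cutoff to 1e-3.

**Oracle.** `brute_force_grid` evaluates the exact log-likelihood on a
uniform lattice and returns the argmax — a slow, transparent cross-check.
The optimizer is required (and tested, on 20 random instances) to land
within one cell of the 101×101 grid argmax and never below its likelihood.

## The synthetic-experiment generator

The simulator emulates the assay's statistical structure: 7 treatment
layouts (6:2, 4:4, 2:6 in even and uneven between-patch distributions, the
4:4 "uniform" layout putting each resource pure in its own patch, and the
4:4 "split" layout with opposite 3:1/1:3 mixes), 20 replicates (flies) per
treatment, 2 patches × 4 substrates. Per replicate it draws a total egg
count and allocates it over the substrates by a multinomial with the
forward-model probabilities.

* **Egg totals**: negative-binomial, mean 30 and dispersion 5 by default.
  The assay literature does not report per-fly totals; a negative binomial
  is the standard overdispersed count model for such data (matching the
  error family used in companion GLMM analyses), and mean 30 gives
  realistic per-substrate counts (≈4 eggs/substrate under neutrality).
  A fixed-total option exists for exact tests. Replicates that draw zero
  eggs are kept in datasets, flagged, and excluded from likelihoods (they
  carry no information).
* **Overdispersion**: optionally the allocation is Dirichlet-multinomial
  with a single concentration parameter around the model probabilities —
  mean-preserving, variance-inflating. Default off, so the generator is the
  exact twin of the fitted model. The fitter never models overdispersion;
  the option exists to probe robustness.
* **Seeding**: one master seed; each (design, replicate) gets its own
  `SeedSequence(master, spawn_key=(design, replicate))` stream, so any
  subset of an experiment regenerates identically.

What the generator does **not** emulate: spatial geometry and distances,
the 48-h time course, fly movement or state, sensory mechanism, and any
between-fly heterogeneity in preference (all flies share one parameter
pair). Passing recovery tests therefore show the estimator is correct for
the model's own data-generating process — not that real assays satisfy the
multinomial independence assumptions.

## Associational-effects statistic

Associational susceptibility/resistance is operationalised as a defined,
repository-owned statistic rather than a mixed-model interaction test: for
a focal resource, the least-squares slope of `log(mean eggs per substrate
+ 0.5)` on the proportion of the alternative resource across treatments.
The +0.5 offset guards zero means. Uncertainty comes from a bootstrap that
resamples replicates within treatment (999 resamples, 95% percentile
interval, by default); an interval entirely above zero classifies
susceptibility, entirely below zero resistance, otherwise none. Both even
and uneven layouts at the same overall frequency enter as separate points
at the same abscissa. The statistic is a deliberately simple proxy for the
frequency-dependence a GLMM interaction would test; its magnitudes are not
comparable to mixed-model coefficients.

## Simulation studies and problem sizes

The package's quantitative guarantees are computed by its own simulation
studies, at sizes chosen to keep Monte-Carlo error well below the asserted
tolerances while remaining desk-scale:

* neutral recovery: 200 experiments at (0.5, 0.5); each coefficient's
  median estimate asserted within 0.50 ± 0.02;
* interval calibration: 200 experiments at (0.9, 0.8); empirical coverage
  of the 95% profile intervals asserted in [0.92, 0.98] (binomial SE at
  200 draws ≈ 1.5 points);
* classifier validation: 200 experiments split between a strong-preference
  scenario (0.95, 0.95 → susceptibility for A, resistance for B) and the
  neutral scenario (→ none for both), asserting ≥ 90% correct
  resource-level classifications;
* oracle agreement: 20 random instances at 3–9 replicates per treatment.

`scripts/acceptance.py` re-runs the first two studies end to end from a
single command-line seed and writes the resulting numbers as JSON.

## Known limitations

* Exactly two resource types; the within-patch formula is written for the
  two-type case.
* No per-patch selection coefficients and no spatial covariates.
* No overdispersion in the likelihood: with strongly overdispersed real
  data the profile intervals will undercover.
* Per-strain fits only; no joint hierarchical model across strains.
* Log-likelihood values include no multinomial constant and are not
  comparable across datasets.
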