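# Methods

This note documents the models, conventions and design choices behind
`mirbw`, in the order the pipeline applies them, plus what the synthetic
generator does and does not emulate.

## Spectral containers and preprocessing

The canonical wavenumber grid spans 925.66–3995.78 cm⁻¹ with 797 uniformly
spaced points (step (3995.78 − 925.66)/796 ≈ 3.8569 cm⁻¹), the window shared
by the common milk MIR instruments; indices 6, 7 and 27 fall at 948.80,
952.66 and 1029.80 cm⁻¹, wavenumbers repeatedly implicated in
milk-composition work. Any other uniform grid may be supplied, which the
tests use to run at reduced cost.

**First derivative.** The gap derivative is a forward difference,
d_i = x_{i+gap} − x_i with gap = 5 by default, left-anchored: the output
keeps the first n − gap wavenumbers. The convention (forward vs centered,
anchor side) is a package choice; it is the simplest rule consistent with a
"gap" difference and is isolated in one function so an alternative can be
swapped in.

**Region subsetting.** The expert ("HSO") windows [950, 1600],
[1750, 1800] and [2600, 3000] cm⁻¹ are treated as closed intervals, matching
their bracket notation; on the canonical grid they retain 284 points. After
subsetting the retained points are no longer uniformly spaced, so the
dataset keeps feature identity in column names rather than a grid object.

**Scaling.** Centering and unit-variance scaling use the sample standard
deviation (n − 1). Transforms are frozen objects fitted on training data
only; inside every cross-validation loop the scale is refit on the training
side of the fold so no validation information leaks into the predictors.

## Cleaning

Order is fixed: BW range filter → GH filter → iterative residual analysis;
each record can be removed at most once and the report keeps per-stage ids.

* **BW ranges** per parity class (1, 2, 3, 4+) default to (376, 705),
  (449, 767), (487, 838), (492, 875) kg — mean ± sd magnitudes for Holstein
  test-day data — read as closed intervals, since boundary records are
  measurement-plausible. The constants are configuration, not re-derived.
* **GH distance.** Spectra are mean-centered, a covariance-scaled PCA
  retains the smallest k components reaching 99% cumulative variance, and
  GH_i = (1/k) Σ_a t_ia²/λ_a, the squared standardized score distance
  averaged over retained components — the common chemometric "global H".
  Records with GH > 3 are dropped. Covariance (not correlation) scaling is
  used because the spectra are already derivative-transformed and share
  units.
* **Residual analysis.** A PLS model of BW on all predictors (component
  count capped at 10, the same cap as validation, to avoid a second free
  parameter) is refit repeatedly; records with |r_i − mean(r)| > 3·sd(r)
  (centered on the mean residual, not on zero) are removed until an
  iteration removes nothing. Termination is guaranteed by strictly
  decreasing size.

## PLS engine

PLS1 by NIPALS with X-deflation: w_a ∝ X'y (unit norm), t_a = X w_a,
p_a = X't_a/(t_a·t_a), q_a = y't_a/(t_a·t_a), then rank-one deflation. The
coefficient path B_A = W_A (P_A'W_A)⁻¹ q_A is materialized for every
A = 1..A_max, so one fit serves all component counts in cross-validation.
Extraction stops early, with a warning, when the deflated covariance norm
falls below 1e-8 of its initial value (rank deficiency). Invariants held by
construction and enforced in tests: unit-norm weights, mutually orthogonal
scores, training RMSE non-increasing in A, and equality with the ordinary
least-squares solution at full rank.

**VIP** uses SSY_a = q_a²(t_a·t_a) as the per-component explained-y sum of
squares: VIP_j = √(p·Σ_a SSY_a (w_ja/‖w_a‖)²/Σ_a SSY_a), which satisfies
Σ_j VIP_j² = p identically. **BETA** is the absolute standardized
coefficient |b_j|; the absolute value is deliberate — a signed ranking would
call strong negative effects irrelevant. Ties in either ranking break by
ascending feature index for reproducibility.

## Filter screen (SBF)

Each candidate predictor (spectral point, parity class, DIM, MY) is tested
univariately: BW = β₀ + s(X) + ε with s a cubic B-spline with three interior
knots at quantiles of X, compared to the intercept-only model by a classical
F-test; keep X when p < 0.05. The basis is unpenalized with fixed dimension
rather than a penalized smooth with data-driven roughness: with an
unpenalized basis the F statistic has its exact null distribution, so the
screen's type-I behaviour is calibrated (the suite verifies ~5% retention on
pure-noise predictors), whereas penalized variants admit only approximate
tests. A constant predictor has no representable relationship; its p-value
is undefined and it is excluded with a warning. No multiplicity correction
is applied — the screen is intentionally tolerant, a coarse pre-selection
before the wrapper.

## Wrapper selection (RFE)

The subset-size schedule starts at the full feature count N_f and descends
by 5 while the size exceeds 255, by 2 while in 201–255, and by 1 at or below
200, stopping before any size under 2. This reconstruction is pinned by the
printed subset counts it must reproduce: 251 subsets from 379 features, 231
from 280, 158 from 159, and 2 × (251 + 231 + 158) = 1280 across the six
families.

At each size: keep the top features of the current ranking, choose the PLS
component count by stratified 10-fold CV over 1..min(10, p, n−1) (the
validation cap reused; the argmin of mean CV RMSE, ties to fewer
components), record mean ± sd of per-fold RMSE, refit on all records, and
re-rank within the subset. Fold assignments are fixed once per RFE run so
subset comparisons share the same partition. Parity enters as a single
ordinal feature (class code 1–4): with one parity feature the ALL set of the
full protocol counts 797 spectral points + parity + DIM + MY = 800.

**Tolerance retention.** For each integer tolerance t in 0..12, the selected
model is the smallest subset whose CV RMSE is ≤ (1 + t/100) × the family's
minimum (ties to the lower RMSE) — 13 per family, kept per tolerance without
deduplication, so downstream bookkeeping (78 subsets, 78 × 101 = 7,878
herd-independent fits at protocol scale) is exact.

## Validation designs

**Strata** are the quartile intervals of BW — (min, Q1], (Q1, median],
(median, Q3], (Q3, max] — with linear-interpolation (type 7) quantiles, the
default of mainstream statistical software. Stratified folds deal shuffled
records round-robin within each stratum, so per-stratum fold counts differ
by at most one.

**Herd-independent partitions** enumerate every herd subset whose record
share lies in the closed 10–30% range and sample the requested number of
repeats uniformly — without replacement when enough feasible subsets exist,
with replacement (warned) otherwise. Whether repeated partitions should be
distinct is genuinely open; distinctness is preferred when available. The
optimal component count is the argmin over A of the mean validation RMSE
across repeats (ties to smaller A — parsimony); the finalist per family
minimizes mean herd-independent RMSE with ties broken by its sd, the CV
mean, then feature count.

**External validation** refits each finalist on the full training set with
its frozen scale and scores an untouched external dataset; finalists'
external predictions are also compared pairwise by Pearson correlation,
which on synthetic data exceeds 0.9 — different retained wavenumber sets
carry the same latent information because adjacent spectral points are
strongly correlated.

## Synthetic generator

The generator emulates the *statistical* structure the pipeline assumes; it
makes no attempt at FTIR physics, instrument standardization or fatty-acid
chemistry. Zones are abstract signal carriers. Defaults (all configurable):

* 9 herds, 10–45 cows each, 2–8 records per cow; parity sampled from
  (0.32, 0.25, 0.18, 0.12, 0.08, 0.05) over parities 1–6 and pooled to
  1..4+ downstream; DIM uniform on 5–305 d.
* Milk yield: Wood curve a·DIM^b·e^(−c·DIM) with a = 16, b = 0.22,
  c = 0.004, parity scale (0.85, 1.0, 1.08, 1.10), noise sd 2.5 kg/d —
  peak ≈ 31 kg/d near DIM 60, herd means in the 20–40 kg/d range typical of
  Holstein recording data.
* Bodyweight: parity-class baselines (560, 615, 650, 670) kg + herd effect
  (sd 12 kg) + cow effect (sd 20 kg) − 25·e^(−DIM/45) (post-calving dip
  recovery) + 0.10 kg/d gain + 35 kg × a latent spectral variable u ~ N(0,1)
  + residual (sd 12 kg). Herd means land in the 550–680 kg band and the
  overall spread ≈ 65 kg. The **noise floor** √(herd² + cow² + resid²) ≈
  26.2 kg is recorded in the truth object: it is the RMSE no predictor-based
  model can beat, since herd and cow effects and the residual are carried by
  no feature.
* Spectra: ~40 fixed Gaussian peaks (σ = 25 cm⁻¹) with per-record amplitude
  jitter, plus informative-zone peaks whose amplitudes are linear in a mix
  of u (weight 0.8 by default) and standardized MY/DIM, scaled so the
  signal-to-noise ratio (default 5) counts in units of the per-point noise
  sd; plus smooth noise (white noise convolved with a Gaussian kernel of 5
  grid steps — the source of the >0.9 adjacent-point correlation) and a
  little white noise. MY/DIM standardization uses config-implied moments,
  not sample moments, so random streams stay partitioned per entity: adding
  herds leaves existing herds bit-identical.
* Outlier injection: spectral outliers add a broad aberrant peak scaled in
  units of the observed per-point spectral sd (magnitude 10 reliably trips
  the GH filter); BW outliers are pushed above their parity-class upper
  bound by at least `magnitude` residual sd.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: instrument-to-instrument standardization error,
heteroscedastic or seasonally drifting spectra, non-Gaussian BW errors,
cross-herd differences in lactation shape, and genetic covariance between
cows. Results on synthetic data demonstrate that the machinery is correct
and that the selection recovers embedded signal, not that any particular
kg-level accuracy transfers to field data.

## Problem sizes used in tests

The full protocol (797 spectral points, ~1,900 records, 101 repeats) is
exercised exactly where its outputs are combinatorial (schedule counts,
13/78/7,878 bookkeeping, cleaning and reduction arithmetic). Statistical
properties run on reduced instances chosen as the package's own test
conditions: a 175-point grid over the fingerprint region, 9 herds with ~480
records, 25 herd-independent repeats for the executed end-to-end run, 10
seeds for feature-recovery averaging, 3 seeds for noise-floor tracking.

## Known limitations

* PLS is linear in DIM and MY, so the exponential early-lactation term is
  only approximated; the residual nonlinearity is small at the default dip
  size but contributes to finalists sitting slightly above the noise floor.
* The GH filter assumes one dominant spectral population; mixtures of
  instrument types would need standardization upstream (out of scope).
* The SBF screen tests the whole smooth model against the null rather than
  the smooth term within a penalized fit; both are defensible readings of a
  "nonparametric F-test", and the chosen one is exactly calibrated.
* `herd_partitions` enumerates subsets and is exponential in herd count; it
  is intended for the tens-of-herds regime of calibration datasets.
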