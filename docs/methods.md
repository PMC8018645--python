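# Methods

This note records the statistical models implemented in `metaplast`, the
conventions chosen where several were defensible, and what the synthetic
panels do and do not emulate.

## Data model

A panel is a long table of replicated measurements keyed by (variety,
location, year, block, compound). The analysis unit downstream is the
combined environment label `location-year`; no ordering or geographic
semantics are attached to it. Block means give one variety × environment
matrix per compound. Missing cells are represented (NaN) and excluded
pairwise from CV and amplitude computations; the stability models
(joint regression, ecovalence, AMMI) require complete matrices and raise
otherwise — imputation is out of scope. All standard deviations use the
sample (n−1) denominator. Per-compound scaling is to mean 0, sd 1; CV is
always computed on raw block means (a CV of centred data is meaningless).

## Variance partitioning

Bray–Curtis, d(i,j) = Σ|x_i−x_j| / Σ(x_i+x_j), is defined for
non-negative profiles, which conflicts with centre-and-scale
preprocessing. The package makes the reconciliation explicit via
`shift_policy`: `minshift` (default) shifts each compound column so its
minimum is 0 after scaling, `range01` min-max rescales, `raise` demands
non-negative input. The choice changes the distances, so it is a named
argument rather than a hidden default.

PERMANOVA partitions the Gower-centred inner-product matrix
G = −½·J·D²·J with sequential (Type I) projections onto nested design
subspaces, in the order the factors are given (environment, then variety,
then their interaction in the pipeline). In balanced designs the order is
immaterial. Degrees of freedom come from projector ranks, so unbalanced
designs are handled; saturated designs (no residual df) raise. Pseudo-F
per term is (SS/df)/(SS_res/df_res); p-values use unrestricted permutation
of sample rows with the +1 correction, p = (1+#{F*≥F})/(1+n_perm),
n_perm defaulting to 9999. Restricted/strata permutation and >2-factor
designs are not implemented. Permutations are applied to G by batched
index gathering, which keeps 1000-simulation calibration runs cheap; the
type-I error is verified to sit in the 95% binomial band around α.

## PCA and the triangle-area metric

PCA is an SVD of the column-centred (pre-scaled) matrix — correlation
PCA — with a deterministic sign convention (largest-|loading| coordinate
positive per component) so results are reproducible across runs. In a
three-environment design each variety has three PC1–3 score points and
the area ½‖(L−A)×(S−A)‖ of that triangle measures its multivariate
environmental responsiveness; the metric is undefined for other designs
and the code enforces that. Areas are rotation-invariant, sign-flip
invariant, and scale quadratically — all asserted as properties.
The weighted variant multiplies axis k by the component's inertia
fraction divided by the mean fraction of the three axes, which preserves
the magnitude of the unweighted area while tilting it toward the more
informative axes; raw-fraction weighting is selectable
(`weighting="raw"`). The normalized form is the package default because
pure fractions (~0.1) would shrink areas by orders of magnitude and make
the two columns incomparable.

## Discriminant-compound screen

The screen is pipeline glue over scikit-learn's random forest, not a
re-implementation: Gini importances with permutation p-values obtained by
refitting on label-permuted data (defaults 500 trees, 2000 permutations),
selection at p < 0.05 intersected with an importance floor. The floor is
interpreted on the raw impurity-decrease scale (per-tree decrease ×
n_samples, averaged over trees), since normalized importances summing to
1 would make an absolute floor meaningless. The raw scale approximates,
but is not numerically identical to, other implementations' "mean
decrease in Gini"; the floor default (1.0) is therefore a convention and
the screen's tests exercise ranking and calibration, not the floor.

## Amplitude screen

Amplitudes are computed on per-compound z-scaled variety × environment
means (z over all cells of the matrix), because ranges of compounds
measured in incommensurable units (g/100 g vs ppb) can only be summed per
variety after a common scaling; `scale_mode="raw"` is retained for
single-family analyses. Only compounds accumulated by all varieties
enter (every cell > `presence_threshold`, default 0 as a detection-limit
convention). Expected amplitudes are the contingency-style margin product
E = Sci·Srj/St and residuals the χ²-style (A−E)/√E; the fully
standardized form with (1−row share)(1−column share) denominators is
available via `standardized=True` since the shorter name is ambiguous in
the literature. The screen statistic is Σ_v|r| per compound with a
*strict* median cutoff — the median compound itself is not selected —
which matches how a median threshold behaves on an odd-sized compound set.

## Stability models

The joint regression regresses each variety's means on the environmental
index I_e (mean over varieties per environment): b_v = cov(y_v,I)/var(I).
Because the index is the variety mean, slopes average exactly 1 on
complete data; this identity is asserted to 1e-9. Slope standard errors
and residual sd come from the per-variety OLS fit. Ecovalence is the
row-wise sum of squares of the doubly-centred means table; its total
equals the two-way interaction SS exactly, and also Σλ² of the AMMI
decomposition — both identities are tested. AMMI reports *all* singular
values; k (default 2) only governs biplot axes and fitted values. Biplot
scaling is symmetric (both sides × √λ) by default with genotype- and
environment-focused variants, as different stability packages disagree on
the convention. Axis signs are fixed by making the largest-|score|
environment positive. Rankings of environments for a variety use the
fitted cell values at the retained k; at full rank they equal the raw
cell-mean ranking. These models run on raw-scale means because sensitivity
plots are read in content units; nothing prevents passing z-scaled
matrices.

## Synthetic panels

The generator emulates the two trial designs the package targets —
a wide first-year screen (16 varieties × 3 locations × 2 blocks × 86
compounds) and a deep multi-environment trial (5 varieties × 20
environments × 3 blocks) — with the cell model
value = μ_c + g_vc + h_ce + (gh)_vce + block_be + ε, or
μ_c·exp(…) under the lognormal option (kept because real abundances are
non-negative and Bray–Curtis assumes it; gaussian is retained for exact
closed-form tests). Conventions:

- Main effects are drawn centred (sum-to-zero), interactions doubly
  centred, so the two-way decomposition of noise-free means is exact.
- σ_gxe is realized as the *exact* element RMS of the interaction matrix
  (the draw is rescaled), making SNR statements in recovery experiments
  exact; `interaction_rank` K constrains the matrix to rank K.
- Under `fw_slopes`, the interaction is (β_v−1)·h_e, so the generating
  sensitivity slope is exactly β_v; the interaction is doubly centred
  whenever the slopes average 1 across varieties.
- One integer seed drives everything; per-compound substreams are derived
  from the compound name, so adding a compound never perturbs another's
  draws. Block effects are shared across compounds (a field effect).
- The per-compound defaults (μ≈10, σ_g≈σ_e≈1, σ_ε≈0.3–0.5) are
  conventions chosen to give realistic CVs of ~10–30%; no published
  per-compound variance magnitudes exist to estimate them from.

What the generator does *not* emulate: chromatographic measurement-error
structure, limits of detection, compound co-regulation, or temporal
drift. Passing tests therefore demonstrate estimator correctness under
the stated model, not robustness to those real-data features.

## Problem sizes in the validation experiments

The calibration and recovery experiments (in `metaplast.acceptance`) use:
slope recovery over 20 replicate panels of 3 varieties × 20 environments
× 2 blocks, judged as 2-SE coverage (a 2-SE band is a ~95% interval, so a
single draw is an unreliable verdict; coverage over 60 checks is the
statistically meaningful one) plus replicate-mean accuracy; screen power
over 200 panels of 5 varieties × 20 environments with one planted
compound whose interaction RMS is 4× the residual sd; and permutation
calibration over 1000 null datasets of 12 samples × 4 compounds with 999
permutations each. These sizes give stable Monte-Carlo estimates while
keeping each experiment in the seconds range.

## Known limitations

- Two crossed factors only in PERMANOVA; blocks are not a strata level in
  the permutations.
- No EM imputation for incomplete variety × environment tables.
- The amplitude screen's z-scaling assumes the shared-scale convention;
  raw-mode sums across compound families are not meaningful.
- AMMI component counts are not tested for significance; k is a display
  choice.
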