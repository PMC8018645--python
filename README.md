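# metaplast

Phenotypic-plasticity and genotype-by-environment (G×E) analysis of
multi-environment metabolite panels.

Crop metabolomic trials quantify tens of compounds across varieties,
locations, years and field blocks. Breeders then need to know, compound by
compound, how much of the variation is environmental, which varieties are
*statically* stable (low environmental CV) and which are *dynamically*
sensitive (strong G×E), and which environments favour accumulation.
`metaplast` packages that workflow for long-format panels keyed by
(variety, environment = location×year, block, compound):

- **Variance partitioning** — Bray–Curtis dissimilarities and a crossed
  two-factor PERMANOVA with sequential (Type I) sums of squares from the
  Gower-centred matrix *G* = −½·*J·D²·J*, pseudo-*F* per term and
  permutation p-values.
- **Structure** — correlation PCA; a per-variety **triangle-area** metric,
  ½‖(L−A)×(S−A)‖ on the variety's three environment points in PC1–3
  (optionally inertia-weighted); Ward clustering; environmental
  CV% = 100·σ/μ per variety and compound; a random-forest
  discriminant-compound screen with permutation p-values.
- **Plasticity screen** — per-(variety, compound) amplitude
  *A* = max−min over environments (on z-scaled means), contingency-style
  expected amplitudes *E* = S꜀ᵢ·Sᵣⱼ/Sₜ, standardized Pearson residuals
  *r* = (A−E)/√E, and selection of compounds whose Σᵥ|r| exceeds the
  median strictly.
- **Stability models** — Finlay–Wilkinson joint regression on the
  environmental index (slope *bᵢ* = environmental sensitivity), Wricke
  ecovalence *Wᵥ* = Σₑ(y_ve−ȳᵥ.−ȳ.ₑ+ȳ..)², and the AMMI model
  (additive main effects + SVD of the doubly-centred interaction) with
  biplot coordinates and best-environment rankings.
- **Synthetic panels** — a generator with known ground truth (variance
  components, interaction rank, exact sensitivity slopes) used throughout
  the tests to validate every estimator against the effects that produced
  the data.

## Worked example

`examples/05_stability_models.py` simulates one compound for 5 varieties ×
20 environments × 3 blocks with generating sensitivity slopes
(2.0, 1.2, 1.0, 0.8, 0.0) and refits them:

```
joint regression (generating slopes 2.0, 1.2, 1.0, 0.8, 0.0):
         intercept  slope  slope_se  resid_sd
variety
V01        -12.545  1.959     0.019     0.215
V02         -3.913  1.229     0.017     0.193
V03          0.844  0.974     0.018     0.195
V04          0.814  0.832     0.018     0.206
V05         14.799  0.006     0.020     0.227

ecovalence (share of interaction SS per variety):
         ecovalence  share
V01         114.870  0.459
...
V05         123.472  0.493

AMMI singular values: [15.74   1.169  0.894  0.786]
```

The fitted slopes recover the generating ones within ~2 standard errors:
V01 (b≈1.96) amplifies environmental swings, V05 (b≈0.01) barely tracks
them. Both extremes contribute most of the interaction sum of squares
(ecovalence shares 0.46 and 0.49), and the dominant first AMMI singular
value shows the interaction is essentially one-dimensional — exactly the
slope differential that generated it. The other examples cover panel
simulation, the PERMANOVA partition, PCA areas/clustering/CV, and the
amplitude screen; each prints its results with a note on how to read them.

A thin CLI mirrors the library (`metaplast simulate | permanova |
structure | screen | stability | run-all | report`); `run-all` writes every
stage output plus a manifest from which the bundle is re-derivable.

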