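# Methods

## Scoring model and the Index of Pathology

The unit of observation is a skeletal element scored in seven ordinal
categories — exostoses, lipping, bone texture, cavitation, foramen shape,
foramen size, articular surface — each ranked 1 (normal bone) to 4 (severe).
Rows of a specimen table may aggregate several identical elements via a
`count` column; all aggregation is count-weighted. Missing ranks are excluded
per category, never imputed, so per-category sample sizes within a taxon may
differ (the packaged study table shows exactly this pattern).

Per taxon and category, the category index is the count-weighted mean rank
`Σ r·n_r / Σ n_r ∈ [1, 4]`; the overall Index of Pathology (IPa) is the sum
of the seven category means, hence in [7, 28]. The overall index is the sum
of means, not a pooled mean of all scores: with unequal per-category n the
two differ, and only the sum-of-means reading keeps the stated [7, 28] bounds
meaningful. When any category is unscored the profile is flagged *partial*
and no overall value is emitted. Rounding (half-even, via decimal arithmetic)
happens only at the reporting boundary.

An element is *pathologic* for the percent-affected summaries iff any scored
category has rank ≥ 2. This threshold is a package choice (the presence /
absence rule behind such summaries is rarely stated in published tables) and
is exposed as a parameter. Anatomical groupings (forelimb/hindlimb/axial;
girdle/stylopod/zeugopod/autopod) come from a packaged element-name
dictionary; matching strips side/position qualifiers and resolves compound
names by their first recognized element. Unknown names classify as
indeterminate rather than erroring, and indeterminate groups are reported as
their own group. Patella and sesamoids carry developmental class `other`;
metapodials, phalanges, and podials are autopod but functionally
indeterminate unless named metacarpal/metatarsal.

### Fixture caveat

The packaged rank-frequency table is preserved exactly as published,
including rows whose printed per-category index values cannot be reproduced
from their own frequency counts (for example, one taxon's foramen-size row
prints 1.40 where the counts give 1.69). Only *Trigonias osborni* reconciles
fully, so golden tests pin that taxon and treat the other rows as fixture
data, not oracles; per-category golden comparisons use a ±0.015 tolerance
because the printed table mixes rounding conventions (1.8947 prints as 1.90).
The packaged study tree is a reconstruction from published clade
relationships (its Newick string is not printed anywhere); no numeric check
depends on its topology.

## Time-calibration

Ages are Ma before present (larger = older), durations Myr, and input
cladograms must be fully dichotomous (polytomies raise an error rather than
being resolved silently).

* **basic** — each internal node takes the maximum FAD over its descendant
  tips; tips sit at their FAD, or at their LAD when terminal ranges are
  appended (`extend_tips_to_lad`, the default); the root is raised by
  `root_extension_myr` (default 1.0 — any positive value works; the value is
  a free choice). Zero-duration branches are expected output.
* **equal** — starts from the basic solution and removes zero-duration
  branches root-to-tip: each maximal chain of zero-duration branches borrows
  from the nearest ancestral branch of positive duration, dividing that
  donor's duration equally among itself and the chain. Only internal nodes
  move (upward), so tip ages and every root-to-tip path duration are
  conserved by construction. When several zero chains hang below one donor,
  they are processed sequentially in preorder; later chains borrow from the
  now-positive branches the earlier pass created. This tie-break is a
  declared convention of this implementation — published descriptions of
  equal-style redistribution do not pin it down — chosen so results are
  deterministic and reproducible. If a zero chain starts at the root
  (possible only with zero root extension), calibration fails with advice to
  increase the extension.

## Independent contrasts and regression modes

Contrasts follow the standard pruning recursion (see README for the
formulas); they require strictly positive durations and direct the user to
'equal' calibration otherwise. Two contrast-regression modes are exposed:

* `positivized_origin` (default): each contrast pair is sign-flipped so the
  predictor contrast is ≥ 0 and the slope is fit through the origin with
  uncentered R² and df (1, n−1). This is the statistically standard
  treatment; on every tree it equals the generalized-least-squares slope
  under the Brownian tip covariance (V[i,j] = shared root-to-MRCA duration),
  and the test suite checks that equivalence to 1e-10 against a direct
  matrix-solve oracle.
* `absolute_intercept`: ordinary regression with intercept on the absolute
  values of both contrast sets. Absolute-value contrasts appear in some
  comparative work; the mode is first-class so such analyses can be
  reproduced, and reports always record which mode produced them. Note
  negative adjusted R² values arise naturally under this mode.

Body mass enters as log₁₀ kg by default with a raw-mass switch; masses
spanning two orders of magnitude make the log scale the natural default, but
because published analyses do not always state the transform the pipeline
emits its full regression grid under either setting. OLS summaries
(slope, R², adjusted R² = 1−(1−R²)(n−1)/(n−p−1) without clamping, F, and the
F(df1, df2) upper-tail p) are computed via statsmodels/scipy.

## Synthetic assemblage generator

The generator emulates the study design so the full pipeline can be exercised
and validated without external data. Defaults are the study's own scale and
are not tuned per experiment:

| parameter | default | meaning |
|---|---|---|
| `n_taxa` | 7 | taxa (the study's count); ≥ 3 |
| `tree_source` | fixture | packaged tree, or random topology |
| `elements_per_taxon` | 110 | scored elements per taxon (study NISP median; study range ~65–275) |
| `thresholds` | (0, 2, 4) | cumulative-link cutpoints (latent logit scale) |
| `baseline` | 0.5 | latent severity at mean log-mass → mean ranks ~1.5–2.5, the band the real assemblages occupy |
| `bm_sigma2` | 0.02 /Myr | Brownian rate of the latent severity (tip sd ≈ 1 over a ~50 Myr tree) |
| `mass_slope` | 1.0 | latent units per log₁₀ kg |
| `mass_sigma2` | 0.008 /Myr | Brownian rate of log₁₀ mass (tip sd ≈ 0.6, the study's spread) |
| `mass_root_log10` | 2.78 | ≈ 600 kg, the study's geometric mean |
| `fad_window` | (5, 48) Ma | uniform tip FADs for random trees |
| `range_myr` | (0.5, 4) | uniform FAD−LAD stratigraphic ranges |

Log₁₀ mass evolves by Brownian motion on the calibrated tree, so tip masses
are lognormal (spanning roughly the study's 36–1840 kg for the default rate)
and phylogenetically structured — deliberate, because body mass is heritable
on real trees, it makes the null calibration of the contrast test exact, and
it is what makes the naive species-level regression anticonservative under
the null (a property the tests document). Latent severity is
`baseline + BM(bm_sigma2) + mass_slope·(log₁₀m − mean log₁₀m)`; ordinal ranks
are drawn per element and category from the cumulative-logit model
`P(rank ≤ r) = logistic(θ_r − μ)` (probit by switch; optional per-category
offsets mimic the real pattern that articular-surface scores run lowest).
All randomness derives from one root seed through named streams
(tree/mass/severity/scores), so stages are independently reproducible and
same-seed runs are byte-identical.

What the generator does *not* emulate: taphonomic loss and preservation bias,
within-taxon age structure, correlated categories within an element, and
non-Brownian mass evolution. Passing recovery tests therefore demonstrate
that the inference machinery is correct and calibrated under its own
assumptions, not that those assumptions hold for any particular fossil
assemblage.

## Recovery experiments

`recovery_experiment` runs a grid over true effect sizes; each cell simulates
studies, runs both the species-level and contrast regressions of overall IPa
on log₁₀ mass, and reports rejection rate, slope bias, and slope RMSE. The
estimand is the *structural slope*: the OLS slope of the noiseless expected
index (closed-form mean rank summed over categories) on log₁₀ mass — the
effect of mass with Brownian and sampling noise switched off. Because the
link is nonlinear the structural slope is not `7·mass_slope`; it is computed
exactly per replicate.

The test suite fixes two cells: a null cell (15 taxa, 150 elements/taxon,
`bm_sigma2 = 0.05`, slope 0, 500 replicates) whose contrast-regression
rejection rate must sit within three binomial standard errors of α = 0.05,
and a strong-effect cell (30 taxa, 200 elements/taxon, slope 2.0,
`bm_sigma2 = 0.005`, 200 replicates) requiring ≥ 99% sign recovery and a mean
slope within 10% of the structural truth. The strong cell's settings were
chosen to be unambiguously strong (high slope, low drift, large samples) as
the definition of a detectable effect; effect size is otherwise treated as a
free experimental axis. These problem sizes keep the whole suite to well
under a minute of simulation while leaving Monte-Carlo error far inside the
asserted bounds.

## Numerical choices and degenerate inputs

* Zero-duration detection uses an absolute tolerance of 1e-12 Myr.
* Perfect fits (R² = 1) report p = 0 rather than propagating an infinite F.
* Through-origin adjusted R² follows the statsmodels convention
  (df_total = n).
* `category_ipa` on an all-zero count vector, constant predictors, n < 3
  regressions, rank values outside 1–4, FAD < LAD, extant taxa with LAD ≠ 0,
  and polytomous trees all raise typed validation errors naming the offending
  row/column/taxon where applicable.
* The allometric mass estimator (a·length^b) is a convenience shell: it
  refuses to run without user-supplied coefficients because no authoritative
  coefficients ship with the package; the pipeline uses tabulated masses.

## Known limitations

* The 'equal' redistribution convention (preorder chain processing) is one
  concrete reading of equal-style time-scaling; other implementations may
  partition donors differently while preserving the same invariants.
* Ordinal ranks are treated as exchangeable within a taxon; there is no
  within-individual or within-element correlation model.
* No phylogenetic signal estimation (λ, K), Ornstein–Uhlenbeck models, or
  stochastic (cal3-style) calibration; the GLS machinery exists only as a
  test oracle.
* The comparative analysis assumes the seven category means behave as
  continuous traits, which is reasonable at the study's per-taxon sample
  sizes (≥ 65 elements) but degrades for small assemblages.
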