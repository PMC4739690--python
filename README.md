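# rhinopath

Osteopathology severity indices and phylogenetically controlled body-mass
regressions for fossil skeletal assemblages.

## The problem

Skeletal assemblages of extinct and extant rhinocerotoids (and other large
herbivores) preserve visible bone pathologies — exostoses, joint-margin
lipping, abnormal surface textures, cavitation, deformed or irregularly sized
foramina, and articular-surface damage. A natural comparative question is
whether heavier lineages accumulate more of this damage. Answering it takes
four steps, all implemented here:

1. **Scoring and aggregation.** Each skeletal element is ranked 1 (normal
   bone) to 4 (severe) in seven pathology categories. Per taxon, the
   count-weighted mean rank of each category is its category index, and the
   **Index of Pathology (IPa)** is the sum of the seven category means:

   IPa = Σ₇ ( Σᵣ r·n_r / Σᵣ n_r ),  bounded in [7, 28].

2. **Time-calibration.** The study cladogram gets branch durations from
   stratigraphic first/last appearance data (FAD/LAD), with either the
   *basic* rule (node age = oldest descendant FAD) or the *equal* rule, which
   additionally removes zero-length branches by sharing time down from the
   nearest ancestral branch of positive duration.

3. **Independent contrasts.** Felsenstein's contrasts transform tip values
   into n−1 standardized, phylogenetically independent differences under
   Brownian motion: C = (Xᵢ−Xⱼ)/√(vᵢ+vⱼ), with ancestral values imputed by
   branch-length weighting and parent branches inflated by vᵢvⱼ/(vᵢ+vⱼ).

4. **Regression.** Ordinary least squares of each pathology index on (log)
   body mass, at the species level and in contrast space, reporting slope,
   R², adjusted R², F, and p.

A synthetic-assemblage generator (random trees, Brownian log-mass and latent
severity, cumulative-link ordinal scores) makes every stage testable without
any external data and supports power/calibration experiments.

## Worked example

The packaged fixtures carry the seven-taxon rhinocerotoid study: taxon
masses and stratigraphic ranges, the per-taxon rank-frequency table, the
specimen inventory, and the study cladogram.

```bash
rhinopath ipa --out demo
rhinopath comparative --out demo
```

or equivalently in Python:

```python
from rhinopath.pipeline import RunConfig, run_ipa_report, run_comparative
report = run_ipa_report(RunConfig(outdir="demo"))
grid   = run_comparative(RunConfig(outdir="demo"))
```

For *Trigonias osborni* (114 scored elements per category) the report reads:

```
         category   n  mean  overall
        exostoses 114  1.89    11.06
          lipping 114  1.33    11.06
          texture 114  2.00    11.06
       cavitation 114  1.34    11.06
    foramen_shape 114  1.58    11.06
     foramen_size 114  1.72    11.06
articular_surface 114  1.19    11.06
```

Each `mean` is that category's average severity (1 = all normal bone, 4 =
uniformly severe); their sum, 11.06, is the taxon's overall IPa — mild overall
pathology dominated by abnormal bone texture. The comparative run then
regresses each index on log₁₀ mass across the seven taxa, with and without
phylogenetic control (overall-index rows shown):

```
analysis  slope  r2_adj  f_stat  p_value
  linear 3.3851  0.5084  7.2050   0.0436
      ic 2.3259  0.1090  1.7342   0.2450
```

The species-level fit says mass explains roughly half the variation in
overall pathology (p < 0.05); the independent-contrast fit, which discounts
similarity inherited from common ancestors, is weaker — the classic signature
of a trend carried substantially by phylogeny. Every output CSV gets a JSON
sidecar recording the configuration and seed.

Synthetic data and recovery experiments:

```bash
rhinopath simulate --out study --tree-source random --n-taxa 20 --seed 7
rhinopath recovery --out rec --mass-slopes 0,1,2 --n-reps 200 --seed 7
```

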