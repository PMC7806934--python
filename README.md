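# lymphoscreen

Quantitative immunofluorescence screening of white blood cells for a
blood-based breast-cancer marker, as a reusable, tested pipeline.

The scientific setting: breast-cancer cells secrete factors that alter
protein expression in circulating leukocytes, so a marker protein (STAU2,
staufen double-stranded RNA-binding protein 2) measured in T and B
lymphocytes can act as a screening signal without touching the tumour.
Fixed white blood cells on a 96-well plate are stained in three channels —
nuclear (Hoechst, blue), pan-leukocyte (anti-CD45, red) and marker
(anti-STAU2, green) — and imaged as 12 fields per well. This package
implements every computational stage of that screen, plus the synthetic
data needed to test it end to end:

- **`lymphoscreen.simulate`** — synthetic inputs with known ground truth:
  calibrated 3-channel field images with disk-shaped cells, two-group
  cohorts of per-sample statistics with the published group moments, and
  paired expression studies with planted shared up-regulated genes.
- **`lymphoscreen.quantify`** — per-cell quantification: blobs are
  connected components above a grey-value threshold, kept when their
  boundary perimeter is 25–200 µm and mean grey value 140–300; green
  marker blobs colocalize to the nearest red leukocyte blob; a cell is
  marker-positive when its green signal has perimeter 25–150 µm and mean
  grey 150–280. A sample reduces to two statistics: average marker
  intensity and % positive cells.
- **`lymphoscreen.cohort`** — group t-tests, ROC curves, and the two-axis
  quadrant classifier: a sample is screen-positive when
  `avg_intensity >= x` **or** `pct_positive >= y` for a cut-off `(x, y)`;
  only the lower-left quadrant is negative. Metrics per cut-off:
  sensitivity, specificity, NPV, PPV, accuracy, odds ratio
  `(tp·tn)/(fp·fn)` with a Woolf 95% CI
  `exp(ln OR ± 1.96·√(1/tp + 1/fp + 1/fn + 1/tn))`, and a chi-squared
  p-value.
- **`lymphoscreen.risk`** — Bayes post-test probability:
  post-test odds = pre-test odds × likelihood ratio, with
  LR⁺ = sens/(1−spec) for a positive result.
- **`lymphoscreen.intersect`** — cross-study marker discovery: per-gene
  t-tests call each gene up/down/ns in two case-control studies (or one
  study vs a fixed gene list), then a 2×2 test (chi-squared, or Fisher
  exact for small expected counts) measures whether the calls co-occur
  beyond chance.

## Worked example

```python
import lymphoscreen as ls

# the balanced cut-off's 2x2, reconstructed from its published rates
table = ls.confusion_from_rates(0.8296, 0.8347, n_diseased=358, n_healthy=363)
m = ls.screening_metrics(table)
print(f"OR = {m.odds_ratio:.2f}, 95% CI = ({m.or_ci_95[0]:.2f}, {m.or_ci_95[1]:.2f})")
print(f"accuracy = {100*m.accuracy:.2f}%, NPV = {m.npv:.4f}, PPV = {m.ppv:.4f}")

post = ls.posterior_probability(ls.RiskInput(1/220, 0.8296, 0.8347, "positive"))
print(f"post-test probability = {100*post:.2f}%")
```

prints

```
OR = 24.59, 95% CI = (16.64, 36.34)
accuracy = 83.22%, NPV = 0.8324, PPV = 0.8319
post-test probability = 2.24%
```

i.e. a woman under 40 (pre-test risk 1 in 220, 0.455%) with a positive
result at the balanced cut-off carries roughly the pre-test risk of a
woman over 40 (2.42%) — the screen re-stratifies young women onto the
older age group's risk level.

A full synthetic screen, from images to metrics:

```python
cfg = ls.ImageSimConfig(n_cells=40, positive_fraction=0.4, background_noise_sd=0.0)
fields, truth = ls.generate_well_fields(cfg, n_fields=12)   # one well
sample = ls.quantify_well(fields, ls.QuantConfig(), sample_id="A1")
print(sample.pct_positive)        # 40.0 — exactly the planted fraction

cohort = ls.generate_cohort(ls.CohortSimParams(n_cancer=358, n_normal=363, seed=0))
metrics = ls.evaluate_cutoffs(cohort)                        # cut-offs A, B, C
```

The same stages are scriptable from a shell via the `lymphoscreen` CLI
(`simulate`, `quantify`, `evaluate`, `risk`, `intersect`); see
`lymphoscreen --help`.

## Documentation

`docs/methods.md` describes the models, parameter choices, numerical
decisions and the limits of what the synthetic data can demonstrate.
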