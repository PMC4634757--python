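# follisig

A transcriptomic signature of early ovarian folliculogenesis, as a tested,
reusable pipeline. The package is for quantitative biologists who want to
discover, quantify and use small biomarker panels that discriminate the
earliest follicular stages — primordial (PD), primary (PM), secondary (SC)
and small antral (SA) — in the two follicular compartments, oocyte (O) and
granulosa cells (GC), with multi-tissue RNA pools (MT) as a specificity
background.

It implements, end to end:

- **NB differential expression** on gene x sample count tables:
  median-of-ratios size factors, method-of-moments dispersion, a
  conditional NB exact test for pairwise stage contrasts, and a
  `count ~ stage` vs `count ~ 1` likelihood-ratio test per compartment,
  with the selection gates FDR < 5%, pairwise p < 1%, fold change > 2;
- **biomarker selection** of group-specific genes against all remaining
  samples pooled (MT included), FDR < 5% with FC > 10 (oocyte) / > 3
  (granulosa);
- **efficiency-corrected qPCR quantification**: standard-curve efficiency
  `E = 10^(-1/slope)`, Pfaffl ratios `E^(Ct_cal - Ct)`, geometric-mean
  reference normalization, geNorm M stability ranking, detection calling;
- **a two-part hurdle mixed model** of the panel: hierarchical logistic
  regression for presence/absence and a Gaussian model on fourth-root
  levels (with a single augmented null record per fully undetected cell),
  both with per-gene random stage vectors `b_g ~ MVN(0, Sigma_stage)`
  whose across-stage correlations are estimated, plus compartment shifts;
- **posterior stage prediction**: for a new observation vector z, y in
  compartment c,

      P(s | z, y) ∝ prior(s) · Π_g p[g,s,c]^z (1-p)^(1-z)
                              · Π_{z=1} N(y^(1/4); mu[g,s,c], sigma)

  with a binary-only variant, and the 100-vector-per-stage resampling
  study of predictive ability (posterior panels + confusion matrices);
- **a synthetic-data generator** reproducing the study design (8 stage x
  compartment groups, 3–4 replicates, 3 MT pools) with full ground truth,
  so every stage of the chain is testable without any external data.

See `docs/methods.md` for the models, estimation (exact-ML EM for the
Gaussian part, Laplace-approximated ML for the logistic part) and the
generator's assumptions.

## Worked example

```python
from follisig import simulate, hurdle, predict

design = simulate.generate_design()                     # 31 LCM samples + 3 MT pools
params = simulate.HurdleSimParams.correlated_stages(    # stage effects with
    corr_pd_pm=0.95, corr_pd_sa=-0.9, seed=3)           # planted correlations
panel = simulate.simulate_hurdle_panel(design, params)  # 24-gene qPCR-style panel

fit = hurdle.fit_hurdle(panel.det, panel.rel, design)
report = hurdle.stage_effect_correlations(fit)
print(report["presence"]["overall"].round(2))
```

prints the estimated across-gene stage correlations of the detection
random effects:

```
      PD    PM    SC    SA
PD  1.00  0.99  0.40 -0.95
PM  0.99  1.00  0.37 -0.96
SC  0.40  0.37  1.00 -0.15
SA -0.95 -0.96 -0.15  1.00
```

Detection behaves almost identically at PD and PM (correlation 0.99) and
reverses between PD and SA (-0.95) — the planted 0.95 / -0.9 structure,
recovered from 24 genes. Predicting the stage of a fresh expression
vector:

```python
vec = predict.resample_vectors(panel.rel, panel.det, design, "SC", "GC",
                               n=1, seed=0)[0]
post = predict.posterior_stage(fit, vec)
print(post.probs.round(6), "->", post.predicted)
```

```
PD    0.0
PM    0.0
SC    1.0
SA    0.0
dtype: float64 -> SC
```

The full pipeline (simulate → qpcr → de → biomarkers → fit → predict) runs
from the command line and writes TSV artifacts plus a manifest into a run
directory:

```sh
follisig run-all --out runs/demo --seed 7
follisig validate --config my_config.yaml
```

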