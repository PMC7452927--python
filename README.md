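# ipssirt

Pharmacometric item-response-theory (IRT) analysis of the International
Prostate Symptom Score (IPSS) — the 7-item, 0–5-scored questionnaire used
to grade lower urinary tract symptoms in benign prostatic hyperplasia
(BPH-LUTS) — for statisticians and pharmacometricians analysing or
designing BPH-LUTS trials.

Instead of modelling only the 0–35 composite score, the package models the
item-level responses through Samejima's graded response model,

    P(Y_ij ≥ k) = expit( a_j (ψ_i − τ_jk) ),   k = 1..5,

where ψ_i is a patient's latent disability, `a_j` the discrimination of
item *j*, and `τ_jk` its ordered category thresholds. On top of the item
model sit:

* **ICC estimation** by marginal maximum likelihood with each
  patient-visit treated as an independent pseudo-individual (IDVIS):
  baseline disability fixed to N(0, 1), an estimated post-baseline
  mean/variance shift, optionally two correlated latent dimensions
  (voiding: items 1, 3, 5, 6; storage: items 2, 4, 7) — 44 or 47 free
  parameters.
* **Fisher-information ranking** of the items over a disability range.
* **Longitudinal mixed-effects models** of the total score and of the
  latent disability, `Baseline + Pmax(1 − e^{−(ln2/Tprog)·t})^{WEI-form} +
  Drift·t + Drug`, fitted by per-subject Laplace marginalisation — as a
  sequential stage on MAP disability estimates with their standard errors
  as a known residual component (PSI-IPPSE), or jointly at the item level.
* **Diagnostics**: an η-sampling cross-validated GAM check of the ICCs
  (posterior-sampled disabilities, binomial P-spline smooths, bands
  widened by √n_samples), residual item correlations, and visual
  predictive checks.
* **An SSE power engine** comparing the model-based drug-effect tests
  (with empirically calibrated type-I error) against cross-sectional and
  while-on-treatment ANCOVA.

Everything runs on synthetic trials: the built-in simulator reproduces the
reference study design (403 patients, placebo/10/20/30 mg single dose,
visits at 0, 0.5, 1, 2, 3, 4, 5, 6 months, screening IPSS ≥ 13) from a
reference item bank and longitudinal estimates shipped in
`ipssirt.reference`.

## Worked example

```python
import numpy as np
import ipssirt as ip
from ipssirt import reference as ref

bank, shift = ref.unidimensional_bank(), ref.unidimensional_shift()

# a full-design synthetic dataset: 403 patients x 8 visits, one latent
# draw per visit (baseline N(0,1), post-baseline N(-1.38, 2.22))
data = ip.simulate_idvis_dataset(bank, shift, n_patients=403, seed=1)
pseudo = ip.reshape_idvis(data)

# refit all 44 ICC parameters by marginal maximum likelihood
fit = ip.GradedResponseMML(pseudo, n_dimensions=1).fit(compute_se=False)
print(f"OFV {fit.ofv:.1f}  a1 {fit.params['a1']:.3f}  a7 {fit.params['a7']:.3f}")

# MAP disability per patient-visit, and its concordance with the total score
ebe = fit.estimate_disability()
r2 = np.corrcoef(pseudo["total"], ebe["ebe"])[0, 1] ** 2
print(f"r2(total, disability) = {r2:.3f}")
```

prints (seed 1):

```
OFV 66376.8  a1 1.422  a7 0.474
r2(total, disability) = 0.962
```

The refit recovers the generating discriminations (1.38 and 0.49) to a few
percent at this design, and the total score explains ~96% of the variance
in estimated latent disability — close agreement between the cheap
composite and the model-based disability scale, with the residual spread
showing why equal total scores can hide different underlying severities.

Ranking the items by Fisher information over disability −6..3:

```python
from ipssirt.information import information_share
rep = information_share(bank, (-6, 3))
print(rep.to_frame().head(3))
print(f"voiding items combined: {rep.voiding_share:.1f}%")
```

```
   item subscore  pct_of_total  cumulative_pct
0     1  voiding          23.8            23.8
1     3  voiding          20.6            44.4
2     5  voiding          15.8            60.2
voiding items combined: 71.6%
```

— incomplete emptying is the most informative item, nocturia (3.5%) the
least, and the four voiding items carry ~72% of the total information.

A command-line layer mirrors the stages
(`ipssirt simulate | fit-icc | fit-long | info | diagnose | power |
pipeline`); `ipssirt pipeline --out dir/` runs a desk-scale end-to-end
analysis.

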