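# ivmr — two-sample Mendelian randomization from GWAS summary statistics

`ivmr` estimates the causal effect of an exposure on an outcome using
genetic variants as instrumental variables, working entirely from GWAS
summary statistics (per-variant effect sizes, standard errors, alleles and
allele frequencies from two different studies). It ships with the complete
11-instrument analysis of plasma vitamin C on Parkinson's disease (PD)
risk and PD age at onset (AAO), bundled as plain-text fixtures, so the
whole pipeline can be exercised and reproduced offline.

Intended users: genetic epidemiologists and biostatisticians who want a
scriptable, tested MR toolchain, and methodologists who want a simulator
with known ground truth for benchmarking MR estimators.

## The model

For instrument *j*, let γ̂_j (SE σ_xj) be its effect on the exposure and
Γ̂_j (SE σ_yj) its effect on the outcome, both expressed on the
exposure-raising allele after harmonization. Under the instrumental-variable
assumptions each Wald ratio Γ̂_j/γ̂_j estimates the causal effect β of one
SD of exposure. The package implements:

- **IVW** — weighted regression of Γ̂ on γ̂ through the origin, weights
  1/σ_yj²; multiplicative random effects by default: SE inflated by
  max(1, √(Q/(k−1))).
- **MR-Egger** — the same regression with a free intercept; the slope is
  robust to directional pleiotropy under the InSIDE assumption and the
  intercept estimates the average direct effect.
- **Weighted median** — the interpolated median of the Wald ratios under
  weights (γ̂_j/σ_yj)², consistent while valid instruments hold >50% of the
  weight; SE by parametric bootstrap.
- **MR-PRESSO** — a simulation-based residual-sum-of-squares test for
  horizontal pleiotropy with per-variant outlier detection, an
  outlier-corrected estimate, and a distortion test.
- **Diagnostics** — Cochran's Q and I² (with a test-based confidence
  interval), the Egger intercept test.
- **Power** — per-variant and total variance explained
  (R² = F/(F + n − 2), F = (β/se)²) and the binary-outcome power /
  detectable odds ratio via the standard non-centrality approximation.

Harmonization orients every pair to the exposure-raising allele, aligns
outcome records by allele match, swap or strand complement, and resolves
palindromic variants (A/T, C/G) by allele-frequency comparison, dropping
them as ambiguous near frequency 0.5.

## Worked example

The bundled preset runs the full vitamin C analysis (exposure GWAS
n = 52,018; PD outcome 33,674 cases / 449,056 controls; PD AAO n = 28,568):

```sh
$ ivmr reproduce-paper --out results/ --seed 1
      PD ivw              beta=-0.049 CI=[-0.294, +0.197] p=0.698
      PD weighted_median  beta=-0.017 CI=[-0.267, +0.233] p=0.896
      PD egger_slope      beta=+0.127 CI=[-0.252, +0.507] p=0.510
      PD presso_raw       beta=-0.049 CI=[-0.294, +0.197] p=0.706
  PD_AAO ivw              beta=-1.132 CI=[-2.513, +0.250] p=0.108
  PD_AAO weighted_median  beta=-1.753 CI=[-3.377, -0.129] p=0.034  *
  PD_AAO egger_slope      beta=-2.588 CI=[-4.620, -0.556] p=0.013  *
  PD_AAO presso_raw       beta=-1.132 CI=[-2.513, +0.250] p=0.140
```

Each `beta` is the change in the outcome (log-odds of PD, or years of
AAO) per 1 SD of genetically raised plasma vitamin C. No method finds an
effect on PD risk; for age at onset the weighted median and MR-Egger reach
p < 0.05 (starred), estimating that each SD of vitamin C delays onset by
roughly 1.8–2.6 years, with IVW showing the same direction (−1.13 years,
p = 0.108). `results/` receives `report.json`, `estimates.tsv`,
`diagnostics.tsv` and per-outcome `scatter_*.tsv` files (the per-variant
effects plus the Egger regression line, ready for plotting).

The same analysis from Python:

```python
from ivmr import datasets, harmonize, ivw

hs = harmonize(datasets.load_vitc_exposure(), datasets.load_pd_aao_outcome())
print(ivw(hs))          # beta=-1.13, 95% CI [-2.51, 0.25]
```

Other entry points: `ivmr run` (your own TSVs), `ivmr power`
(variance explained, detectable OR), `ivmr simulate` (synthetic studies
with ground truth).

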