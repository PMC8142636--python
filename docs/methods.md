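# Methods

This note documents the statistical procedures implemented in `ivmr`, the
conventions and numerical choices behind them, and what the simulator does
and does not emulate.

## Data model and harmonization

A `VariantAssociation` is one variant's summary record in one GWAS:
alleles (A/C/G/T, distinct), effect-allele frequency in [0, 1], beta, a
positive SE, a p-value in (0, 1] and an optional sample size. Invariants
are enforced at construction; TSV readers collect all invalid rows and
raise one error naming every offending variant rather than dropping rows
silently. Positions are stored as given (1-based, GRCh37 in the bundled
tables) and never used in computation.

Instrument selection keeps variants with p below a threshold (default the
conventional genome-wide 5×10⁻⁸). Instruments are assumed pre-pruned for
linkage disequilibrium; no clumping, proxy lookup or reference-panel
queries are performed.

Harmonization proceeds per shared variant:

1. orient the exposure record to its exposure-raising allele (swap
   alleles, negate beta, reflect the frequency when beta < 0);
2. align the outcome record by literal allele match, by swap (negating
   beta and reflecting the frequency), or — before declaring a
   mismatch — by strand complement followed by the same two checks,
   since summary files differ in strand convention;
3. palindromic pairs (A/T, C/G) cannot be aligned by labels: the
   orientation minimizing |eaf_exp − eaf_out| is chosen, and the variant
   is dropped as an ambiguous palindrome when min(eaf, 1 − eaf) >
   0.5 − *w*. The window *w* defaults to 0.08 (resolvable only when the
   exposure frequency is outside [0.42, 0.58]) — a conventional safe
   margin, exposed as a parameter since there is no canonical value.

Dropped variants always carry a reason, and |retained| + |dropped| equals
the number of distinct input variants. The allele-swap transform is an
exact involution on alleles and beta; the frequency reflection
1 − (1 − eaf) is exact only to one ulp, which is the resolution the tests
assert.

## Estimators

All multi-instrument estimators regress outcome effects Γ̂_j on exposure
effects γ̂_j with weights 1/σ_yj², ignoring the error in γ̂ (the standard
first-order convention; the Wald-ratio SE is σ_yj/|γ̂_j|).

**IVW.** Slope through the origin. The default is a multiplicative
random-effects model: the fixed-effect SE 1/√(Σγ̂²/σ_y²) is multiplied by
max(1, √(Q/(k−1))), where Q is the weighted residual sum of squares, so
between-instrument heterogeneity widens the interval but can never shrink
it below the fixed-effect SE. On the bundled PD-AAO data this floor is
active in spirit only (Q/(k−1) = 1.18 > 1); the floor matters for the
Egger fit below.

**MR-Egger.** The same regression with a free intercept. SEs come from
the 2×2 WLS information matrix, both inflated by max(1, √(Q_egger/(k−2))).
On the PD-AAO data Q_egger/(k−2) = 0.957 < 1, so the floor is engaged;
this is precisely what reproduces the published interval
[−4.623, −0.560] — an unfloored fit (e.g. plain statsmodels WLS) gives a
2% narrower SE. The intercept estimates the average direct (pleiotropic)
effect; the intercept test flags directional pleiotropy at a configurable
alpha (default 0.05).

**Weighted median.** Ratios r_j = Γ̂_j/γ̂_j with weights w_j = (γ̂_j/σ_yj)²
are sorted; the standardized cumulative weight of the j-th order statistic
is p_j = (S_j − w_j/2)/S_total and the estimate interpolates r against p
at p = 0.5. Several interpolation conventions exist; this one is the
half-step convention used by the mainstream MR toolchain. The SE is a
parametric bootstrap: γ̂ and Γ̂ are redrawn from normal(beta, se) per
variant, weights recomputed, the median recomputed, over n_boot (default
1000) seeded replicates; CI and p use the normal reference on the
bootstrap SE.

**Reference distributions.** IVW, Egger and weighted-median CIs and
p-values use standard-normal quantiles; the printed half-width/SE ratios
of the reproduced study are 1.96, not the t quantile, so this matches the
source toolchain. MR-PRESSO (below) is the exception.

## MR-PRESSO

Observed statistic: RSS_obs = Σ_j w_j (Γ̂_j − β̂^(−j) γ̂_j)² with
w_j = 1/σ_yj² and β̂^(−j) the fixed-effect through-origin slope computed
without variant j. The null distribution redraws γ̂*_j ~ N(γ̂_j, σ_xj) and
Γ̂*_j ~ N(β̂^(−j) γ̂_j, σ_yj) and recomputes the full leave-one-out RSS per
replicate; the global p-value is (1 + #{RSS* ≥ RSS_obs})/(n_sim + 1), so
its floor is 1/(n_sim + 1). Per-variant outlier p-values compare each
variant's observed weighted squared residual with its own simulated
distribution and are flagged at alpha/k (Bonferroni). With outliers
removed, the corrected estimate is re-fitted and a distortion test
compares the raw-vs-corrected slope change against the change from
removing random subsets of the same size (1000 subsets).

The raw and corrected estimates equal the IVW fit numerically, but their
p-values use a Student-t reference with k − 1 degrees of freedom while
the 95% CI keeps the normal quantile. This mixed convention mirrors the
original tool's output (identical beta and CI to IVW, larger p: 0.139 vs
0.108 on the PD-AAO data) and is reported with `ref_dist="t"` so callers
can tell the references apart. Default n_sim is 1000 with a mandatory
explicit seed parameter for reproducibility.

## Heterogeneity

Cochran's Q is computed on the ratio scale around the **fixed-effect**
IVW estimate (the standard definition, regardless of which IVW model is
reported), df = k − 1, p from the chi-square upper tail.
I² = max(0, (Q − df)/Q)·100. The I² CI is the test-based interval on
H = √(Q/df): a normal interval for ln H with
se(ln H) = (ln Q − ln df)/(2(√(2Q) − √(2k−3))) when Q > k and
√(1/(2(k−2))·(1 − 1/(3(k−2)²))) otherwise, back-transformed and truncated
to [0, 100] (for k = 2 with small Q the interval is reported as [0, 100]).
On the PD-AAO data this reproduces the published I² = 15.6% with CI
[0.0%, 56.1%] exactly.

## Variance explained and power

Per-variant R²_i = F_i/(F_i + n_i − 2) with F_i = (β_i/se_i)², summed over
the independent instruments (0.76% for the strongest vitamin C variant,
1.79% in total on the bundled data). An alternative formula
β²/(β² + 2·n·se²) is available as `formula="naive_printed"`; it is
internally inconsistent with the per-variant values the source study
tabulates (it understates R² by roughly a factor of two, its "2n" acting
as a spurious doubling of the sample size) and is provided for comparison
only.

Binary-outcome power uses the non-centrality approximation of the mRnd
calculator: with case fraction K, the attenuated IV effect is
b = K(OR/(1 + K(OR − 1)) − 1), its variance v = (K(1−K) − b²)/(N·R²), and
power is P(χ²₁(ncp = b²/v) > χ²₁,1−α). At OR = 1 power equals alpha
exactly. `detectable_or` inverts this by plain bisection on OR in
(0.5, 1) (protective) or (1, 2) (risk) to |power − target| < 10⁻⁶.

Two named case/control presets ship for the PD outcome: the full
meta-analysis counts (56,306 cases / 1,417,791 controls) and the publicly
available analysis subset (33,674 / 449,056). The full-meta preset is the
configuration under which 80% power corresponds to a protective OR of
0.91 — the subset gives 0.88 — and is the reproduction default.
Continuous-outcome (AAO) power is not implemented: it would require
regression coefficients from an observational vitamin C–AAO study, which
is not available.

## Simulator

`simulate_study` draws, per instrument: a true exposure effect γ_j
uniform on `gamma_range` (strictly positive, mirroring the harmonized
orientation), a direct effect α_j (zero, balanced-normal, or directional
with mean `pleiotropy_mean` and SD `pleiotropy_scale`; optionally
correlated with γ at ρ = 0.5 to violate InSIDE; optionally confined to a
random `invalid_fraction` of instruments), and the true outcome effect
Γ_j = θγ_j + α_j. Reported SEs follow the single-variant GWAS identity
se ≈ sd(phenotype)/√(2·n·p(1−p)) with the allele frequency drawn uniform
on (0.05, 0.95). The noise scales multiply only the *realised* sampling
error, not the reported SE, so `se_*_scale = 0` yields observed effects
exactly equal to the truth while weights stay finite — the configuration
used for exactness tests.

Defaults are calibrated once to the bundled study: k = 11 instruments,
exposure GWAS n = 52,018 on a standardized phenotype (this reproduces the
fixture's exposure SEs to within ~5%), outcome GWAS n = 28,568 with an
effective phenotype SD of 15 years (the value that matches the fixture's
AAO instrument SEs; it exceeds the ~12-year phenotypic SD of onset age
because meta-analytic heterogeneity inflates the effective SE), and
θ = −1.134 years per SD, the IVW estimate on the bundled data.

What the simulator does **not** emulate: linkage disequilibrium between
instruments, sample overlap between the two GWAS, winner's-curse selection
of instruments, allele-frequency differences between studies, strand
mislabeling, or non-normal sampling error. Passing operating-characteristic
tests therefore demonstrate correctness of the estimators under the
idealized two-sample model, not robustness to those real-data artifacts.

`operating_characteristics` runs seeded replicates through the same
harmonization path as real data and tabulates bias, empirical SE, 95% CI
coverage and rejection rate at 0.05 for IVW, Egger or the weighted median.

## Reproduction tolerances and scale choices

The bundled tables carry 3-decimal effects, so reproduced estimates agree
with the published ones to ~0.01 on betas and CI bounds and ~0.005 on
deterministic p-values; the published PD IVW p-value (0.708) is the one
quantity outside that band (computed: 0.698), because the smallest PD
outcome effects (|β| down to 0.002) lose ~20% relative precision to
rounding — the published beta and CI are reproduced, and the same
rounding analysis shows the printed PD row is not self-consistent at 3
decimals. The published PD heterogeneity cells (I² = 2.4%, Q p = 0.0669)
are mutually inconsistent for k = 11 (the computed Q = 16.5 implies
I² = 39%) and are not used as a reference; the PD-AAO row, which is
internally consistent, is.

Stochastic checks use: 1000 bootstrap/simulation replicates for the
weighted median and MR-PRESSO (global-p Monte-Carlo SD ≈ 0.015 at
p ≈ 0.3); 1000 simulated studies for type-I error and coverage; 500 for
Egger-intercept recovery; 200 for the MR-PRESSO size check at n_sim = 200.
These sizes keep the full suite to a few seconds while leaving
Monte-Carlo error well inside the asserted bands. All stochastic paths
take explicit seeds; the pipeline derives per-component sub-seeds from
one master seed, and the report digest (which excludes only the
timestamp) is identical across runs with the same configuration.
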