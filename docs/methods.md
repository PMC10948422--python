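# Methods

This note documents the statistical model, the defaults and why they were
chosen, the numerical decisions, and what the synthetic-data tests do and do
not demonstrate.

## Two-sample MR model and estimators

Each genetic instrument *j* carries a true effect b<sub>j</sub> on the
exposure; the exposure has causal effect θ on the outcome; a direct
(pleiotropic) effect α<sub>j</sub> may bypass the exposure.  Observed
summary statistics are β̂<sub>Xj</sub> ~ N(b<sub>j</sub>, σ²<sub>Xj</sub>)
and β̂<sub>Yj</sub> ~ N(θ·b<sub>j</sub> + α<sub>j</sub>, σ²<sub>Yj</sub>),
independent across studies (no sample overlap).  Valid instruments have
α<sub>j</sub> = 0.

- **Wald ratio / IVW.** Ratio standard errors use the first-order delta
  method (σ<sub>Yj</sub>/|β<sub>Xj</sub>|), which ignores uncertainty in
  β<sub>Xj</sub>; this is the conventional choice and is accurate when
  instruments are strong (the F ≥ 10 filter enforces |z<sub>X</sub>| ≥
  √10).  IVW defaults to the multiplicative random-effects variant: the
  fixed-effect standard error is inflated by √(Q/(k−1)) whenever Cochran's
  Q exceeds its k−1 degrees of freedom, and never deflated.  A fixed-effect
  mode is available by flag.  With a single instrument IVW degrades to the
  Wald ratio with a logged note.
- **MR-Egger.** Weighted least squares of β<sub>Y</sub> on β<sub>X</sub>
  with intercept, weights 1/σ²<sub>Y</sub>, after sign-standardizing every
  pair so β<sub>X</sub> ≥ 0 (required for the intercept to estimate average
  directional pleiotropy).  Inference uses t with k−2 df, and the residual
  dispersion multiplier is floored at 1, mirroring common practice.
  I²GX = max(0, (Q<sub>GX</sub> − (k−1))/Q<sub>GX</sub>) quantifies
  regression dilution; values below 0.9 trigger a logged attenuation
  warning.
- **Weighted/simple median.** The inverse-variance-weighted median is
  computed by linear interpolation of the cumulative weight function at
  0.5 (cumulative weight minus half the variant's own weight, the standard
  construction).  Standard errors come from a seeded parametric bootstrap:
  each ratio is resampled from N(r<sub>j</sub>, se<sub>j</sub>) and the
  median recomputed; default 1000 replicates.  P-values are normal.
- **Weighted mode.** Maximizer of a weighted Gaussian KDE over the ratios;
  bandwidth is φ times the modified Silverman rule
  0.9·min(sd, mad)·k^(−1/5) with φ = 1 by default (the conventional choice
  in the mode-estimator literature, exposed as a flag).  The maximum is
  located on a 2001-point grid and polished by bounded scalar minimization
  (xatol 1e-10); a degenerate bandwidth (all ratios equal) returns the
  common ratio.  Bootstrap as for the medians.

Estimates for binary outcomes are exponentiated to odds ratios with 95%
bounds exp(β ± 1.959964·se).  `wald_p_from_or_ci` inverts that convention
(se = CI log-width / 2·1.959964) to recover the two-sided Wald p implied by
a reported OR and CI — the basis of the published-table consistency
checker.

## Instrument selection

Two named presets reflect the asymmetry of the two directions: the
brain-structure→disease direction uses p < 5e-6 with a 10 Mb clumping
window, the disease→brain-structure direction p < 5e-8 with 250 kb; both
use r² ≤ 0.001, MAF > 0.01.  Clumping is greedy on ascending p (ties broken
lexicographically by variant ID so the kept set is order-independent), the
window is interpreted as distance from the index variant inclusive, and
candidates absent from the LD reference are dropped with a warning by
default (strict mode raises).  Per-SNP variance explained defaults to
z²/(z² + n − 2), which needs only summary fields; 2·MAF(1−MAF)β² is
available for standardized traits.  With k = 1 the F formula reduces
algebraically to z², so the weak-instrument filter is equivalent to
|z<sub>X</sub>| < √10.  The F filter is applied per-SNP; the joint
F over the instrument set is computable via `compute_f_statistic` on the
summed R².  Live confounder-lookup services are out of scope; confounder
exclusion uses a static blocklist file (one variant per line) whose
semantic intent is "variants previously associated with confounders of the
exposure-outcome pair" (for the motivating application: type 2 diabetes,
lipids, adiposity, exercise, smoking, alcohol in the forward direction).

## Harmonization rules

Variants are matched by ID only (summary files in this lineage key on
rsID); position disagreements are logged, not fatal, since they usually
reflect genome-build differences.  Palindromic variants are always dropped
by default — the stricter rule — because strand cannot be inferred from
alleles; an opt-in frequency-based rescue aligns by minor-allele
concordance but refuses frequencies inside (0.42, 0.58).  Variants missing
from the outcome are dropped (no proxy search).  Indels and multi-allelic
records are rejected at read time.

## Sensitivity diagnostics

Cochran's Q uses the ratio-scale weights and the fixed-effect estimate;
p is upper-tail chi-square with k−1 df.  MR-PRESSO follows the
residual-sum-of-squares construction: observed RSS around leave-one-out
through-origin fits, null distribution from n_sim = 1000 (default) seeded
draws of outcome betas under the no-pleiotropy model, global and per-SNP
empirical p-values with a +1/(n_sim+1) continuity correction (so p is never
exactly 0 and the per-SNP floor times the Bonferroni factor stays below the
0.05 flag threshold for k ≤ ~50).  Outliers are flagged on
Bonferroni-corrected per-SNP p < 0.05, the corrected estimate is IVW on the
unflagged set, and a warning fires when more than half the instruments are
flagged (the method assumes ≥ 50% valid).  The distortion test is
deliberately omitted.  The pipeline purges flagged outliers and re-runs all
estimators, recording `presso_outlier` exclusions.

## FDR families and tiers

BH step-up adjustment supports a declared family size m larger than the
number of p-values supplied, because a study's family is defined by design
(e.g. 34 regional tests within one measure class per direction), not by how
many rows reached the final table.  The 34-test family reproduces the three
reference adjusted values (0.0238, 0.0493, 0.0907) from raw p-values
0.0007/0.0029/0.008 at ranks 1–3 exactly, which is how the family size was
inferred; alternatives (e.g. 138) do not.  Tiers: significant iff
P_FDR < 0.1, nominal iff p < 0.05 and P_FDR ≥ 0.1, else null; IVW is the
tier-defining method, other estimators are reported for concordance.  Note
that BH adjustment is *not* exactly idempotent as a map (a second
application can raise tied tail values); the tests assert monotonicity and
dominance instead.

## Colocalization

Hypothesis sums are accumulated entirely in log space with log-sum-exp;
the distinct-causal term Σ<sub>i≠j</sub> ABF1<sub>i</sub>·ABF2<sub>j</sub>
is computed as a log-space difference and clamps to −∞ when non-positive
(single-variant regions).  Priors default to p1 = p2 = 1e-4, p12 = 1e-5.
Effect-size prior standard deviations default to 0.15 (quantitative) with
0.2 recommended on the log-odds scale for case-control traits, the
reference framework's documented defaults, exposed as flags.  Inputs are
beta/se; a fallback reconstructs (|β|, se) from (p, MAF, N, case fraction)
for files lacking standard errors — signs are lost, which is immaterial
because ABFs depend on z².  Region extraction is lead ± 500 kb inclusive on
the lead's chromosome.  Lead variants are user-supplied (typically MR
instruments); the package does not choose them.

## Synthetic-data generator

`simulate_gwas_pair` emits valid GWAS records for both studies.  Choices
and what they emulate:

- Standard errors are 1/√(2·MAF(1−MAF)·N) for standardized quantitative
  traits and additionally scaled by 1/√(φ(1−φ)) (φ = case fraction) for
  binary outcomes on the log-odds scale, so se magnitudes and their 1/√N
  scaling match real summary data.  Default sample sizes are 23,909
  (exposure) and 80,610 with φ = 0.258 (outcome), the scale of the
  motivating brain-morphometry and ALS studies.
- Exposure effects are spike-and-slab (π_causal = 0.3, slab sd 0.15) so a
  p-threshold selection stage has realistic behavior; the slab is
  half-normal, i.e. effect alleles are coded exposure-increasing.  This is
  the orientation in which a *directional* pleiotropy mean is meaningful —
  with symmetric effect coding, the Egger orientation step would cancel
  any directional component and the intercept test would have no power by
  construction.  Simulation studies that state an instrument count directly
  (e.g. "50 instruments") use π_causal = 1 so every emitted variant is an
  instrument.
- Pleiotropy modes none/balanced/directional draw α<sub>j</sub>
  independently of b<sub>j</sub> (InSIDE holds); defaults sd 0.02,
  directional mean 0.05.
- Variants sit on an LD-block position grid (10 kb within block, 1 Mb
  between blocks) with non-palindromic A/G alleles, one variant per block
  by default so clumping is exercised but ground truth stays identifiable;
  `make_ld_fixture` provides the matching block-diagonal r² reference.
- `simulate_coloc_region` draws marginal z-scores through an exchangeable
  correlation structure (z<sub>j</sub> = r<sub>j,causal</sub>·effect_z +
  correlated noise) under shared/distinct/null causal layouts; default
  effect_z = 8, 50 variants.
- `simulate_multi_exposure_study` gives each exposure disjoint instruments
  (distinct phenotypes have largely distinct association signals) and
  builds one outcome GWAS from the per-exposure causal contributions, so a
  multi-phenotype screen has a well-defined joint ground truth.

What the generator does **not** emulate: realistic human LD maps,
minor-allele-frequency spectra, polygenic infinitesimal backgrounds,
sample overlap between studies, population stratification, or winner's
curse from discovery-stage selection.  Passing tests therefore demonstrate
the correctness and calibration of the estimators under their assumed
model, not robustness to those real-data complications.

## Verified behavior (computed by the test suite and acceptance script)

Under the generator's study conditions: IVW type-I error at θ = 0 with 50
instruments stays within [0.03, 0.08] over 500 replicates; θ = 0.2 is
recovered with |bias| < 0.02 over 200 replicates; a directional pleiotropy
mean of 0.05 triggers the Egger intercept test in the large majority of 200
replicates while the slope CI keeps covering zero; MR-PRESSO flags a ratio
displaced by 10 joint-se units and its corrected estimate matches the
clean-subset IVW within 2 se; colocalization posteriors always sum to 1
within 1e-9, match a 16-configuration brute-force enumeration to 1e-10 on
3-variant regions, and cleanly separate shared (median PPH4 > 0.75) from
distinct (PPH3 > PPH4) scenarios over 100 replicates each; clumping agrees
with an exhaustive pairwise checker; identical configs and seeds reproduce
result tables byte-for-byte.

One caveat surfaced by the simulations: the rule that removes instruments
associated with the outcome at p < 0.05 censors the strongest instruments
of a genuinely causal exposure, attenuating its IVW estimate (visible in
the README example: β̂ ≈ 0.12 for θ = 0.15).  The rule is implemented as
specified because it is part of the analysis design being reproduced, but
users should be aware of this bias when effects are real and instruments
strong.

## Known limitations

- No multivariable MR, MR-RAPS, Steiger filtering, proxy-variant search,
  liftover, or PLINK/VCF parsing.
- MR-PRESSO omits the distortion test.
- Colocalization assumes at most one causal variant per trait per region
  (no SuSiE-style decomposition).
- The consistency checker brackets printed rounding by corner evaluation
  of the rounding intervals, which is exact for monotone maps but slightly
  conservative otherwise.
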