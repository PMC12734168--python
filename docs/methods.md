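# Methods

## Effect sizes

Between-groups studies use Hedges' g: the mean difference standardized by
the pooled SD with the textbook degrees-of-freedom denominator
n_t + n_c − 2, multiplied by the small-sample correction
J = 1 − 3/(4·df − 1) (equivalently 1 − 3/(4(n_t+n_c) − 9)). A variant
denominator n_t + n_c + 2 is retained behind
`pooled_sd(..., denominator="printed")` purely so sensitivity to that
(non-standard) form can be audited; it is never the default.

Pre–post cohorts use the standardized mean change: (X̄_pre − X̄_post)
divided by SD_change = √(SD²_pre + SD²_post − 2r·SD_pre·SD_post). The
correction factor for a single-group change score is applied at
df = n − 1 by default; because primary reports rarely state which df they
fed to J, the convention is a keyword (`j_convention="single_group" |
"total_n"`). When no paired correlation is available r = 0.5 is imputed,
the conventional midpoint, and is overridable per record.

Sampling variances are the standard large-sample approximations —
(n_t+n_c)/(n_t·n_c) + g²/(2(n_t+n_c)) for two arms, and
(1/n + g²/(2n))·2(1−r) for change scores. These formulas are an explicit
modelling choice of this package (many primary sources leave them
unstated), which is why they live in one function (`variance_of_g`) that
every caller shares.

Sign conventions are preserved, never harmonized silently: RCT pain
outcomes come out negative when treatment beats control (treat − control),
cohort change scores come out positive for improvement (pre − post). The
simulation recovery harness maps cohorts onto the RCT orientation by
negation, which leaves the variance unchanged since it is even in g.

## Random-effects pooling

The engine is the DerSimonian–Laird moment estimator: Cochran's Q under
fixed-effect weights 1/v_i, C = Σw − Σw²/Σw, τ² = max(0, (Q − k + 1)/C),
then random-effects weights 1/(v_i + τ²). I² = 100·(Q − df)/Q floored at
0. Confidence intervals default to μ̂ ± 1.96·se; a Knapp–Hartung interval
(t quantile on k − 1 df with the robust variance) is available as
`ci_method="hksj"`. τ² can alternatively be estimated by REML, implemented
as a bounded scalar maximization of the restricted log-likelihood with
`scipy.optimize.minimize_scalar`; the boundary fit is accurate to the
optimizer tolerance (~1e-5), which is why homogeneous-data tests compare
to zero at 1e-4.

Degenerate inputs: pooling k = 1 study is allowed with τ² = 0 and a
warning; k = 0 and non-positive variances are rejected. Subgroups are
pooled fully independently — each route gets its own τ², matching the
practice of reporting distinct heterogeneity per route.

The shipped study table contains seven studies (three intramuscular RCTs,
one intradiscal RCT, three intradiscal pre–post cohorts). Because the
intradiscal subgroup has been reported both as "three cohort studies" and
as all four intradiscal rows, the inclusion rule is a configuration switch
(`intradiscal_inclusion="cohort_only" | "all"`, default `cohort_only`).
Two published summary results for this table — the overall pooled
g = −2.42 (CI [−3.384, −1.456], τ² = 6.176) and the intradiscal subgroup
g = 2.87 (τ² = 4.92) — cannot be reconstructed from the table under any
standard variance formula (our reconstruction gives an overall μ̂ ≈ +1.01,
although Q ≈ 861 and τ² ≈ 6.18 agree closely with the published 860.57 and
6.176). The pipeline computes its own reconstruction and writes the
`TAU2-IRREPRODUCIBLE` note to the provenance log; it never asserts
equality with those two printed values. The intramuscular subgroup *is*
reproducible: DL pooling of the three RCTs gives μ̂ ≈ −1.54 against the
published −1.55.

## Harm risk

Pure probability arithmetic: odds p/(1−p), RR = p_e/p_b, OR as a ratio of
exact odds, ARI = p_e − p_b, NNH = 1/ARI. Two mutually inconsistent
published risk pairs are shipped as named presets rather than reconciled:

- `combined-risk` — 9.52% (intradiscal) vs 1.45% (intramuscular): gives
  RR 6.57, OR 7.15, odds 0.1052/0.0147.
- `severe-complication` — 0.10% intradiscal severe-complication rate with
  the intramuscular baseline back-calculated as 0.10%/6.57 ≈ 0.0152%
  (trials of the intramuscular route report no severe events, so the
  back-calculated figure is an upper bound, not an observation). This
  yields ARI = 0.085%, NNH ≈ 1180 (nearest ten), and ≈10 vs ≈1.5 expected
  cases per 10,000 procedures. Note the literal division 0.10/0.015 is
  6.67; the headline 6.57 is only consistent with the back-calculated
  baseline, a rounding quirk the reports flag as `RISK-RATIO-ROUNDING`.

A protective exposure (ARI < 0) is reported as an NNT with an explicit
`protective` flag rather than an error. Reports round RR/OR to 2 dp, odds
to 4 dp and the NNH headline to the nearest 10; raw values are always kept
in the JSON output. CTCAE bands (G1–G2 for intramuscular, G3–G5 for
intradiscal) ride along as labels only — no qualitative matrix scoring is
attempted.

## Gas diffusion

Fick's first law gives the flux J = −D·dC/dx; the second law gives the
order-of-magnitude transit time t ≈ x²/(2D) for a 1-D path (x²/(6D)
available as a sensitivity variant). Shipped coefficients at 37 °C, in
10⁻⁹ m²/s: O₂ 2.0, O₃ 1.2 (an alternative 1.1 is also quoted in the
literature and shipped as `GAS_O3_ALTERNATE`; 1.2 is the default because
it reproduces the published 3.75 worked value), CO 2.1, NO 3.3, N₂ 2.0.
The default path is 3 mm (paravertebral space to disc surface); the
arrival table spans the quoted 2–3 mm range.

A standing unit discrepancy is documented rather than resolved: at 3 mm,
x²/(2D) for O₂ is 2,250 s (= 37.5 min), yet the worked examples are
printed with a "min" label (2.25 min). The implementation computes SI
seconds only and reports the mantissa in units of 10³ s; every report
carries the `EQ12-UNITS` code. The scan-schedule consistency check (scans
at 0, 3, 7, 12 min) is plain interval arithmetic with a configurable pad —
with a zero pad a scan exactly at the arrival time counts as "after".

## Image metrics

SNR = mean(signal ROI)/sd(noise ROI) and CNR = |mean(A) − mean(B)|/sd(noise)
with ROIs as explicit boolean-mask inputs (sample SD, ddof = 1). SSIM uses
scikit-image with the standard constants (K1 = 0.01, K2 = 0.03, window 7³)
and a data range taken from the joint min/max unless configured.
Preprocessing z-scores the volume and applies a 3×3×3 median filter; it is
deterministic but not idempotent. Gas segmentation thresholds below a
configurable HU cut (default −400; air ≈ −1000, fat ≈ −100) and counts
26-connected components; the reported volume is voxel count × spacing³.
Rigid registration is out of scope — phantoms are generated pre-aligned.
Published before/after SNR/CNR/SSIM tables from real patient scans cannot
be reproduced without the (undeposited) images; this module's contract is
the metric definitions, verified on constructed volumes and phantoms.

## Synthetic data

The trial generator simulates the exact data-generating process the
random-effects model assumes: study effects θ_i ~ N(μ, τ²), normal
outcomes. RCTs draw two arms with a standardized difference of θ_i
(control mean 5, SD 2 on a VAS-like 0–10 scale — cosmetic, since g is
scale-free); cohorts draw correlated pre/post pairs (pre mean 7, SD 2,
r = 0.5 by default, matching the imputation convention) with a mean change
of −θ_i change-SD units, so beneficial treatment yields positive pre–post
g. Per-arm sizes default to 20–60, the range spanned by the shipped study
table's arms. RCTs are labelled intramuscular and cohorts intradiscal,
mirroring the design mix of the published evidence base.

Randomness contract: every stream is `default_rng([root_seed, STREAM_ID,
*indices])` with fixed per-component stream ids, so generators are
individually reproducible and adding one never shifts another's draws.

What the generator does **not** emulate: publication bias, outcome-scale
floor/ceiling effects, dropout, non-normal outcomes, within-study
reporting error, or anatomically realistic CT content (the phantom is a
concentric disc/annulus/muscle geometry with additive Gaussian noise, no
beam hardening or scanner physics). Passing recovery tests therefore
demonstrate estimator correctness under the model's own assumptions, not
robustness to real-data pathologies.

Validation harness sizes (chosen to keep the default suite in seconds):
parameter recovery uses 200 replicate meta-analyses of k = 20 studies at
μ = −1, τ² = 0.2; the empirical-variance check uses 500 replicate RCTs at
n = 50 per arm; the law-of-large-numbers check uses arms of 10⁵; binomial
coherence uses 10⁶ procedures. Known small-sample behaviour: the τ²
truncation at zero inflates its mean estimate when the true τ² is 0, which
the recovery summary reports but does not assert away.

## Pipeline

`run_full_analysis` is deterministic given config and inputs (no
timestamps in outputs; reruns are byte-identical). Any stage failure
removes partial outputs and re-raises with the stage name. The provenance
log records every estimator switch plus the standing discrepancy notes
(`EQ12-UNITS`, `TAU2-IRREPRODUCIBLE`, `RISK-RATIO-ROUNDING`), so every
number in the bundle can be traced to a config choice.
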