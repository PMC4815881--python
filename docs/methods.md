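# Methods

## The risk model

The package models polygenic susceptibility to testicular germ cell
tumour (TGCT) with a log-normal relative-risk (RR) distribution. An
individual's polygenic risk score is the weighted allele count

    PRS = Σₙ βₙ xₙ,   βₙ = ln(ORₙ),   xₙ ∈ {0, 1, 2},

over a panel of susceptibility SNPs (the packaged panel holds the 19
known TGCT loci; the 12q21 locus carries two reported signals, of which
only the primary, rs995030, enters the score). Under Hardy–Weinberg
equilibrium and independence of loci, the population variance of the
score is

    σ² = Σₙ 2 pₙ (1 − pₙ) βₙ²  = 0.7404 for the packaged panel,

and log-RR is taken as N(μ, σ²), i.e. RR ~ LN(μ, σ²). Setting
μ = −σ²/2 normalises the population mean RR to 1. Under multiplicative
risk, the score distribution among future cases is the population
density reweighted by e^x, which for a normal population is the same
normal shifted right by σ²: cases ~ N(μ + σ², σ²).

Per-allele odds ratios are treated as per-allele relative risks — the
standard rare-disease approximation; TGCT lifetime risk is 0.5%.

Tail summaries come in two conventions. `midpoint_percentile` reports
the RR at the midpoint centile of the stratum (99.5th for the top 1%),
versus the population median: exp(z_q σ). This gives the headline 9.2
(top 1%) and 4.1 (top 10%). `truncated_mean` is the statistically exact
stratum mean, exp(σ²/2)·Φ(σ − z)/f over the median, giving 10.3 for the
top 1%; it always dominates the midpoint value because the log-normal
is right-skewed. Absolute lifetime risk is RR × 0.5%, capped at 1.

## Discrimination

With the case/population pair of normals, a risk threshold t gives
FPR = 1 − Φ((t−μ)/σ) and TPR = 1 − Φ((t−μ−σ²)/σ). The ROC curve is
evaluated on 1201 evenly spaced thresholds over μ ± 3σ² (three
*variances*, deliberately), and the area is integrated by the trapezoid
rule **over the computed points only**, without extrapolating to the
(0,0)/(1,1) corners. That truncated area is 0.7235 → 0.72; the exact
binormal area Φ(σ/√2) = 0.7286 and is exposed as `method="analytic"`
(a corner-completed trapezoid converges to it). The truncated variant is
retained because it is the convention behind the published 0.72.

The familial benchmark converts a sibling recurrence risk λ_s = 8 into
an "all predisposition" log-normal model via σ² = 2 ln λ (multiplicative
polygenic risk with siblings sharing half the log-risk variance). The
fraction of cases above the population q-quantile is 1 − Φ(z_q − σ),
giving 97.9% → 98% above the median and 88.4% above the 80th centile
for the familial model.

## Screening cascades

Screening is simulated as deterministic expected-value arithmetic on a
population of 10⁶ men — no sampling — with baseline assumptions:
lifetime risk 0.5%, mortality 2.8% of cases, chemotherapy in 65% of
cases, biopsy sensitivity 97.5% (complication rate 2.8%), semen CIS
assay sensitivity 67% / specificity 98%, uptake 100%, follow-up of the
top 1% of the PRS whose average RR is 9.2. The tail RR enters at
printed precision (9.2, and 19.2 in the improved scenario) rather than
being recomputed, because the cascade arithmetic is defined on the
rounded value (10 000 × 0.5% × 9.2 × 97.5% = 448.5 → 449; the unrounded
model RR would give 447).

* **Two-stage**: biopsy the whole top stratum. Detected =
  460 × 0.975 = 448.5 → 449; deaths prevented 13; chemotherapy avoided
  292; stage-1 PPV 4.5%; 9.0% of population cases found; NPV 99.5%.
* **Three-stage**: semen assay first; only assay-positives are biopsied.
  Semen TP = 460 × 0.67 = 308.2, FP = 9540 × 0.02 = 190.8, biopsies
  499.0. Two modes:
  * `coherent` (default for new analyses) applies each sensitivity
    once: detected = TP × 0.975 = 300.5, and PPV × biopsies = detected
    exactly.
  * `paper_replication` chains off the *rounded* two-stage count,
    applying biopsy sensitivity twice — detected = 449 × 0.67 × 0.975 =
    293.3 → 293, deaths 8, chemotherapy avoided 191 — and reports the
    non-invasive PPV as the rounded detection count over the biopsies,
    293/499.0 = 58.7%. This is the unique chain consistent with all
    four published three-stage figures; whether the double application
    of biopsy sensitivity was intentional cannot be determined, which
    is why it is isolated in a clearly named mode.
* **Improved**: coherent mode with tail RR 19.2 (absolute lifetime risk
  9.6% in the stratum) and semen sensitivity 80%: PPV = 748.8/948.8 =
  78.9% → 79%.

Counts are rounded half away from zero at presentation only; reports
carry the unrounded values alongside. Preventative orchidectomy is
assumed fully curative (residual risk 0.0, kept as a parameter), and
CIS is assumed universally present in future cases.

## Heritability chain

The "improved" variance is reconstructed, not published: common-SNP
heritability h² = 0.37 on the liability scale converts to a sibling
recurrence risk under the liability-threshold model (siblings share
ρ = h²/2 of a standard-normal liability; disease above T = Φ⁻¹(1−K),
K = 0.005), λ_s = P(both sibs above T)/K² = 3.81; then σ² = 2 ln λ_s =
2.68, halved for a 50%-discovered-loci scenario to 1.34, implying a
top-1% midpoint RR of 19.7 — near, but not equal to, the published
19.2. The screening module therefore consumes 19.2 as a fixed input and
this chain is documented as a plausibility reconstruction only. The
bivariate tail is evaluated with the bivariate-normal CDF and is
cross-checked in the tests against direct 2-D quadrature and a 10⁷-draw
Monte Carlo.

## Synthetic cohorts and the exact finite-panel distribution

`cohort_sim` draws genotype dosages per locus as Binomial(2, p) —
Hardy–Weinberg, no linkage disequilibrium, no missingness — and assigns
case status with probability baseline × e^{PRS}/mean(e^{PRS}), i.e.
multiplicative risk calibrated so the cohort-average risk equals the
0.5% baseline exactly in expectation. All draws are seed-deterministic.

The module also computes the *exact* distribution of the finite panel
score by successive convolution of the per-locus three-point
distributions on a 0.001-wide grid (masses split linearly between
flanking bins, preserving the mean exactly; masses below 1e-15 pruned
with renormalisation), plus the exact case-reweighted distribution,
rank AUC and case-capture fractions derived from it.

This pair of oracles quantifies how far the real 19-locus score is from
its log-normal idealisation, with consequences the tests assert:

* the exact case shift is 0.673 rather than σ² = 0.740, and the exact
  case-to-population mean-RR ratio is 1.85 rather than e^{σ²} = 2.10 —
  the score is left-skewed because its strongest locus (rs995030,
  OR 2.55) has risk-allele frequency 0.80;
* the exact rank AUC is 0.7184, about 0.010 below the binormal 0.7285;
  simulated cohorts converge on the exact value, not the binormal one;
* central quantiles (20th–80th) agree with the normal approximation
  within 0.05 on the log scale, but the 1st/99th deviate by up to 0.15,
  so closed-form tail summaries (9.2 midpoint, 10.3 truncated mean for
  the top centile) run above the exact finite-panel value of 8.0;
* the exact distribution puts 48.3% / 79.7% of cases in the top 20% /
  50% of genetic risk, against 50.8% / 80.5% from the closed form — the
  discrete route thus reproduces the otherwise-unexplained published
  48% figure, while 77% is not recovered by either route and is left
  documented rather than targeted.

What the simulator does **not** emulate: linkage disequilibrium,
genotyping error, non-genetic risk factors (e.g. cryptorchidism),
age structure, competing mortality, and family correlation. Passing
tests therefore validate the internal mathematics and the quality of
the log-normal approximation for this panel — not the clinical
performance of screening in a real population.

## Numerical choices and problem sizes

* Standard-normal and bivariate-normal quantities via scipy to full
  double precision; no table lookups.
* ROC grid: 1201 thresholds by default (odd, so μ is a grid point);
  AUC integration via the trapezoid rule on FPR-sorted points.
* Convolution grid: bin width 0.001 on the log scale (variance error
  below 3e-6 for the packaged panel).
* Rounding for display: half away from zero, applied after snapping to
  9 decimals so expected-value chains landing exactly on .5 (448.5) are
  not dropped by binary representation error.
* Test cohorts: 500 000 individuals (≈2 500 cases at the 0.5%
  baseline) for the empirical oracles, 10⁶ draws for the log-normal
  truncated-mean check, 10⁷ for the bivariate-tail Monte Carlo; fixed
  seeds throughout.

## Known limitations

The two-/three-stage replication arithmetic is faithful to a published
chain that is itself internally inconsistent (biopsy sensitivity applied
twice); `coherent` mode is the defensible default. The heritability →
19.2 chain is a reconstruction. The model treats ORs as RRs, assumes
locus independence, and ignores non-genetic risk — all reasonable for a
rare disease and this panel, but untested against individual-level data.
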