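# Methods

## Kinetic model

All rate estimation assumes first-order mRNA decay with constant
synthesis over the labeling window: dA/dt = α − λA. The pre-existing
pool (transcribed before label addition) then decays as
PE(t) = A₀·e^(−λt) and the nascent pool accumulates as
NS(t) = α(1 − e^(−λt))/λ. Inverting the two observables at t = t_L
gives the estimators

    t½ = −t_L·ln2 / ln(P/A₀),        λ = ln2/t½,
    α  = N·λ / (1 − e^(−λ·t_L)).

The model does not require steady state: a change in total abundance
during the window is absorbed exactly, because P and N are measured
separately. What it does require is that λ and α are constant over the
window — rates that change within 1–2 h are aliased into effective
averages.

Numerical choices: for λ·t_L < 1e−8 the synthesis-rate expression is
0/0 at machine precision and is replaced by its limit N/t_L (the two
branches agree to first order in λ·t_L; continuity at the switch is
tested). Estimates are undefined, with an explicit per-gene
`drop_reason`, when P ≥ A₀ (no measurable decay within the window —
half-life too long to resolve), when P, A₀ or N are non-positive, or
(optionally) when the replicate coefficient of variation of the total
exceeds a threshold; the CV cutoff is an artifact decision, off by
default and exposed in configuration, since no published criterion
exists for the "highly variable expression" drop-out class.

## Fraction normalization

Equal RNA mass is hybridized for the total (T), newly synthesized (NS)
and pre-existing (PE) samples, so the separated-fraction intensities are
on arbitrary per-chip scales. For each gene the true fractions satisfy
Cp·PE/T + Cn·NS/T = 1; regressing PE/T on NS/T across genes (ordinary
least squares, one fit per temperature on replicate-mean intensities)
yields Cp = 1/intercept and Cn = −slope/intercept. Fits with
intercept ≤ 0 or slope ≥ 0 have no physical interpretation and raise.

Genes with a ratio outside [0, 3] are excluded from the fit as gross
outliers (they arise from near-zero totals); the bound is configurable.
Unweighted least squares is used deliberately — no errors-in-variables
correction — matching the plain regression procedure the method is
built on. A per-replicate fitting mode is intentionally not the default:
rates are computed from replicate-mean intensities throughout.

## Significance calling and classification

Differential total-RNA abundance between temperatures is scored with a
moderated d-statistic in the SAM style: d = (mean_warm − mean_cool)/(s + s₀)
on log2(intensity + 8), s the pooled standard error, computed over all
total-RNA samples (both timepoints, all replicates — six columns per
temperature in the standard design). The offset 8 stabilizes low
intensities and is configurable. s₀ is chosen among the percentiles
0, 5, …, 100 of the s distribution to minimize the coefficient of
variation of the median-absolute-deviation of d across s-quintiles —
a simplified, self-contained version of the variance-decoupling search;
replicating the original SAM software's exact heuristic is a non-goal.
The null distribution comes from balanced column relabelings (all
distinct relabelings when few, otherwise a seeded sample); the
significance cut Δ is the smallest observed |d| at which the estimated
FDR (median permuted exceedance / observed exceedance, strict
inequality) drops to the target. With this definition the gene at the
smallest |d| can never itself be flagged, so "FDR = 1 flags everything"
holds only approximately; the tested property is monotonicity (a looser
target never flags fewer genes).

Abundance fold-change is the ratio of geometric-mean total intensity
(warm/cool, all total samples, no offset so that the steady-state
identity below is exact). Classes use ≥ semantics: WG (warm gene) at
fold ≥ 2, CG at fold ≤ 0.5, UG otherwise; an up/down/unchanged split at
1.5-fold additionally requires permutation significance.

Q10 of a rate is (rate_warm/rate_cool)^(10/ΔT); decay Q10 is computed
on λ, equivalently t½_cool/t½_warm.

## Synthetic-data generator

The generator emulates a two-temperature (17/27 °C) whole-seedling
labeling experiment read out on expression arrays: 4 sample types ×
2 temperatures × 3 biological replicates, labeling 2 h at 17 °C and 1 h
at 27 °C. Per gene it draws, log-normally: the cool synthesis rate
(mean 73 units/h, log-sd 1.0), the cool half-life (mean 4.96 h, log-sd
0.75), and synthesis/decay Q10s (medians 3.40 and 2.80; log-sd set from
the mean/median ratios 3.57/3.40 and 3.29/2.80). Means and medians
follow the reported cohort statistics of such experiments; the log-sd of
the cool rates is not reported anywhere and was fixed once at values
giving the multi-decade spread seen in genome-wide rate histograms.
Warm rates follow from the Q10s; each temperature starts at steady
state A₀ = α/λ (an optional log-normal fold-shift moves A₀ off steady
state to exercise the non-steady-state estimator paths).

Measurement artifacts, in order: optional symmetric cross-contamination
between the labeled fractions ((1−c)X + cY); the equal-loading rescale —
every NS and PE chip column is scaled to a common target sum, which is
exactly the distortion the regression correction must undo; and i.i.d.
multiplicative log-normal noise per measurement (default sd 0.1,
approximating the proportional error of array intensities at moderate
signal). The loading target defaults to the summed total-RNA signal at
that temperature: equal RNA mass per chip implies comparable overall
chip signal, and this keeps the PE/T, NS/T ratios in their physical
range. It can be set to any positive constant. Detection calls are all
present by default; an option flags the lowest-intensity quantile
absent to exercise the call filter.

What the generator does not emulate: probe-level effects,
cross-hybridization, between-array normalization artifacts, intensity-
dependent (rather than proportional) noise, and biological covariation
between rates and transcript features. Passing recovery tests therefore
demonstrate correctness of the estimators under the stated error model,
not robustness to every failure mode of real arrays.

### Resolvability

With multiplicative noise of sd σ on three replicates, the standard
error of ln(P̄/Ā₀) is ≈ σ·√(2/3), while the signal is
|ln(P/A₀)| = t_L·ln2/t½. Half-life precision therefore degrades in
proportion to t½/t_L: at σ = 0.1, ±20% recovery is reliable for
half-lives up to roughly the labeling time and becomes impossible for
t½ ≫ t_L — the same window limitation that produces the `ratio_ge_1`
drop-outs in real data. The recovery tests assert high accuracy inside
the resolvable window and monotone degradation beyond it, rather than a
flat recovery rate over all half-lives.

## Feature association

Q10-binned feature frequencies use eight unit-width half-open bins over
(0, 8) by default; genes outside the range are excluded from bins and
counted separately, and empty bins report no percentage rather than 0%.
Group comparisons use the two-sided Mann–Whitney U test — exact
enumeration when n_a·n_b ≤ 10,000 and there are no ties, otherwise the
tie-corrected normal approximation — chosen because Q10 distributions
are log-normal-like and skewed; a t-test on log Q10 would also be
defensible. Promoter motifs are IUPAC consensus patterns scanned in
upstream sequence on both strands by default; the shipped defaults
(G-box CACGTG, evening element AAATATCT, morning element CCACAC, ABRE
ACGTGKC, heat-shock element halves TTCNNGAA/GAANNTTC, CArG box
CCWWWWWWGG) are standard consensi, not measured binding sites, and are
overridable in configuration. Rate–feature relationships use Spearman
rank correlation with large-sample p-values.

## Problem sizes

Recovery and calibration analyses run on simulated cohorts of 500–2,000
genes with 200–500 permutations — large enough that the binomial error
of estimated proportions is well below the asserted margins, and the
acceptance computation completes in seconds.

## Known limitations

- Two timepoints identify a single (α, λ) pair per gene and temperature;
  no goodness-of-fit test of the first-order assumption is possible.
- The correction-factor regression assumes one global Cp, Cn per
  temperature; gene-specific capture efficiency (e.g. U-content-dependent
  labeling) would bias rates and is not modeled.
- The permutation test's granularity is limited by the number of
  distinct balanced relabelings (924 for 6 + 6 columns), bounding how
  finely the FDR can be estimated.
- Inputs are assumed already between-array normalized; no quantile or
  scale normalization is applied.
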