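# Methods

`hypoxikit` implements the quantitative core of a preclinical hypoxia-biomarker
workflow for xenograft tumour models of head and neck squamous cell carcinoma
(HNSCC): transcriptomic hypoxia scoring, tumour-growth-rate estimation for
drug-efficacy readout, and viral (HPV) RNA detection. This note records the
models, the parameters that matter, and the design choices made where the
procedure was genuinely open.

## Expression normalisation and filtering

Bulk RNA-seq counts (genes × samples) are filtered and normalised before any
scoring:

* **Low-count filter.** A gene is retained iff its maximum count across
  samples is ≥ 10 *and* its total count is ≥ 15. Filtering precedes
  normalisation so the all-positive reference set for RLE is non-empty. The
  filter is idempotent.
* **RLE (relative log expression) normalisation**, the median-of-ratios
  method. The per-gene reference is the geometric mean across samples,
  restricted to genes with strictly positive counts in every sample; each
  sample's size factor is the median of its count/reference ratios over those
  genes; normalised values are counts divided by the size factor. Genes with
  a zero anywhere are excluded from size-factor estimation but retained and
  normalised. Size factors are reported as raw medians, **not** rescaled to
  geometric mean 1: every downstream score is invariant to a common rescaling
  of all factors, so the convention is immaterial but is kept fixed and
  documented. Consequence: scaling one sample's counts by *c* multiplies the
  *ratio* of its size factor to any other sample's by *c* (the absolute
  factors all shift by a common c^(1/n), because the geometric-mean reference
  moves too).

## Signature scoring

A hypoxia gene signature is an ordered set of gene identifiers supplied as a
plain-text list; signatures are external inputs (the published signature
lists are not bundled). Scoring is relative to a **reference population** —
by default all xenograft (CDX + PDX) samples in the annotations, where some
hypoxia is expected; the reference is configurable (e.g. to exclude
non-HNSCC models). At least two reference samples are required (sample sd,
n−1 denominator).

Per sample, three scores:

* **z-sum score**: per-gene z = (value − ref mean)/ref sd, clipped to
  [−3, 3]; genes with zero reference sd score z = 0 with a warning; the
  clipped z values are summed over signature genes present in the matrix.
  Bounded by ±3n.
* **Simple signature score**: +1 per signature gene above the reference
  median in that sample, −1 per gene below; exact ties contribute 0. Integer
  in [−n, n].
* **Hypoxia Score**: the fraction of signature genes (present in the
  matrix) strictly above the reference median — the unique affine rescaling
  of the simple score onto [0, 1] (all-below ↦ 0, all-above ↦ 1). Genes
  missing from the matrix are dropped with a warning and excluded from the
  denominator.

Scores are computed per individual sample; replicate aggregation (per-model
mean ± SEM per signature, and the cross-signature mean of per-model means)
is a separate step. A single replicate reports SEM 0 with a flag.

All three scores are monotone in the expression of any signature gene, the
z-sum saturates once a gene passes the clamp, and all are invariant to a
common rescaling of size factors.

## Tumour growth kinetics

Calliper measurements convert to volume by the ellipsoid formula
V = π/6 · width · length² (width the shorter axis; swapped with a warning
otherwise). Days are relative to treatment start (day 0).

The growth model is the Gompertz curve in the W0-parameterisation:

    W(t) = A · exp( ln(W0/A) · exp(−(e·Ku/A)·t) )

with W0 the volume at day 0, A the asymptote (mm³) and Ku the maximum
absolute growth rate (mm³·day⁻¹) — the slope at the inflection W = A/e. The
curve is used strictly as a smoother; fitted parameters are not interpreted.

Procedure per animal:

1. **W0** by ordinary least squares of volume on day over all observations
   in the closed window [−7, +5] days, evaluated at day 0; a non-positive
   intercept falls back to the observation nearest day 0 (warned). Even on
   noiseless data this linear step carries a small (~2%) smoothing bias in
   the downstream mean rate, because the true curve is convex over the
   window; with W0 fixed at its true value the fit and rate recovery are
   exact to optimiser precision.
2. **(Ku, A)** by nonlinear least squares with W0 fixed, on all observations
   from day −7 through the last measurement ≤ day 21 plus the first one
   beyond (anchoring). Multi-start trust-region optimisation (A₀ at 2×, 5×,
   10× the maximum observed volume; Ku₀ from the steepest observed two-point
   slope), A bounded below at 0.9 × max(W0, max volume) and above at
   1000 × max(W0, max volume). The upper bound stabilises the
   exponential-growth ridge — for data far below the asymptote, (Ku, A) →
   ∞ at fixed ratio — and at 1000× the data range the bounded curve is
   exponential to within measurement precision. Ku is unconstrained in sign
   so shrinking tumours are representable. Non-convergence is flagged and
   refused downstream, never silently accepted.
3. **Daily rates** by central finite difference on the fitted curve,
   rate(t) = [W(t+h) − W(t−h)]/2h with h = 0.5 day (configurable), at
   t = 1, 2, …, 21. If the fitted curve decreases anywhere over the window,
   days with fitted volume < 10 mm³ are excluded; the **mean daily growth
   rate** averages the retained days. Fully-excluded animals are flagged
   degenerate.
4. **Normalisation**: within each model, mean daily rates are divided by the
   median control rate (control median ↦ 1.0); skipped with a warning when
   the control median is non-positive.
5. **Group comparison**: per model, two-sided unpaired Student t-test of
   treated vs control mean daily rates (≥ 2 animals per arm), Holm-Sidak
   adjustment across the family of models, significance at adjusted
   p < 0.005 by default. A zero pooled variance (identical constant arms)
   is handled explicitly: p = 1 for equal means, p = 0 otherwise.

Scaling all volumes by c scales W0, A, Ku and the mean daily rate by c and
leaves normalised rates unchanged. The maximum of the rate curve equals Ku
only when the inflection falls inside the day window; slow-growing
parameterisations (e.g. Ku = 20, W0 = 250, A = 2000 put the inflection near
day 27) legitimately undershoot it in-window.

## Viral RNA detection

Alignments of non-human reads to viral genomes (SAM/BAM via pysam, or a TSV
of per-read intervals; 0-based half-open) are summarised per genome into a
mapped-read count and a per-base pileup depth vector (difference-array
construction, O(reads + genome)). A genome is called **positive** iff
mapped reads ≥ 400 *and* the longest strictly contiguous run of positions
at depth ≥ 5 spans ≥ 200 bp. The two conditions are independent: the read
count is genome-wide, the run comes from the pileup. No gap tolerance;
a single base below depth 5 breaks a run. Ties in run length break leftmost.
Reports use 1-based inclusive coordinates. Adding reads can never flip a
positive call negative.

## Biomarker variability and agreement

Coefficient of variation is 100·sd/mean (sample sd), undefined for < 2
values or zero mean. Pearson correlations between biomarkers (hypoxia
scores, stained hypoxic fraction, proliferation counts, growth rates) are
computed on per-model means, unweighted, with models missing either value
dropped pairwise and a minimum of 3 complete pairs.

## Synthetic data

The generators emulate the study's data shapes with known ground truth;
every output is fully determined by an integer seed.

* **Expression**: 20 models × 3 replicate tumours by default (the study's
  panel scale), 1000 genes, a 15-gene signature (the size of the smallest
  published HNSCC signature), baseline means log-normal (median 100,
  log-sd 1), negative-binomial counts with dispersion φ = 0.2 (variance
  μ + φμ², a typical bulk RNA-seq scale), library factors log-normal
  (log-sd 0.3). Planted hypoxia levels h are evenly spaced on [0, 1] across
  models; signature-gene means are multiplied by 2^(β·h), β = 1 by default
  (a 2-fold shift at full hypoxia). What it does **not** emulate: correlated
  gene-gene structure, stromal/mouse-read contamination, batch effects, or
  signature genes that respond to proliferation rather than hypoxia — so a
  passing recovery test shows the scoring arithmetic ranks a planted
  monotone signal correctly, not that any published signature measures
  hypoxia in real tumours.
* **Growth**: trajectories from the same Gompertz form the fitter assumes
  (W0 = 250 mm³, Ku = 40 mm³·day⁻¹, A = 2000 mm³ — the treatment-start and
  endpoint volumes of the study design), measured every 2–3 days from day
  −7 to 21, multiplicative log-normal noise at CV 10%; the treated arm
  multiplies Ku by 0.4 (a 60% growth-rate reduction). Ground truth is the
  analytic mean derivative over days 1..21. Because generator and fitter
  share the model family, recovery tests measure estimation error under
  noise, not model misspecification.
* **Rate studies**: for operating characteristics of the group comparison,
  animal-level mean daily rates are drawn directly (base 40 mm³·day⁻¹,
  15% relative Gaussian noise, 8 per arm, 20 models of which 5 carry the
  60% reduction), which isolates the testing stage from curve fitting.
* **Viral reads**: uniform read placement in a chosen region of an
  HPV16-length genome (7904 bp); the expected call is computed by a naive
  per-base counting loop kept independent of the pileup implementation.

## Problem sizes and numerics

Test and acceptance runs use 50 tumours per growth condition, 200 repeats
of the 20-model comparison study, and 100 repeats of the null scoring
design — sizes at which the measured quantities (median recovery error,
false-flag rate, detection rate, null Spearman) are stable to well inside
the margins asserted. Optimiser tolerances are 1e-12 (xtol/ftol/gtol) with
max 2000 function evaluations per start; finite differences use h = 0.5 day;
count reconstruction from normalised values is exact to 1e-9 relative.

## Known limitations

* The Gompertz W0-form here is one of several W0-parameterisations in the
  growth-modelling literature; it is isolated in `gompertz_volume` so an
  alternative is a one-line change.
* The W0 regression bias (above) is inherent to fixing W0 from a linear
  fit; it is small relative to calliper noise but systematic.
* The HPV caller consumes whatever alignments it is given; mapping-quality
  or duplicate filters applied upstream change the counts it sees.
* Signature scoring assumes the count matrix and signature share a gene-id
  namespace; no identifier mapping is performed.
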