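# Methods

## Turnover kinetics

**Model.** Cells growing exponentially in ¹⁴N minimal medium are switched
to ¹⁵N medium at `t0`. Pre-existing protein decays as
`N14(t) = N0 · exp(−k_deg (t − t0))`. Assuming a steady-state proteome
during exponential growth, `N0 = N14(t) + N15(t)` and `k_deg = k_syn`,
which gives `1 + 1/R = exp(k_syn (t − t0))` for the measured light/heavy
ratio `R`, i.e. `Y = ln(1 + 1/R)` is linear in time with slope `k_syn` and
the half-life of the pre-existing pool is `T = ln2 / k_syn`. The
steady-state assumption is taken as given; dilution-by-growth corrections
and non-steady-state degradation models are out of scope.

**Fitting.** `fit_ksyn` runs OLS of `Y` on `t` with a free intercept by
default: the idealized model passes through the origin, but a labeling lag
(medium exchange, amino-acid pool turnover) shifts real series, and the
slope — the only quantity used downstream — is unbiased either way. The
strict through-origin form is available (`through_origin=True`,
`--through-origin`). Fit significance is the two-sided P of the Pearson
correlation (t-distributed, n−2 df). Proteins need ≥3 timepoints; series
failing that are withheld with a reason rather than raised, so cohort runs
don't die on sparse proteins.

**Censoring.** Estimates with `T > 500` min or `P > 0.05` are flagged
censored: a slope that flat cannot be distinguished from zero over a
≤90-min labeling course. Cohort summaries count censored proteins in the
">500 min" bin; the mean half-life is computed over uncensored proteins by
default (`mean_includes_censored=True` enters them at the cap instead —
appropriate when nearly everything is censored, as under oxidative
stress). Distribution comparisons use the two-sample Kolmogorov–Smirnov
test with censored values at the cap.

**Proteome trend.** `proteome_trend` aggregates the per-timepoint ratio by
the median (robust to the heavy right tail of ratio noise); the mean is a
switch away. Note that R(t) is hyperbolic, so even noiseless aggregate
ratios have |Pearson r| noticeably below 1 on a linear axis.

## Dual-isotope peptide chemistry

Digestion is fully tryptic (cleave after K/R), suppressed before proline
by default — the standard trypsin convention, exposed as a switch — with up
to 2 missed cleavages. Compositions come from the standard residue table
plus water, with carbamidomethyl-C fixed and oxidized-M variable
(≤2 oxidations per peptide when expanding the database). Element masses
are NIST monoisotopic values (via pyteomics). Under the ¹⁵N label every
nitrogen is counted at the heavy mass, so
`mass(N15) − mass(N14) = n_N × 0.9970349 Da` holds exactly per
composition. Chemically the carbamidomethyl nitrogen is introduced by
unlabeled iodoacetamide during sample prep and would stay ¹⁴N; treating it
as labeled keeps the whole-composition invariant exact and shifts affected
peptides by at most one Δm_N — a known approximation.

**Envelopes.** Isotope envelopes are computed by convolving per-element
isotopologue distributions on the integer mass-number grid while tracking
first moments, so each aggregated peak carries an exact centroid mass.
Nitrogen uses its natural distribution under ¹⁴N and the two-point
`{¹⁴N: 1−q, ¹⁵N: q}` distribution under ¹⁵N with incorporation `q = 0.99`
by default (¹⁵N media label >99% of nitrogen in practice; configurable).
Peaks below a relative intensity of 1e-3 are truncated (bounds peak lists
while keeping >99.9% of area); bins below 1e-12 of the base peak are
dropped unconditionally because their 0/0 centroids are numerically
meaningless. Pre-truncation intensities sum to 1 within 1e-9.

**Database and quantification.** The dual-label database indexes every
(peptide, missed-cleavage, oxidation, label) form by monoisotopic mass and
answers ±ppm range queries by bisection; candidate lookup converts an
observed precursor m/z at charge z to neutral mass and applies a 10 ppm
default tolerance, both labels eligible. Charges 1–4 are considered where
a range is needed. MS1 quantification integrates matched envelope-peak
intensities (±10 ppm per peak, mirroring the precursor tolerance) across
scans in the retention window for each label and reports
`R = area(¹⁴N)/area(¹⁵N)`; summed area is the default granularity with
per-scan apex as an option, since either reading of "peak area" is
defensible. A heavy area at/below floor yields a missing result with a
reason, never an exception — downstream kinetics drops missing ratios
rather than imputing. Fragment-ion scoring and decoy-FDR filtering are
deliberately not implemented; the pipeline quantifies at MS1 level and
accepts an identification table as input.

## tRNA-seq

**Alignment.** Reads are aligned by a unit-cost semi-global dynamic
program: the read must be explained end to end, both reference ends are
free, and reference positions annotated as modified match any read base at
zero cost. Semi-global rather than fully local because errors are what is
counted — a local alignment could silently clip its way under any error
budget — and because the 3′ offset must be measured against the reference
terminus. Acceptance requires ≤3 errors (mismatches + indels) and ≥25 nt.
Among co-optimal alignment ends the one closest to the reference 3′ end is
reported (deterministic truncation offsets). Multi-mapping resolution is
winner-takes-all: fewest errors, then longest aligned length, then
lexicographically smallest species id; fractional assignment is out of
scope. The batch kernel (numba) abandons a reference once its running row
minimum exceeds the error budget or the current best; this never changes
which reference wins or its error count. The single-pair `align_read` runs
the full exact DP.

**Normalization and profiles.** Per-species counts are divided by the
spike-in count; fold decreases are per-species ratios of normalized
abundances, summarized both as their arithmetic mean and as the
ratio-of-totals (the two differ under heterogeneous fold changes, so both
are reported). Species with zero stress counts are flagged and excluded
from the mean. Truncation profiles are fractions of a species' accepted
reads at 3′ offsets 0–10, with the offset-3 fraction reported separately
for tandem-CCACCA species (loss of one CCA unit). Replicate concordance is
Pearson/Spearman over spike-normalized counts of shared species.

## Growth and qPCR statistics

OD from transmitted intensity follows Beer–Lambert:
`OD = log10(I_blank / I)`; the device's validated linear range is
OD 0–0.45. Growth-rate constants are OLS slopes of `ln(OD)` vs time inside
an explicit window; an automatic window (sliding, maximal R², near-ties
broken toward the steepest slope so a flat arrest segment never wins) is a
convenience only. Negative rates indicate net death. Rate comparisons use
the two-tailed Student t-test (equal variance; Welch behind a flag), with
degenerate zero-variance input reported as NaN with a reason.

ΔCT is defined as `CT(reference) − CT(target)` — larger ΔCT means more
target — and `ΔΔCT = ΔCT(stress) − ΔCT(normal)`, fold change `2^ΔΔCT`, so
negative ΔΔCT means the target decreased. This spike-in-minus-target
convention is stated prominently because much of the qPCR literature uses
the opposite sign. PCR efficiency correction is out of scope.

## Synthetic data: what it does and does not emulate

* **Turnover**: per-protein `k_syn` log-normal(ln 0.007, 0.3) per minute —
  centering half-lives near 100 min, the *E. coli* scale — observed at
  15/30/60/90 min; ratio noise is multiplicative log-normal with CV 0.1 by
  default (ratios are positive and MS ratio error scales with the ratio);
  oxidative stress multiplies every rate by 0.05, pushing nearly all
  half-lives past the 500-min cap. Ratios that diverge (k→0) are capped at
  1e6. Not emulated: missing ratios from failed identifications,
  protein-specific timepoint dropout, correlated (batch) noise.
* **MS1**: both envelopes of each peptide pair under a Gaussian elution
  profile, the light one scaled by the prescribed ratio, plus additive
  intensity noise and random noise peaks. Retention-time drift, charge
  envelope interference and detector saturation are not modeled, so ratio
  recovery here measures integration correctness, not chromatographic
  robustness.
* **tRNA reads**: 47 synthetic reference species (random bodies — real
  tRNAs share structural motifs and are harder to tell apart), CCA ends,
  three tandem-CCACCA species, ~8 modified positions each; the spike-in is
  the study-style T7 transcript ending in CCA, ≥3 edits from every
  reference (checked at generation). Reads are 3′-anchored full-prefix
  copies truncated per a configurable pmf, substituted at 1% per base and
  15% at modified positions (RT misreading; the elevated rate is a free
  parameter since no measured value exists). Default relative abundances
  are log-normal across species (σ = 0.8), fixed per spec seed and shared
  across conditions and replicates — without between-species variance,
  replicate correlations would be meaningless. The spike-in occupies 10%
  of the library by default; its true share is protocol-dependent and is a
  free parameter. Not emulated: 5′ coverage variation, ligation bias,
  isodecoder homology, tRNA charging.
* **Growth / CT**: piecewise-exponential OD with an optional arrest
  window and additive noise; CT tables via `CT = CT0 − log2(quantity)`
  with Gaussian cycle noise.

Passing recovery tests on these generators demonstrates the estimators
invert the assumed data-generating processes at realistic noise; it does
not certify performance on real libraries, where reference homology and
systematic biases dominate.

## Problem sizes and numerical choices

Recovery runs use 500-protein cohorts, 10⁵-read libraries per condition,
1000 random alignment pairs and 100 random peptides — large enough that
binomial/Poisson sampling error sits well inside the asserted tolerances,
small enough for interactive runs. Sub-seeds for each stage derive
deterministically from the master seed. The aligner's independent
cross-check is edlib in infix mode with masked positions encoded as
wildcard equalities; it verifies error counts but plays no role in the
pipeline itself.
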