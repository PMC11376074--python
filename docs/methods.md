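# Methods

## Scope and design

The package turns a set of inspection-based and spreadsheet-level
computations used in reservoir geomicrobiology into explicit, testable
algorithms.  Its five modules cover chromatogram-based biodegradation
scoring, targeted alkyl-CoM metabolite screening, molecular
abundance/activity quantification, evidence integration with a
transformed ridge regression, and a synthetic-data generator that
produces every pipeline input with known ground truth.  The generator is
first-class code: every claim the test suite makes about the analysis
stages is made against data whose truth labels are known by
construction.

## Biodegradation scoring (0–4)

A crude oil's total ion chromatogram (TIC) is graded on the ordinal
scale 0–4.  The published criteria are visual — a "straight" TIC versus
a "slight" or "significant" UCM hump, alkane/isoprenoid concentration
comparisons — so the implementation operationalizes them in four steps:

1. **Peak detection** (`detect_peaks`).  Local maxima on a lightly
   Gaussian-smoothed trace (σ = 2 grid points), kept when their
   prominence exceeds `min_snr` (default 8) times the post-smoothing
   noise level (noise estimated robustly from first differences via the
   MAD) and `min_prominence_fraction` (default 0.05) of the tallest
   peak, and when their FWHM is below `max_fwhm` (default 1.0 min) —
   anything broader is unresolved structure, not a chromatographic peak.
   Peak *height* is prominence, i.e. measured above the local baseline,
   which is how an analyst reads peak sizes off a trace riding on a UCM
   hump; it also makes the ratios below insensitive to the hump.
2. **Series assignment** (`assign_series`).  A linear carbon-number →
   retention-time calibration (default 2.0 min per carbon, nC10 at
   10 min) with pristane eluting 0.55 min after nC17 and phytane
   0.55 min after nC18, the standard apolar-column elution order.  Each
   peak takes the nearest calibrated identity within `rt_tolerance`
   (0.3 min); ties on one identity go to the tallest peak.  Diagnostic
   ratios are height-based by default (area mode available) and
   undefined when a member is missing.
3. **UCM index** (`compute_ucm_index`).  The unresolved fraction of the
   trace: a rolling-minimum envelope (window 2.0 min, wide enough to
   reach baseline between resolved peaks) of the smoothed trace,
   integrated and divided by the total area above zero.  Smoothing
   precedes clipping so zero-mean baseline noise does not rectify into a
   spurious offset; σ = 5 points tempers the downward bias of a rolling
   minimum under noise.
4. **Rule evaluation** (`score_degradation`).  First match in the order
   4 → 0: (4) no n-alkane assignments and UCM ≥ `ucm_significant`;
   (2/3) UCM ≥ `ucm_significant`, both ratios < 1, Pr+Ph at least
   `dominance_threshold` times the median surviving n-alkane — degree 3
   when at most `residual_count_threshold` n-alkanes survive, else 2;
   (1) UCM ≥ `ucm_slight` and both ratios > 1; (0) any remaining profile
   with n-alkanes; otherwise the trace is flagged *indeterminate* rather
   than forced into the scale.

The published scale quantifies neither "slight" versus "significant"
UCM, nor how "significantly higher" Pr/Ph must be, nor where moderate
degradation splits into 2 versus 3 (the source treats them jointly).
The package fixes these as conventions, all exposed as parameters:
`ucm_slight` = 0.10 and `ucm_significant` = 0.35 of trace area,
`dominance_threshold` = 2.0, `residual_count_threshold` = 5.  Scores are
invariant under positive rescaling of the trace, and exactly one label
(or indeterminate) is produced for every valid input.

## Alkyl-CoM MRM screening

Product-ion m/z values follow the generalized empirical formula
`12.00055·n + 1.00837·(2n+1) + 79.9`, reported at one decimal; the
per-atom constants are calibrated on authentic hexadecyl- and
eicosyl-CoM standards and absorb instrument calibration, hence the
slight difference from IUPAC monoisotopic masses.  The three product
ions per homolog are HSO₃⁻ (80.9), C₂H₃SO₃⁻ (106.9) and CnH₂n₊₁SO₃⁻.
Only product-ion formulas are published, so the precursor for each MRM
pair is defined here as the intact molecular anion CnH₂n₊₁–S–C₂H₄–SO₃⁻:
carbon·(n+2) + hydrogen·(2n+5) + monoisotopic S (31.97207) + 79.9.

Matching uses `mz_tolerance` = 0.3 Da on both coordinates — covering
rounding at the stated one-decimal machine accuracy.  A homolog is
*detected* iff its precursor → HSO₃⁻ pair matches with intensity
strictly greater than `intensity_threshold` = 2000; matches to the other
two product ions are recorded as corroboration but are neither necessary
nor sufficient.  Two readings of the threshold are conceivable (absolute
counts of the bisulfite pair, or a ratio to a reference channel); the
absolute-count reading is implemented, with the threshold a parameter.
Variety is the number of distinct detected chain lengths, bounded by 25
for the full C4–C28 series, and is monotone: adding observed rows never
lowers it, raising the threshold never raises it.

## Abundance and activity

* **qPCR** — `fit_standard_curve` fits Cq = slope·log10(copies) +
  intercept by least squares over ≥ 3 dilution points (efficiency
  `10^(−1/slope) − 1`; a nonnegative slope is flagged invalid).
  `quantify_copies` inverts the curve and converts to copies per gram
  with explicit metadata (dilution factor, input mass, extract fraction
  per reaction), since reported per-gram values leave the conversion
  arithmetic to the analyst.  Below-quantification samples are reported
  as missing, never zero, keeping log10 summaries well defined.
* **Amplicon fraction** — target features (exact-match cluster
  representatives, abstracted as a boolean flag on the feature table)
  summed and divided by the per-sample total; zero-total samples are
  missing, not 0.
* **MAG activity** — per-MAG read counts divided by genome length, then
  normalized per sample; fractions partition to 1 wherever any read
  mapped.
* **FPKM** — `counts · 10⁹ / (length_bp · total_mapped)`; invariant
  under joint scaling of counts and totals, linear in counts.

## Evidence integration and regression

The three per-sample booleans (16S detected, *acrA* transcribed,
alkyl-CoM detected) map onto four described co-occurrence groups:
(T,T,T) → 1, (T,F,T) → 2, (F,F,T) → 3, (F,F,F) → 4; the remaining four
combinations are labelled "other" rather than forced into a group.
`detection_summary` reports detected/total fractions per occupied
stratum (degradation degree, oilfield); empty strata are absent, never
0/0, and the stratum-weighted average equals the pooled proportion.

The regression uses X = ln(FPKM + 1) (pseudocount 1 because zero FPKM
occurs and must stay finite) and Y = logit((d + ½)/5), a symmetric,
monotone mapping of the integer degrees 0–4 into finite logits — the
scale of the published fitted form is not otherwise specified.
`fit_ridge` minimizes ‖Y − Xβ − b‖² + λ‖β‖² with the penalty on the
slopes only; λ = 0 reproduces ordinary least squares exactly (rank
deficiency then raises with a pointer to λ > 0).  The derivation
convention of a zero intercept (centered data) is available via
`fit_intercept=False`; the default estimates the intercept, matching a
fitted form with a constant term.  When no λ is given, the CLI selects
it by efficient leave-one-out cross-validation over a log-spaced grid
(10⁻⁴…10², 25 points), since no published value exists.

## Synthetic data: what it emulates

`simulate_chromatogram` inverts the scoring rules.  Gaussian peaks
(σ = 0.1 min) sit on the linear retention calibration over nC10–nC35
with a bell-shaped abundance envelope (1.0 mid-series, 0.5 at the
edges); Pr and Ph have fixed height 0.4.  The degree presets attenuate
the n-alkane series (factors 1.0, 0.65, 0.18, 0.18-with-three-survivors,
0) and set a target UCM area fraction (0, 0.25, 0.60, 0.85, 0.90 —
chosen inside the slight/significant bands with margin).  The UCM is one
wide Gaussian (σ = 9 min, centred at 33 min); its amplitude is solved in
closed form from the target fraction using Gaussian areas, so the
noise-free round trip through the scorer is exact by construction for
every degree.  Degrees 2 and 3 share one attenuation level and differ
only in surviving-alkane count, giving distinguishable fixtures for a
jointly described pair.

`simulate_mrm_run` emits the three theoretical ion pairs per planted
homolog plus decoys placed ≥ 1 Da (both coordinates) from every
theoretical value, so no decoy can match below that tolerance.

`simulate_expression` draws the log-FPKM covariates from normals
(mean 2.5, sd 1.0) truncated below at ln(pseudocount), so
FPKM = exp(X) − 1 is nonnegative and the log transform round-trips
exactly; the latent response Y = β₁X₁ + β₂X₂ + c + ε (defaults
β = (0.01, 0.86), c = 0.49, σ = 0.1, n = 200) maps to integer degrees by
the inverse logit-degree transform.  Both the quantized degrees and the
latent response are returned: coefficient-recovery checks use the latent
response (quantization to five logit grid points adds distortion much
larger than σ, biasing coefficients toward zero), while a separate check
confirms the quantized pipeline still ranks the archaeal term first.
The log-normal-like FPKM distribution is a modelling convention — field
data do not constrain it.

`simulate_study` couples everything to one ground truth per sample:
degrees drawn from a mix defaulting to (0.08, 0.20, 0.25, 0.22, 0.25)
(predominantly degraded, as reservoir surveys find); per-degree
alkyl-CoM detectability (0.64, 0.33, 0.50, 1.00, 0.78); 16S positivity
0.85 with *acrA* transcription in 60% of positives; 16S copies
10^(2+1.5d) g⁻¹ (lognormal scatter, clipped to 10¹–10¹⁰), amplicon
fractions and MAG transcript shares rising with degree on a logistic
scale, and qPCR Cq values produced by the forward standard-curve model
(slope −3.3219, intercept 38, dilution 10, 0.5 g input, 1% extract per
reaction) that the quantification stage inverts.

What the generator does **not** emulate: raw mass spectra and isotope
patterns, retention-time drift and co-elution beyond the single UCM
hump, compositional correlations between markers beyond their shared
dependence on degree, read-level sequence data, and batch effects.
Passing round trips therefore demonstrate the internal consistency and
correctness of the computations under the stated statistical structure,
not performance on real instrument output.

## Numerical choices and problem sizes

Seeds thread through `numpy.random.default_rng` everywhere; identical
inputs and seeds give byte-identical outputs.  Round-trip suites use 20
noise-free and 20 noisy chromatograms per degree (noise sd at 5% of the
tallest peak), 100 replicate expression studies of n = 200 for the
coefficient-ordering check, and studies of 30–50 samples for
integration tests — sizes at which every statistical check is stable
while the whole suite runs in seconds.

## Known limitations

* The 0–4 thresholds (`ucm_slight`, `ucm_significant`, dominance,
  residual count) are conventions standing in for unquantified published
  language; cross-study comparability requires agreeing on them.
* The precursor-ion definition for MRM pairs is a structural inference
  from the metabolite's formula, not a published calibration.
* The ridge stage treats the ordinal degree as a continuous response
  after the logit transform; an ordinal link model would be the stricter
  alternative.
* Indeterminate chromatograms (no peaks, no significant UCM) are
  excluded from regression rows rather than imputed.
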