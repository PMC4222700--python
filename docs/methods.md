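# Methods

`sgscreen` re-implements, end to end, the quantitative machinery of a
genome-wide microscopy screen for stress-granule (SG) formation defects in
budding yeast: synthetic micrograph generation with ground truth, per-cell
punctum counting, the normalized SG phenotype score with hit calling,
cross-stress profiling, hypergeometric functional enrichment,
low-complexity-region (LCR) detection, and the statistics of the two
downstream assays (forward mutability and qPCR).  This note records the
models, the parameters that matter, and the design choices that were
genuinely open.

## Synthetic micrographs (`sgscreen.simulate`)

A field emulates fixed yeast cells expressing a fluorescent SG marker
(Pab1-RFP-like).  Cells are soft-edged disks — radius uniform on
`cell_radius_px` (default 6–9 px), placed by rejection sampling with a 3-px
moat so no two masks touch and soft edges of neighbours remain resolvable —
filled with a constant cytoplasmic intensity (default 1200 a.u. over a
400 a.u. background) and blurred with a 1-px Gaussian.  Yeast cells are
near-circular, and a disk is the simplest shape that still exercises
segmentation; buds, septa and vacuoles are deliberately not modelled.  Each
cell is SG-positive with probability `sg_positive_fraction` (default 0.35,
the wild-type level under 400 mM 2-deoxyglucose); positive cells carry
1–2 diffraction-limited puncta, rendered as Gaussian spots (σ = 1.5 px,
amplitude 4000 a.u.) placed uniformly within 0.6× the cell radius so they
always lie inside the mask.  Gaussian read noise (default sd 20 a.u.) is
always added; Poisson shot noise is optional so tests can run noiseless
oracles.  Output is clipped to unsigned 16-bit, the assumed camera depth.

All randomness comes from per-purpose child streams of one
`SeedSequence(seed)` in a documented spawn order (placement, flags, puncta,
second channel, noise), so any single stage — e.g. the per-cell
SG-positive Bernoulli draws — can be replayed independently and used as an
oracle.

Screen designs default to the full screen's sampling geometry: 25 replicate
images of 80 cells per strain/condition, with per-field positive counts
drawn binomially from each strain's true fraction.  Field images are
rendered lazily so calibration-scale designs (thousands of cells) cost only
the binomial draws.

The optional second channel (Hsp104-GFP-like aggregates) places each focus
near an SG punctum (within 2 px) with probability `coloc_prob`, default 0 —
the two aggregate types are spatially separated — and otherwise at least
2.5 px away from every SG punctum, so the planted colocalization
probability is recoverable without a chance-proximity correction.

Sequence, qPCR and plating generators plant known truth in the same way:
LCR tracts at recorded 1-based coordinates inside near-uniform
(maximal-complexity) filler; Ct values following
Ct = Ct₀ − log(q)/log(E) + N(0, σ) with a 1/2…1/500 dilution ladder for the
standard curve; colony counts Poisson-distributed around
frequency × cells plated.

## Image quantification (`sgscreen.imaging`)

The original screen's analysis ran in a proprietary package whose feature
set and thresholds are unpublished, so this module is calibrated against
the synthetic oracle, not against original images.

Segmentation: Gaussian smoothing (σ = 2 px), global Otsu threshold (or a
fixed value), connected-component labelling, area filter (30–2000 px), and
an optional distance-transform watershed to split touching cells.  The Otsu
threshold is floored at median + 5×MAD-σ of the smoothed image so a field
with no cells (unimodal histogram) yields zero labels rather than noise
specks.  Cells touching the border are kept by default (no exclusion rule
is assumed); a flag drops them.

Punctum detection: single-scale Laplacian-of-Gaussian (σ = 1.5 px, the
expected spot width), the standard choice for diffraction-limited foci.
Local maxima of the scale-normalized response are screened at 0.2×
`min_contrast` (a matched Gaussian spot of contrast A responds at ≈A/2),
then each peak must exceed `min_contrast` (default 200 a.u.) above the
median intensity of its parent cell — a per-cell reference, so bright cells
do not inflate calls.  Contrast is measured on a punctum-scale smoothed
copy of the image: smoothing at σ = 1.5 px suppresses pixel noise ≈5× while
attenuating a matched spot only 2×, which is what keeps the recovered
fraction within 0.02 of truth at read noise of one tenth of the punctum
amplitude (`min_contrast` should sit several σ above the smoothed noise
floor; at noise sd 400 the tests use 600).  Peaks closer than
`min_separation_px` (default 3 px) are merged to the brighter one; puncta
outside any cell are discarded; positions are intensity-weighted centroids
(0-based row/col).

A cell is SG-positive when it carries at least `min_puncta` (default 1)
accepted SG-channel puncta.  The per-image output is
f = n_positive / n_cells; an image with zero cells yields a flagged
undefined fraction, never a division by zero.

## Phenotype score and hit rule (`sgscreen.screen`)

S = (f_mut − f_wt)/f_wt × 100 (percent): 0 at wild-type level, −100 when
the mutant forms no SGs, +100 at twice the wild-type fraction.  S is
undefined when the wild type formed no SGs.  Per strain and condition, S is
computed from the replicate means; its standard error by first-order
(delta-method) propagation of the two means' standard errors; significance
by a two-sided two-sample Student's t-test on per-image fractions.  The
t-test is an assumption — the screen's significance procedure is not
named — justified because per-image fractions of ~80 cells are near-normal
and Student's t is the test used elsewhere in the same study.  Identical
constant samples are defined to give P = 1.  No multiple-testing correction
is applied at the screen stage (correction enters only in enrichment).

A strain is a hit when |S| strictly exceeds 20% *and* P < 0.05 (both
strict).  Under the default sampling geometry the SE of S is ≈4.3%, so the
|S| > 20 arm dominates the joint rule's null behaviour and the joint
false-positive rate sits far below the t-test's nominal 0.05; the
calibration tests therefore check the significance arm against
0.05 ± 3 SE and the joint rule against that bound from below.
Confirmation-rate tables bin |S| in half-open 10-point bins ([30, 40) …
[90, 100], the top bin closed), with rates rounded to integer percent; the
open/closed convention is an assumption, stated here because it is not
derivable from the source table.  Wild-type reference is the measurement
matched to the same condition; a pooled reference is a caller choice.

## Enrichment (`sgscreen.enrichment`)

Exact hypergeometric upper tail P(X ≥ k) for k query hits among n query
genes, with K of N background genes annotated (default background size
4691, the screened collection plus slow growers).  Only terms with k ≥ 1
are tested and the family size m counts exactly those — this matters
because m scales the Bonferroni-corrected P.  Bonferroni is the default
(the cited term-finder's style of correction); Benjamini–Hochberg is
available.  Annotations are flat term→gene pairs; ontology propagation must
happen upstream.  Printed P-values from the original analysis are
order-of-magnitude context only: per-term K and the exact correction are
not recoverable, so the tests assert strong significance of a plausible
reconstruction, not the printed digits.

## Sequence features (`sgscreen.lcr`)

The original LCR counts were produced by a published complexity method
whose parameters are not recoverable; this package implements a SEG-style
sliding-window Shannon-entropy detector (window 12, threshold 2.2 bits,
minimum length 12, merge gap 2, all config-exposed) and treats the
published proteome-scale totals as input-count worked examples for the
summary arithmetic, not as detector-output oracles.  Entropy is in bits
over the 20-letter alphabet, X excluded from counts.  Residues covered by
any low-entropy window are marked, runs merged across gaps ≤ 2, and merged
spans are greedily trimmed from whichever end lowers entropy more until
the reported segment itself satisfies the threshold — so segment entropy ≤
threshold is an invariant, not a tendency.  Coordinates are 1-based
inclusive.  Disorder is not predicted: long IDR segments are maximal runs
(≥ 30 residues) above a score threshold (0.5) in supplied per-residue
tracks.

## Assay statistics (`sgscreen.assays`)

Mutation frequency = (resistant colonies × selective dilution) / (viable
colonies × non-selective dilution) — invariant to rescaling counts and
dilutions describing the same culture.  Stress induction is the
replicate-paired fold over the untreated control, averaged with SE
(mean ± SE of three independent determinations is the reporting
convention); mutant-vs-wild-type comparison is Student's t on log folds —
the log stabilizes ratio variance, and the original test is unnamed, so
this is recorded as an assumption.  Fluctuation analysis
(Luria–Delbrück rates) is out of scope: the readout is a frequency.

qPCR uses efficiency-corrected (Pfaffl-style) quantification,
ratio = E_t^(ΔCt_t)/E_r^(ΔCt_r) with ΔCt = calibrator − sample, because
standard curves are fitted per primer pair (E = 10^(−1/slope) from Ct vs
log10 dilution); with E = 2 for both genes this reduces to plain ΔΔCt, so
both conventions are covered.  Time courses are scaled to percent of the
wild-type maximum (largest replicate-mean level across timepoints) and
compared per timepoint by Student's t with stars at p < 0.05 / p < 0.01.

## What the synthetic data does and does not show

The generator reproduces the sampling geometry (binomial per-field counts,
25 × 80 replication), realistic intensity scales, and planted truth for
every detector.  It does not model real morphology (buds, vacuoles,
out-of-focus light), spatial plate effects, uneven illumination, or
autofluorescence — so passing tests demonstrate the correctness and
calibration of the algorithms under the stated noise model, not
performance on original micrographs.  Screen-scale outcomes (the specific
hit genes, 194 hits, per-gene identities) require the original images and
are explicitly not reproduced; the pipeline's guarantees are checked as
properties (perfect punctum detection on noiseless fields, score recovery
within ±2 SE at true S ∈ {−100, −50, 0, +100}, null calibration of the hit
rule, exact hypergeometric tails, planted-tract recovery, E and fold
recovery in qPCR, fold recovery in mutability).

## Problem sizes used in the shipped analyses and tests

The `analysis/` drivers run a 9-strain × 2-condition × 8-replicate screen
of 40-cell fields (144 images, 384² px) — large enough for every hit
decision to be comfortably powered, small enough to run in about a minute.
The acceptance tests use the full 25 × 80 geometry for score recovery
(225 rendered fields) and closed-form binomial sampling for the
2000-strain null calibration.  All seeds are fixed in the drivers and
tests; the library itself takes seeds everywhere.

## Known limitations

- Segmentation and detection parameters are tuned to the synthetic
  contrast regime; real data will need recalibration (all parameters are
  dataclass fields).
- The LCR detector's operating point is not the published method's; only
  summary arithmetic on published counts is comparable.
- The watershed splitter uses a fixed 5-px peak separation and is intended
  for occasional touching pairs, not dense clumps.
- Undefined quantities (zero-cell images, zero wild-type fractions, empty
  punctum sets) are flagged (`None`/NaN/raise) rather than silently
  coerced; callers composing new analyses must respect the flags.
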