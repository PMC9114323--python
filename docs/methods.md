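# Methods

## Scope and model

`fusloc` quantifies two things a cell biologist studying nuclear retention
of RNA-binding proteins (RBPs, here FUS) needs to measure:

1. **How much nascent-transcript "binding surface" a cell offers.**
   FUS binds RNA in a length-dependent manner, so a nascent transcript's
   capacity to tether FUS in the nucleus grows with both its length and its
   expression. From a HOMER `findPeaks`-style nascent RNA-seq (Bru-Seq)
   peak table, each peak's read count is normalized to 10 million total
   aligned reads (the *peak score*), peaks with score < 0.1 are discarded
   as noise, and each retained transcript receives

       binding_surface_score = log2(peak_score × length)

   where `length` is the span of the called peak region (the proxy for the
   actively transcribed transcript length). Distributions of the score are
   compared between conditions (e.g. control vs. disease iPSCs) with the
   Mann–Whitney U test, optionally restricted to a CLIP-defined set of
   RBP-bound target genes.

2. **Where a protein or poly(A+) RNA sits within each cell.** From a
   multi-channel image with whole-cell and nucleus label masks, per-cell
   integrated densities (sum of pixel intensities over an ROI, i.e. mean ×
   area) are background-adjusted and combined into a cytoplasmic/nuclear
   ratio `C/N = (ID_whole − ID_nuc) / ID_nuc`, a DAPI-normalized total
   (corrects focal-plane bias), and a nuclear poly(A+) concentration
   (DAPI-adjusted nuclear intensity per nuclear pixel). Paired per-cell
   ratios of two channels can be correlated (Pearson, t-distribution
   p-value on n−2 df); two conditions are compared by rank-sum, more than
   two by Kruskal–Wallis followed by Dunn's pairwise z-tests.

## Conventions and numerical choices

- **Coordinates.** Peak tables are read as 1-based inclusive (the HOMER
  dialect) and stored 0-based half-open, so `length = end − start`.
  Records with inverted coordinates are rejected and counted. The read
  count column is selectable (`count_column`), because the dialect does
  not fix which column holds the per-peak count.
- **Filter boundary.** "Scores smaller than 0.1 are discarded" is taken
  literally: a score of exactly 0.1 is retained (`>=` comparison).
  Zero-read peaks are removed before scoring since their binding surface
  score is undefined (log of zero); they could never pass the filter.
- **Logarithm base** is 2, and only 2.
- **Percent reduction** is `100 × (mean_ctrl − mean_other) / mean_ctrl`,
  with the control group as the reference denominator.
- **Multiple peaks per gene** are scored independently (the unit of
  analysis is the called peak); `aggregate_by_gene` (sum of scores, max
  length) is available but off the default path.
- **Rank-sum test.** Midranks for ties; exact enumeration p-value when
  n₁+n₂ ≤ 12 and the pooled sample is tie-free, otherwise the normal
  approximation with continuity and tie correction (scipy's
  implementation; the test suite checks it against a from-scratch
  enumeration of all rank assignments). Two-sided by default. No
  multiple-testing correction across figure-level comparisons; Dunn's
  pairwise p-values are Bonferroni-adjusted by default (configurable).
- **Background adjustment** is `ID − background_mean × area`, with the
  background mean measured on a user-supplied staining-free ROI,
  independently per channel. Negative adjusted densities are non-physical
  and are clamped to zero with a per-cell flag. Background adjustment is
  applied before DAPI normalization (a switch exposes the alternative
  order). The DAPI integrated density uses the nuclear ROI, since DAPI is
  nuclear.
- **Cell in/exclusion.** Cells whose whole-cell mask touches the image
  border are excluded (partial cytoplasm would bias the ratio). Cells with
  non-positive adjusted nuclear density have an undefined ratio and are
  excluded from downstream ratio statistics.
- **Segmentation is out of scope**: label masks are inputs. The
  `threshold_nucleus_mask` helper (midpoint threshold + connected
  components) is for clean synthetic DAPI channels only.

## Synthetic data: what it emulates and what it does not

The generators provide ground truth for every stage; no external data are
needed.

**Peak tables** (`simulate_peak_pair`). Transcript lengths and expression
are log-normal in log10 units (defaults: length 10^N(3.5, 0.6) bases,
expression 10^N(2, 1) reads), spanning the several orders of magnitude
seen in real nascent-transcript tables; these defaults are not fitted to
any particular dataset. The affected condition's expression is multiplied
by `1 − effect_fraction` (default 0.10, the scale of the reduction the
pipeline is meant to detect); measurement noise is multiplicative
log-normal (`noise_log_sd`, default 0.02 log10 ≈ 5% CV) — Poisson counts
are available via `count_model="poisson"` when count realism matters.
Total depth defaults to 10^8 aligned reads, the order of magnitude of real
Bru-Seq tag directories. A configurable fraction of genes (default 0.3) is
designated the RBP-target set.

Two sampling designs are exposed:

- `paired=True` (default): both conditions share each transcript's
  expression base — a matched-transcript design. This is the right mode
  for *effect recovery*: the ratio of mean peak scores estimates
  `1 − effect_fraction` tightly (the test suite checks 10% ± 2 pp at
  n = 2000, and |bias| < 2 pp over 100 replicates).
- `paired=False`: each condition draws lengths and expression
  independently from the same distributions, emulating independently
  called peak tables. This is the regime in which the two samples are
  genuinely i.i.d., and hence the right mode for checking the rank-sum
  test's *null calibration* (rejection rate at α = 0.05 within
  [0.03, 0.07] over 500 replicates, checked at n = 200 transcripts per
  condition). Under the paired design with small noise the unpaired U
  statistic is almost deterministic (both samples ride the same base
  draws), making the test extremely conservative rather than miscalibrated
  — a property worth knowing when interpreting rank-sum p-values on
  matched peak tables generally.

What the generator does **not** emulate: gene-length/expression
correlation, chromosomal structure, overlapping or strand-ambiguous peaks,
depth differences between samples, and peak-calling artifacts. Passing
tests therefore demonstrate the correctness of the scoring and comparison
arithmetic under the stated generative model, not robustness to
peak-calling noise in real data.

**Cell images** (`simulate_cell_image`). Disk-shaped cells (radius 12 px)
with concentric nuclei (radius 6 px) on a default 512×512 field; the
nuclear channel intensity is uniform (default 100 AU) and the cytoplasmic
intensity is solved per cell so that the cytoplasmic-to-nuclear
integrated-density ratio equals `true_cn_ratio` exactly on the rendered
pixel masks before noise. A uniform background offset and Gaussian noise
(clipped at 0) are then added, and a staining-free corner square is
reserved as the background ROI. Cell placement is rejection sampling with
a 10,000-attempt budget (an explicit error, never a hang, when the field
is too crowded). Real micrographs differ in every optical respect — PSF
blur, uneven illumination, autofluorescence, touching cells, 3D structure
— so recovery tests validate the measurement arithmetic, not segmentation
or optics.

**Paired ratios** (`simulate_ratio_pairs`). Bivariate normal pairs with
population correlation `r_target` mapped through `exp(0.4·z)` to keep
ratios positive. The exp transform attenuates the Pearson correlation of
the ratios slightly for 0 < |r| < 1; |r_target| = 1 is exactly degenerate.

## Problem sizes

Simulation-based checks use n = 2000 transcripts for effect recovery
(matching the scale at which a ~10% multiplicative effect is estimated to
within ±2 pp), 500 replicates × 200 transcripts for null calibration, and
50 cells for image recovery — sizes chosen so the full suite exercises
every stage in seconds while keeping Monte-Carlo error well inside the
asserted tolerances.

## Known limitations and documented discrepancies

- The source protocol's description of peak selection contains an internal
  inconsistency (a read-count cutoff of "> 1 million" alongside the
  normalized-score cutoff of 0.1, whose quoted percentage is also off by
  two orders of magnitude). The normalized-score rule — discard peak
  scores < 0.1 per 10 million aligned reads — is what is implemented.
- The protocol's background-adjustment sentence, read literally, subtracts
  the staining integrated density *from* background × area, which would
  negate the signal; the standard orientation (signal minus background) is
  implemented.
- Whether the two replicate lines per condition were pooled before peak
  counting is not specified upstream; each peak file is treated as one
  sample and pooling is left to the caller.
- Gene-identifier matching for target subsetting is exact and
  case-sensitive; no alias resolution is attempted.
- Headline dataset-scale numbers (tens of thousands of retained peaks)
  require the original sequencing data and external alignment/peak-calling
  tools; this package starts from peak tables.
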