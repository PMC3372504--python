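# Methods

## Coordinates, anchors and orientation

All coordinates are 0-based half-open (BED convention); GTF input is 1-based
inclusive and converted on read. Anchors are strand aware: the TSS of a
minus-strand gene is its highest genomic base and its EAG (end of annotated
gene) the lowest. Anchored windows are built from the anchor's *boundary*
coordinate (for a plus-strand gene the EAG boundary is its BED `end`, for a
minus-strand gene its `start`) as `[boundary − flank, boundary + flank)`,
with minus-strand rows reversed so that column index always increases in the
direction of transcription. This boundary convention makes the construction
exactly symmetric under a genome mirror plus strand flip, which the test
suite asserts bitwise.

Isolation filtering measures strand-blind gaps between transcription-unit
intervals on the same chromosome; a gene is kept when its nearest neighbour
is at least `min_distance_bp` away (default 4000, so that downstream windows
do not overlap neighbouring units). Transcript collapsing keeps the longest
isoform per gene name by default (`union` merges extents and exon sets);
names appearing on several chromosomes or strands are dropped and logged
because no single anchor exists for them.

## Coverage

Sequenced tags mark only the 5′ end of the immunoprecipitated fragment, so
each read is extended in its own orientation to 200 bp (reads already longer
keep their native length) and clipped at chromosome edges. Coverage is
accumulated as *covered base-pairs per 50-bp bin* in exact int64 arithmetic;
the reported bin value is covered bp / bin width (mean per-base fragment
depth), multiplied by 1e6/total fragments under rpm normalisation. Keeping
the integer layer makes base-pair conservation (Σ bins × width = Σ fragment
lengths) exact, lets matrix extraction at arbitrary anchors stay
order-independent (integer window sums, one division at the end), and is why
the mirror-symmetry test can demand bitwise equality. Window values at
non-bin-aligned anchors are per-base resamplings of the piecewise-constant
binned track, which is identical to fractional-overlap weighting.

The scaled ("metagene") matrix splits each gene body into `n_body_bins`
(default 100) proportional intervals with integer floor cuts, flanked by
fixed-width bins; genes shorter than `n_body_bins` bp are dropped and
logged.

## Clustering

K-means (Lloyd's algorithm, k-means++ seeding, best of 50 restarts, fixed
`random_state`) on the raw rpm rows; `k` is fixed per analysis (2 for binary
splits such as histone vs non-histone, 4 for the pause-pattern taxonomy).
No row scaling is applied by default because absolute occupancy is part of
the signal that separates highly from weakly expressed broad-pause genes;
`unit_max` and `zscore` scalings are available. Centroids are recomputed as
exact row means of the final assignment. Partition quality against known
labels uses the adjusted Rand index; the test suite cross-checks the ARI
implementation against a brute-force pair-counting enumeration.

## Pause metrics

Per-gene background is the mean and standard deviation of the gene's mock
(control IP) row; an all-zero mock row falls back to the pooled global mock
statistics and is flagged.

**Extent.** The downstream segment of the signal row is smoothed with a
3-bin centred running mean restricted to the downstream side (so low
gene-body bins do not leak across the EAG), and the extent is the end of the
*last* smoothed bin at or above `mean + 2·sd` of the background — signal is
considered lost only after its final excursion above background. On
noiseless monotone profiles this coincides with the first crossing below the
threshold; on sampled data it is robust to isolated Poisson dips, which a
first-crossing rule turns into gross under-estimates at realistic depth
(~2 fragments per 50-bp bin). Extent is 0 when no downstream bin reaches
the threshold and is implicitly capped at the flank.

**Decay length λ.** Because each 32-bp tag is extended to E = 200 bp in
read orientation and both strands are sampled, the observed track is the
underlying occupancy convolved with a ±E box. The first E bp downstream of
the EAG therefore mix gene-body and pause signal, and a naive log-linear fit
over that region overestimates λ badly for sharp (histone-like) pauses
(about two-fold in our simulations). λ is instead fit by unweighted
nonlinear least squares of the box-convolved model

    floor + [ B·max(E−d, 0) + P0·λ·(e^(−max(d−E,0)/λ) − e^(−(d+E)/λ)) ] / 2E

over bins spanning `(EAG, EAG + 2·extent]` (the doubled range decouples the
fit from noise in the extent estimate and lets post-pause bins pin the
floor). The body plateau B is measured just upstream of the EAG beyond the
transient; the nonspecific floor is a free parameter initialised from the
quietest far region of the row — it is fitted rather than taken from the
mock because after per-track rpm scaling the mock level equals the
genome-average signal, not the signal track's local background. With E = 0
the model reduces to `floor + P0·e^(−d/λ)` and is exact on noiseless data.
λ is undefined (NaN) when the extent spans fewer than 3 bins, when the
downstream profile has no decaying trend, or when the fit fails or hits its
bounds (λ outside [10 bp, 20 kb]).

**Indices.** `tss_index` = mean density in [TSS−50, TSS+300) over the body
density (body = [TSS+300, EAG−500), widened to the whole gene when that
window would be empty); `downstream_index` = mean density in (EAG, EAG+4000]
over body. A pseudocount ε = 0.01 rpm guards the denominators.

**Shape.** `none` if extent = 0; `narrow` if extent ≤ 1000 bp; `broad`
otherwise. The 1000-bp boundary sits between the histone-type positive
region (~0.1–0.3 kb) and the distances at which histone signal is
undetectable (≥1.5 kb), and below the poly(A)⁺ regime (detectable to
4–6 kb).

## Expression and nascent strandedness

Expression tables are consumed post-normalisation: replicate columns are
averaged, rows below a configurable low-intensity quantile are dropped, and
duplicate (multi-locus) gene names are removed. Top-n selection is
deterministic with lexicographic tie-breaks, making top-n nested in
top-(n+1). Per-cluster summaries report n, median, quartiles and 1.5·IQR
whisker bounds. Antisense fractions count stranded reads overlapping a
window downstream of the EAG in transcription orientation; with no
overlapping reads the fraction is undefined (NaN), never 0.

## Perturbation comparison

The two-condition comparator mirrors a ChIP-qPCR panel: per gene class,
fixed offset windows (core histone: +0.1–0.3 kb and +1.5–2 kb from the EAG;
poly(A)⁺-like: +0.5–1, +2–3 and +4–5 kb; a −50..+300 TSS window for all,
skipped for genes under 500 bp where promoter and gene end are not
separable). Region value = mean signal / max(mean mock, ε); condition
effect = treated/untreated ratio per gene with class-level bootstrap 95%
CIs (1000 seeded resamples). The comparator runs on *raw* (absolute)
coverage: qPCR %input is an absolute per-locus measurement, and per-million
scaling would fold a perturbation's global occupancy change into every
locus (under rpm, a treatment that doubles downstream occupancy on half the
genes depresses unchanged histone loci to a ratio of ~0.78 purely by
composition).

## Synthetic data

The generator is the package's test substrate and defines its study
conditions. One chromosome carries `n_genes` non-overlapping genes with
random strands; spacing 20–30 kb (every gene passes the 4-kb isolation
filter; a 0.8–1 kb mode mimics clustered histone loci, where none do), gene
lengths 1–6 kb, half core-histone-type / half poly(A)⁺-type by default.
Histone-type genes are intronless; poly(A)⁺-type genes get 1–5 exons.

Per-base intensity components (arbitrary units/bp): TSS Gaussian of
amplitude 8 centred 30 nt past the TSS with sd 150 bp (the
promoter-proximal stall at 20–50 nt); gene-body plateau 1.0; downstream
exponential pause of amplitude 6 with λ = 250 bp capped at 1 kb
(histone-type) or λ = 1500 bp capped at 8 kb (poly(A)⁺-type); uniform
background 0.05/bp (≈11% of reads, a clean IP). The resulting
signal-to-mock contrast downstream of the EAG is ≈6-fold, in line with
ChIP-qPCR enrichments over mock. 32-bp tag 5′ positions are Poisson-thinned
from the normalised intensity (dataset size ~Poisson(depth)); chip/mock
reads draw a random strand, nascent reads inherit the strand of their source
gene (sense-pure when the nascent background is off, the default). Default
depths: 200 signal, 100 mock and 100 nascent reads per gene — the mock:signal
ratio follows the ~2.4:1 ratio typical of published Pol II/mock pairs — and
the 200-gene default scenario runs the full pipeline in well under a minute
on one CPU.

The polyadenylation-inhibition condition multiplies poly(A)⁺-type pause
amplitudes by γ (default 2) and TSS amplitudes by δ (default 0.5), leaving
histone-type genes untouched, and samples the treated track at the same
per-intensity read rate (total depth scales with total occupancy mass),
modelling an absolutely calibrated measurement.

What the generator does **not** emulate: mappability and GC structure, PCR
duplicates, per-gene expression variability (amplitudes are fixed per
class), non-uniform mock background, overlapping or nested transcription
units, and sequence-level effects. Passing tests therefore demonstrate
correctness of the pipeline's arithmetic and its statistical recovery of
planted shapes under Poisson sampling — not robustness to every artefact of
real ChIP-seq libraries.

## Numerical and design choices

- Bin values are mean per-base depth, not fragment-start counts: conserves
  base-pairs exactly and makes the per-base brute-force oracle tests exact.
- Divisions happen last in every value computation so raw values match
  per-base arithmetic bit for bit.
- K-means ties between restarts resolve by scikit-learn's deterministic
  best-of-`n_init` with a fixed `random_state`; the same seed gives
  byte-identical outputs end to end (asserted on full pipeline reruns).
- Top-expressed ties break lexicographically; heatmap row order is
  cluster-major then descending row sum, a strict permutation.
- ε = 0.01 rpm pseudocount in pausing-index and mock denominators.
- Flank defaults 4000 bp (overridable to 6000 or 1000 per analysis);
  `n_body_bins` = 100 for metagene profiles; both fixed-width and scaled
  body averaging are provided since either convention is common.

## Known limitations

- Decay fits on genes whose pause dies within ~2 bins of the EAG are
  undefined; the shape call still works from the extent.
- The scaled-body matrix uses integer floor cuts, so its mirror symmetry is
  exact only when the gene length is a multiple of the bin count; the
  fixed-width TSS/EAG matrices are exactly symmetric always.
- Single-end, fixed-length extension only; no paired-end or duplicate
  handling (tags of the emulated platform are 32 bp single-end).
- The perturbation comparator assumes absolutely calibrated tracks; with
  rpm-only real data, ratios at unchanged loci shift by the global
  composition factor and need spike-in-style calibration to interpret.
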