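# Methods

`archscape` reimplements, as one tested pipeline, the bespoke computations
used in multi-scale studies of linker-histone (H1) chromatin biology in
*Arabidopsis*: nucleosome positioning from MNase-seq, occupancy summaries
over chromatin states and expression classes, spatial statistics of
chromatin density in electron micrographs, heterochromatin quantification
in stained nuclei, and FRAP recovery kinetics. Every analysis stage is
paired with a synthetic-data generator that knows its own ground truth, so
the whole chain can be validated end to end without any external download.

## Coordinates and formats

All in-memory coordinates are 0-based, half-open (BED convention). SAM
positions are converted on read; fixedStep wiggle is written 1-based, as
the format requires, and converted back on read. "Overlap" always means
half-open intersection: intervals that merely touch do not overlap. The
adapter flag of a read (whether sequencing ran through the terminal
adapter, i.e. the full nuclease-protected fragment was observed) is not
representable in standard BED; it travels as an `adapter=0|1` token in the
name field and defaults to true when absent.

## Nucleosome peak calling and NRL statistics

Reads are filtered to the mononucleosomal range 147–220 nt (both bounds
inclusive; override with `--min-len/--max-len`) and must have reached the
adapter. Reads overlapping a blacklist (e.g. residual foreign-accession
segments in an introgressed line) are removed. Read centers
(`floor((start+end)/2)`) are piled up at base-pair resolution; candidate
positions are visited in decreasing center count (ties: leftmost first),
and a candidate becomes a peak iff its boundary — the interval of the
longest read whose center sits at that position (ties: leftmost start) —
does not overlap any previously accepted peak's boundary. Accepted
boundaries are therefore mutually disjoint, which the caller asserts after
every run. There is no coverage floor by default (`--min-count 1`).

Nucleosome repeat lengths (NRLs) are distances between consecutive peak
centers on the same chromosome, pooled across chromosomes (per-chromosome
distances are retained for diagnostics), histogrammed in 10-bp bins
(`[170,180)` etc.), and grouped as short (< 160 bp), mid (160–200 bp,
boundaries in the mid group), long (> 200 bp). Two distributions are
compared by a 2×3 chi-square on the group counts (df = 2, no continuity
correction); when an expected cell drops below 5 the Freeman–Halton exact
conditional test replaces it.

A known, deliberate property of this caller: because each accepted peak
claims its longest read's footprint (≥ 147 bp), two called peaks can never
sit much closer than ~150 bp. The called-distance distribution is
therefore left-censored, and on dense, regular arrays a fraction of true
nucleosomes whose flanking neighbours were both accepted with wide
boundaries cannot be called at all. On simulated 500-kb phased arrays
(NRL 175 bp, positional jitter sd 5 bp, 20× coverage) the caller recovers
~88–89% of true dyads, each within ±10 bp (placement error sd ~1.2 bp),
and the remaining misses are exactly these geometric blocks; raising
coverage widens the longest-read boundaries and lowers recovery further.
For an irregular array (NRL 165, jitter sd 15) the censoring also shifts
the modal called-distance bin one bin above the true modal spacing and
converts skipped nucleosomes into doubled (> 200 bp) distances. Users
comparing genotypes should therefore read the short/long group frequencies
and the chi-square contrast, which remain faithful, rather than absolute
recovery.

"Fake pairs": a fully sequenced single-end fragment `[s, e)` is split into
mates `[s, s+75)+` and `[e−75, e)−` sharing a pair identifier, so tools
that insist on shifting single-end reads can be fed paired-end-like input
without altering the informative content. Reads shorter than 75 nt are
skipped and counted.

## Occupancy tracks

Each filtered read is replaced by an 80-nt interval centered on its
midpoint; bins of 10 nt accumulate base-pair overlap (exact integer
arithmetic: total mass = 80 × reads, with clipping at chromosome edges
reported). A `count` mode assigning the full 80 nt to the midpoint bin is
available behind a flag. Smoothing by a 20-nt running window is realized
as the symmetric 0.25/0.5/0.25 kernel on the 10-nt grid with reflecting
edges, which keeps constants flat and conserves mass to machine precision.
Cross-sample quantile normalization replaces each rank with the
cross-sample mean of that rank, averaging ties; after normalization the
per-sample sorted vectors coincide exactly for tie-free data (integer raw
tracks contain large tie blocks, where tie-averaging makes the sorted
vectors agree only up to those blocks — normalize after smoothing, or on
continuous tracks, when the exact identity matters).

State densities are overlap-weighted means of bin values over each
chromatin state's intervals (CS1–CS9, which must be disjoint per
chromosome); genotype contrasts are reported as Δ% = 100·(alt − ref)/ref.
Metaprofiles align elements on the TSS, element start/end, or a scaled
body (100 body bins, 500-bp real-coordinate flanks by default);
minus-strand profiles are reversed; elements whose window leaves the track
are dropped; groups (chromatin state, expression quintile) are averaged
separately. The phasing score is the lag of the maximum of the profile's
normalized autocorrelation within 120–250 bp, with the autocorrelation
value as amplitude; flat profiles have no period.

## Expression summaries

RPKM uses the column totals of the supplied count table as library sizes,
making the computation self-contained. Quintile assignment is per
genotype: genes with zero counts in *all* replicates form the `zero`
group; remaining genes are ranked by mean RPKM (ties broken by gene
identifier) and split into five groups of as-equal-as-possible size, Q5
highest. DE-table filtering thresholds a precomputed table at p < 0.05 and
linear fold change > 2 (or < 1/2); a log2 fold-change column is
auto-detected by the presence of negative values and can be forced. List
overlaps use the two-sided Fisher exact test plus the one-sided
hypergeometric enrichment tail.

## Chromatin-density spatial autocorrelation (D value)

An ROI (≥ 64×64 px; TEM default 2 nm/px) is mean-subtracted and its
non-periodic autocovariance computed by zero-padded FFT with bias
correction by the per-lag overlap counts, normalized by the variance, and
radially averaged on a 1-px radius grid. The shape parameter is defined
operationally as `D = 3 + slope` of the least-squares line on
(log r, log ACF) over 20–60 nm, dropping non-positive ACF samples and
requiring at least 5 points. A flat ACF gives D = 3; a steeper decay a
lower D. Note that per-ROI mean subtraction makes the estimator accurate
only for fields whose correlations decay to zero well inside the ROI; for
scale-free fields the subtracted spatial mean depresses the ACF tail and
biases D downward. Group dispersion of D is summarized by median, IQR and
range, and compared between groups by a two-sided Mann–Whitney test on
absolute deviations from each group's median.

## RHF and immunosignal ratios

The relative heterochromatin fraction is the chromocenter share of total
nuclear stain intensity: with supplied ROIs (the standard, manual
workflow) it is a plain ratio of sums; in auto mode chromocenters are
connected components brighter than mean + 2·SD of the nuclear intensity
(k configurable) with a minimum area filter (default 12 px ≈ 0.05 μm² at
65 nm/px confocal sampling). The measure is invariant to global intensity
scaling. Antibody quantification is the mean antibody signal over the mean
counterstain signal within the nucleus mask, optionally divided by a
reference group's mean ratio.

## FRAP

Curve tables carry bleach-ROI, whole-nucleus and background intensities
with `time_s` measured from the bleach event (pre-bleach frames at
t ≤ 0). Normalization is double: (bleach − background) /
(nucleus − background) cancels acquisition photobleaching and detector
gain, and division by the pre-bleach mean sets the pre-bleach level to 1.
Recovery is fit by nonlinear least squares with
`I(t) = I0 + A·(1 − exp(−k·t))` on post-bleach frames, multi-started at
k ∈ {0.01, 0.1, 1}/s; the mobile fraction is `A / (1 − I0)` (clipped to
[0, 1]), the halftime `ln 2 / k`. Because `time_s` is anchored at the
bleach, noiseless model data round-trip exactly, including the mobile
fraction. A two-component fit was considered and rejected as the default:
the single exponential captures the binding-dominated recovery regime
targeted here, and the early diffusional phase is not resolvable on the
default acquisition grid. Genotypes are compared by the ratio of group
mean rates with a studentized (bootstrap-t) 95% CI on the log fold (1,000
resamples over curves, delta-method standard error); at typical group
sizes (n ≈ 10) the studentized interval holds its nominal coverage where
a plain percentile interval undercovers.

## Synthetic-data generators

All generators are deterministic given their seed and emit ground truth
alongside the data; no test reads truth back out of the data.

- **Phased-array MNase reads**: dyads placed sequentially with spacing
  ~ Normal(NRL, jitter), each present with an occupancy probability
  (default 1: an idealized array); reads pick dyads uniformly, draw
  lengths from a clipped Normal (default mean 160, sd 15, clipped to
  [130, 240] so the 147–220 filter is exercised nontrivially) and center
  on the dyad plus protection noise (sd 2 bp). Wild-type-like preset:
  NRL 175, jitter 5; mutant-like: NRL 165, jitter 15. Default 62,500
  reads over 500 kb ≈ 20× raw coverage. Not modelled: sequence bias of
  the nuclease, linker-length heterogeneity between genomic domains,
  multi-mapping — so passing recovery tests shows the caller's geometry
  is right, not that real-genome confounders are handled.
- **Density fields**: the target ACF `C(r) = r^slope` (capped at 1 below
  1 px) is cosine-tapered to zero between 48 and 96 px and converted to a
  power spectrum; a white-noise field is filtered by its square root and
  rescaled to 16 bits. The taper reflects the finite range of chromatin
  density correlations and keeps the mean-subtracted ACF estimator
  unbiased in the 20–60 nm fit band; the default 768-px field mirrors the
  ~800-px ROIs of the imaging protocol.
- **Nuclei**: a disk nucleus with non-overlapping chromocenter disks whose
  pixel intensity is set analytically so the chromocenter share of total
  noise-free nuclear intensity equals the requested fraction; Gaussian
  noise (sd 3% of base) is added inside the nucleus. Real nuclei have
  textured euchromatin and irregular chromocenter shapes; the generator
  validates the ratio arithmetic and the threshold detector, not
  segmentation robustness.
- **FRAP curves**: the exponential model above, observed through detector
  gain, a shared background, per-frame acquisition photobleaching
  (default 0.002/frame) and relative Gaussian noise (default 2%), on a
  grid of 5 pre-bleach frames, 10 post frames at 1 s and 10 at 60 s.
- **Count tables**: negative-binomial counts (default dispersion 0.1,
  3 replicates) with expression levels log-uniform over five decades plus
  a zero-expression subset; counts scale with gene length so RPKM ranking
  recovers the level ranking; the generating stratum is recorded per gene.

## Numerical choices and degenerate inputs

Even-length read centers use the floor of the midpoint. Candidate and
longest-read ties resolve toward smaller coordinates for determinism.
Empty NRL distributions (fewer than 2 peaks everywhere) warn and return an
empty object whose group frequencies are NaN. Constant image ROIs are a
zero-variance error; non-positive ACF values are dropped before the
log-log fit and fewer than 5 surviving points is a fit failure. A fit of
FRAP recovery failing from all starts raises with diagnostics. Quantile
normalization requires identical bin grids. The wiggle writer emits
span = step (the span convention of the upstream tool is not recorded in
its outputs).

## Validation suite and problem sizes

The test suite validates each stage against independent oracles:
brute-force sequential acceptance for the peak caller (1,000 random 5-kb
instances in the acceptance suite), naive per-base-pair scans for all
interval arithmetic, hand-computed chi-square and hypergeometric tails for
the tests, Bessel-function structure for grating ACFs, and Monte-Carlo
recovery for the simulators (20 ROIs per slope for D; 20 curves for the
FRAP rate; 100 meta-trials for CI coverage; 200 trials for dispersion
ranking). These sizes keep the full suite within a few minutes on one
core while leaving Monte-Carlo standard errors well inside the asserted
tolerances. `scripts/acceptance.py --seed N --out results/acceptance.json`
reruns the whole validation from scratch and writes every measured
quantity.

## Known limitations

- The peak caller's boundary rule censors called spacings below ~150 bp
  (see above); dyad recovery saturates near 89% on dense idealized arrays
  and the mutant-like modal called bin sits one bin above the true modal
  spacing.
- D is a log-log slope over a fixed window, equivalent to shape parameters
  of power-law ACF models only in the power-law regime; absolute D values
  from other tools (e.g. Whittle–Matérn-type fits) need not coincide.
- The DE filter consumes a precomputed table; no differential model is
  fit here.
- Images are 2D single-channel; no deconvolution, registration or 3D
  segmentation.
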