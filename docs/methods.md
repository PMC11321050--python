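# Methods

## Scope and model overview

aneukit quantifies whole-chromosome aneuploidy in single cells from
three data modalities: gene × cell RNA-seq counts, integer metaphase-
spread chromosome counts, and multi-channel fluorescence images of
nuclei with centromere foci. Only whole-chromosome events are modeled;
segmental copy-number changes, doublets, ambient RNA and cell-cycle
covariates are out of scope throughout. Every analysis stage has a
matching synthetic generator with ground truth, so all quantitative
guarantees below are established on simulated data; what that does and
does not imply for real data is discussed at the end.

## Karyotype inference from scRNA-seq

**QC.** Cells with fewer than `min_genes_detected` detected genes
(default 5000, appropriate for high-depth full-length protocols) or a
mitochondrial read fraction above `max_mito_fraction` (default 0.20)
are excluded, with a per-cell reason report. Mitochondrial genes are
identified by an id prefix (default `MT-`) or an explicit list. For
the simulated matrices used in tests, which have ~10× fewer genes than
a real transcriptome, the gene threshold is configured down (300–500).

**Normalization.** Every retained cell is scaled to the same total
count, the median raw library size. Dosage is multiplicative — a
trisomy raises the expectation of every gene on that chromosome by
1.5× — so the chromosome *deviation* is a ratio, not a difference:
`r[c,k] = s[c,k] / median_c s[.,k]`, where `s[c,k]` sums normalized
counts over the genes of chromosome `k`. With an odd number of cells
the median cell's deviation is exactly 1; with an even number the
median is the mean of the two central order statistics (standard
convention).

Equal-total normalization couples chromosomes: a trisomy occupying a
fraction `f_k` of the disomic library inflates the cell total by
`0.5 f_k`, so the noise-free deviation is exactly

    r = 1.5 / (1 + 0.5 f_k)   (gain),   r = 0.5 / (1 - 0.5 f_k)  (loss).

For human chromosome 7 (`f_k` ≈ 0.05) this gives r ≈ 1.46 rather than
1.5. The effect-size gates below are placed with this shrinkage in
mind. The unit tests verify the closed form to machine precision on
noise-free matrices and to 2% under Poisson sampling.

**Permutation null.** Significance of a deviation is assessed against
permutations of the gene→chromosome assignment: gene labels are
shuffled globally (preserving the multiset of chromosome gene-set
sizes, and each cell's expression profile), chromosome scores and
deviations are recomputed per permutation, and a two-sided add-one
p-value is computed on the `|log r|` scale:

    p = (1 + #{perm : |log r_perm| >= |log r_obs|}) / (1 + n_perm).

p therefore lies in (0, 1] with minimum `1/(1+n_perm)`. Because the
permuted gene set is shared across cells, between-gene expression
variance cancels in the ratio to the per-permutation median, and the
null reflects per-cell sampling noise of size-matched random gene sets
— the correct reference for a per-cell chromosome sum. Two-sidedness
on `|log r|` treats a 1.5× gain and a 0.67× loss symmetrically.

`n_perm` defaults to 999. This is not only a resolution choice: BH-FDR
combined with the discrete permutation floor means that with `m`
(cell, chromosome) pairs and `D` true discoveries, calls require
roughly `m / (n_perm + 1) <= alpha * D`. At 200 cells × 23 chromosomes
(m = 4600), n_perm = 199 leaves the smallest attainable q above 0.05
and nothing is ever called; 999 is comfortably sufficient. The
implementation refuses n_perm < 100.

**Calls.** Benjamini–Hochberg FDR is applied over all pairs
(alpha = 0.05). A pair is called a gain iff `q <= alpha` and
`r >= gain_min` (default 1.25), a loss iff `q <= alpha` and
`r <= loss_max` (default 0.75) — midpoints between disomy and the
expected 1.5×/0.5× dosage, preventing significant-but-tiny deviations
from being called. Each gained or lost chromosome counts as one
aneuploid chromosome; cells are classed euploid (0), simple (1–3) or
complex (≥4). Chromosome X is included; Y is excluded by default
because its near-zero expression makes the score unstable; MT is never
a karyotype target; chromosomes with fewer than 25 genes are reported
but flagged low-confidence.

Measured performance at the reference conditions (200 cells × 2000
genes, NB dispersion 0.1, 20% simple + 5% complex cells, n_perm 999):
per-pair precision ≈ 0.98, recall ≈ 0.93–0.95, cell-class accuracy
≈ 0.99; on all-euploid matrices the non-neutral call rate is ~0, well
inside alpha. Missed events concentrate on the smallest chromosomes
(few genes → noisy scores), an intrinsic property of
expression-aggregate methods.

## Metaphase-spread statistics

Each spread's deviation is `|n_i − nearest(46, 92, 184)| / ploidy(2, 4, 8)`;
*complexity* is the condition mean and *heterogeneity* the sample SD
(ddof = 1; a single spread reports 0). Ties in the nearest euploid
number (e.g. 69) resolve to the lower anchor; this is configurable in
principle but fixed here and documented. Spreads are classed by the raw
distance (0 / 1–3 / ≥4). A condition with fewer than 30 spreads is
flagged low-n. Limitation: balanced gain+loss events cancel in the
count and are invisible to spread statistics.

The missegregation test treats each chromosome's observed gain+loss
event count among `n` cells as Binomial(n, P) under the null that all
chromosomes missegregate equally. P is user input — typically the
overall aneuploid fraction of (cell, chromosome) pairs; the package
offers the plug-in estimator `events_total / (n_cells × n_chromosomes)`
but does not presume it. The two-sided p-value uses the
minimum-likelihood convention (sum of all outcome probabilities no
larger than the observed one), delegated to scipy's exact binomial
test; the suite verifies agreement with an exact rational-arithmetic
pmf summation to 1e-12 for n ≤ 200. Significance tiers are 0.05 /
0.01 / 0.001. Chromosome-size dependence uses Spearman rank correlation
against embedded GRCh38 chromosome lengths (≥5 chromosomes required;
constant event vectors are rejected as undefined).

## Module scoring

Scores are computed on log1p of the equal-total-normalized matrix —
the conventional scale for module scores. Genes are ranked by mean
expression across cells and cut into `n_bins` equal-size bins
(default 24); for each program gene, `n_ctrl` (default 100) control
genes are drawn without replacement from its bin, and the score is
mean(program) − mean(pooled controls) per cell. Program genes are
excluded from control pools, which makes the score exactly location-
equivariant: adding a constant to a cell's program genes moves that
cell's score by that constant. If a bin has fewer candidates than
`n_ctrl`, sampling falls back to with-replacement with a warning —
expected on small simulated matrices, rare on real transcriptomes. The
default program is the p53 pathway set (CDKN1A, GADD45A, PLK2, MDM2,
RPS27L, TRIAP1, FAS); missing genes are reported, never silently
dropped. Null calibration (random 7-gene sets on an aneuploidy-free
matrix score 0 within sampling error) and planted-shift recovery are
verified in the suite. Score-vs-aneuploidy uses OLS with Pearson r;
class comparisons use one-way ANOVA with post-hoc Tukey HSD, both
delegated to scipy/statsmodels.

## Centromere-foci counting

Processing is 2D with 8-connectivity; confocal z-stacks are assumed to
enter as maximum-intensity projections (the algorithm is
dimensionality-agnostic; 2D keeps fixtures small). Nuclei are Otsu-
thresholded on the nucleus-marker channel, components below
`min_area_px` (default 200) discarded. Requiring a nucleus mask in the
Cdt1-like channel stands in for G1 gating; explicit cell-cycle
classification is out of scope. Within each nucleus the centromere
channel is Otsu-thresholded again; connected components are centromere
clusters. Cluster intensity is background-subtracted using the
per-nucleus median of sub-threshold pixels — without this the
intensity-ratio count would be offset-sensitive.

Counting: `I_median` over clusters approximates the single-centromere
intensity (most centromeres are separated); base count =
`round(I_i / I_median)`. The three brightest clusters per nucleus
(ties broken by label order) and every cluster with `I_i < I_mean` are
instead counted by their number of local intensity maxima (≥1), since
extreme intensities carry the largest ratio errors. Median and mean
are computed once from all clusters before any mitigation. A nucleus
with a single cluster is counted by maxima alone and flagged. Local
maxima are detected on the negated Laplacian-of-Gaussian response of
the background-subtracted cluster patch (sigma 0.6 px, minimum peak
separation 1 px, relative peak threshold 0.2) — standard blob
enhancement that resolves near-touching foci down to roughly twice the
PSF sigma, the physical limit for maxima-based splitting. Every
decision is ratio- or rank-based, so N is invariant under positive
rescaling of the centromere channel (verified by test). Classes:
N ≤ 47 euploid, 48–49 simple, ≥50 complex — the counter cannot
reliably see small deviations below 47, hence the asymmetric euploid
band. Mean immunostain (p53) intensity is the arithmetic mean of that
channel over each nucleus mask.

Measured accuracy: exact N for every nucleus at any true N in 30–92
with separated spots (any intensity CV up to ~0.1); median absolute
error ≤ 2 at 20% clustering, CV 0.2 and read noise 5% of spot
amplitude. Residual error is dominated by unresolvable spot pairs
closer than ~2 PSF sigma inside the brightest clusters.

## Synthetic generators

All generators are pure functions of (parameters, seed); a single
global seed fans out to stages via fixed child streams
(`default_rng([seed, stage_index])`).

**Counts.** Per-gene baseline means are log-normal (default
logmean = log 8, logsd = 1); per-cell library factors log-normal
(logsd 0.2); counts are negative-binomial with variance μ + αμ²
(α = 0.1 default; α = 0 degrades to Poisson). Chromosome gene counts
are apportioned from an embedded GRCh38 protein-coding table
(22 autosomes + X; 13 MT genes appended for QC exercises), or any toy
genome. Simple aneuploid cells receive 1–3 and complex cells 4–8
whole-chromosome events (gain to 3 copies or loss to 1, equal odds);
expected counts scale by copies/2. Default population: 20% simple, 5%
complex. A noise-free variant emits expected counts directly for
closed-form tests.

**Spreads.** Counts are 23 × ploidy plus a deviation drawn from a
user-supplied signed-integer distribution; configurations that could
produce non-positive counts are rejected.

**Images.** Nuclei are uniform disks (radius 50 px) on a
non-overlapping grid; centromere foci are symmetric 2D Gaussians
(sigma 1.5 px) with per-spot amplitude CV; the immunostain channel is
uniform per nucleus at its p53 level; Gaussian read noise is added to
all channels and intensities clipped at 0. Isolated spots keep ≥4
sigma mutual separation. A `cluster_fraction` of spots is placed near
an existing spot at distances between half a FWHM and 0.8 PSF widths
(PSF width taken as the 1/e² beam diameter, 4 sigma) — merged into one
thresholded component, with a fraction far enough apart to show two
intensity maxima, as in real centromere clusters. Truth records spot
centers, amplitudes, grouping, per-nucleus counts and p53 levels.

**What the generators do not emulate**: segmental CNVs, doublets,
ambient RNA, cell-cycle expression covariates, 3D PSFs, chromatic
shift, uneven illumination, nuclear shape variation. Passing tests
establish correctness of the computations under the stated models, not
performance on real microscopes or transcriptomes; in particular the
caller's ≥0.9 precision/recall is specific to the simulated noise
level and aneuploid fractions.

## Numerical and reproducibility choices

Degenerate inputs fail loudly: zero-total cells, all-excluded QC,
constant images, empty spread sets, single ploidy classes and
out-of-range thresholds all raise with messages naming the offending
setting. Chromosomes whose median score is zero are excluded with a
warning. CSV output uses a fixed float format (`%.10g`), so identical
config + seed reproduces byte-identical files; the run report contains
no timestamps. Problem sizes in the test suite (120–200 cells,
600–2000 genes, 50 nuclei, 199–999 permutations) were chosen so the
full suite and the acceptance script each complete in well under a
minute on one CPU while keeping every statistical check comfortably
powered.
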