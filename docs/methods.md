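# Methods

`cnscratch` implements the computational core of a multi-region tumor
copy-number analysis for metastatic castration-resistant prostate cancer
(mCRPC): estimating tumor purity from haplotype B-allele frequencies,
fingerprinting each sample's dominant clone by its copy-number *transition
points*, clustering samples into clonally related groups (SCRATCH),
testing whether autosome-derived and chromosome-X-derived dendrograms are
topologically congruent, scoring androgen-receptor (AR) transcriptional
activity from expression, and computing breakpoint/mutation clonality
statistics.  Because the motivating data are access-controlled, the package
ships a first-class synthetic-data generator that plants a known clonal
structure; every downstream stage is validated by recovering that truth.

## Genome model and coordinate conventions

All computation happens on a fixed-width bin grid (default 500 kb, 0-based
half-open coordinates).  The default desk-scale genome is four autosomes of
200 bins each plus a 120-bin chromosome X with a designated AR bin, an
enhancer bin immediately centromeric to it, and an Xq arm starting at a
configurable centromere bin.  Samples are assumed male (prostate cancer),
so the germline carries one copy of chromosome X: the normal copy number
c_n is 2 on autosomes and 1 on chrX everywhere in the package.

## Synthetic clone trees

`simulate_clone_tree` plants a patient as a hierarchy of copy-number
events, all ±1 in copy number unless noted:

- **truncal** events present in every sample, including three long (15–30
  Mb) loss-of-heterozygosity (LOH) deletions on distinct autosomes that
  later serve as purity anchor regions;
- **cluster** events present exactly in one cluster's samples (default 15
  autosomal plus 4 chrX events per cluster); alternating clusters also
  receive a focal high-level AR amplification (+5..+20 copies) on Xq
  covering the AR and enhancer bins, emulating the AR-gained vs AR-neutral
  clone classes observed in treated mCRPC;
- **branch** events shared by sister clusters: clusters are joined in a
  random binary order and each join carries events (half autosomal, half
  chrX) shared by both sides, reflecting that clusters are clades of one
  patient clone tree;
- **subclone** events: within each cluster a random binary genealogy over
  its samples is planted, each internal node sharing events split between
  an autosome and chrX (chrX subclone events have moderate amplitudes,
  −2..+3, because treatment-selected subclones differ substantially in
  AR-locus architecture).  This within-cluster hierarchy on *both*
  chromosome sets is what makes dendrogram congruence a testable property
  rather than a cluster-label coincidence;
- **private** events unique to one sample.

Event boundaries are rejection-sampled so that no two events share a
boundary bin and no event overlaps an anchor region; deletions are rejected
if any carrying sample would drop below zero copies.  Per-sample purities
are uniform on [0.2, 0.9], the tumor-content range retained for analysis.
Everything is deterministic given the seed.

Mutation sets mirror the truncal/cluster/private hierarchy with configurable
counts (defaults 50/20/5), and expression counts shift an AR-response
signature's up-genes by `effect_size * log2(AR copy number)` on the log2
scale (down-genes by the negative), with Gaussian log-scale noise.

### Read counts and noise

Expected bin counts follow `depth_per_bin * r` with the normalized ratio

    r = (rho*c_t + c_n*(1-rho)) / D,    D = rho*psi + 2*(1-rho),

where `c_t` is the clone's copy number at the bin and `psi` the tumor
ploidy.  Ploidy is defined as the **median autosomal copy number** of the
tumor, which matches the median normalization of raw counts (the median
autosomal bin has ratio 1) and makes the absolute-CN transform an exact
inverse of the simulator on noiseless data.  Counts are gamma-Poisson
(negative binomial) with dispersion `k` (variance `mu + mu^2/k`; `k = inf`
is the Poisson limit).  Defaults are ~1700 reads/bin — the count implied by
0.34X shallow WGS over 500-kb bins with 100-bp reads — with `k` equal to
the mean (variance twice Poisson), a typical shallow-WGS overdispersion.
The generator does not model GC/mappability bias, FFPE artifacts or
subclonal admixture within a sample (each sample is its dominant clone at
purity rho); recovery results therefore speak to the statistical machinery,
not to wet-lab artifact robustness.

### Phased SNPs

Heterozygous SNPs are placed uniformly in anchor regions (default 20/Mb).
The germline phasing carries a Markov switch process: the reported
haplotype orientation flips between consecutive SNPs with probability
`switch_rate` (default 0.02), shared across samples because phasing is a
germline property.  Per sample, SNP depth is Poisson (default 30) and the
haplotype-A read count is binomial around

    B = (rho*n_A + (1-rho)) / (rho*(n_A+n_B) + 2*(1-rho)),

the expected haplotype-A allele fraction for local allele-specific copies
(n_A, n_B) on an autosome.

## Purity estimation

Two independent estimates are combined per sample.

**Haplotype-BAF route.**  Anchor regions — long, low-ratio, allelically
imbalanced segments — are selected in a high-coverage reference sample.
Selection thresholds replace the original visual inspection with explicit,
logged values: segment length ≥ 10 Mb, ratio at least 0.1 below the
sample's length-weighted median, block-corrected pooled BAF more than 0.08
from 0.5.  Each candidate is annotated with the allele-specific state
(n_A, n_B): every small imbalanced state is inverted through the BAF
equation to an implied purity and the state whose implied purity best
reproduces the observed depth ratio (within 0.1, assuming near-diploid
ploidy) is kept — the "solution satisfying both constraints".  Switch
errors are corrected within anchors using the high-purity sample: runs of
per-SNP BAF on one side of 0.5 form phase blocks, blocks with pooled BAF
below 0.5 are flipped (so haplotype A is the retained allele) and blocks
within ±0.05 of 0.5 are dropped.  A low-coverage sample's purity then comes
from its pooled (depth-weighted) haplotype-A BAF in each anchor via

    rho = (1 - 2B) / (B*(n_A + n_B - 2) - (n_A - 1)),

clipped to [0, 1]; the sample estimate is the median over anchors and
requires at least 3 usable anchors (≥ 20 SNPs each) to be valid.  Pooling
counts rather than averaging per-SNP BAFs weights by depth, which matters
at shallow coverage.

**Grid fit.**  A purity/ploidy grid search (rho 0.05–1.00 step 0.01, psi
1.5–5.0 step 0.05) minimizes the length-weighted distance of implied
segment copy numbers from integers,

    E(rho, psi) = sum_s w_s |CN_s - round(CN_s)| * (1+|psi-2|)^0.5 / rho^0.5,

with both penalty exponents 0.5 (penalizing low cellularity and
non-diploid ploidy).  Ties break toward higher purity, then ploidy nearer
2 — which resolves the classic halved-purity/doubled-ploidy lattice
degeneracy.  A flat profile returns (1, 2) with a degeneracy flag.  The fit
is reliable on noiseless or high-purity data; at purities below ~0.4 with
±1 events it tends to the rho=1 corner, which is why it is only one arm of
a consensus.

**Consensus.**  If both estimates are valid and within 0.1 they are
averaged; if they disagree by more, the haplotype-BAF estimate wins and
the sample is flagged discordant (the 0.1 window is this package's
choice; the original reconciliation rule is not specified).  Samples with
consensus purity below 0.2 are excluded from downstream analysis (boundary
inclusive).

In the bundled pipeline the "high-coverage" reference is chosen
automatically: candidates are tried in order of decreasing grid-fit purity
until one yields ≥ 3 anchors.  Low-purity samples whose anchors were
merged away by segmentation fail this screen naturally.

## Segmentation and transition points

Segmentation is a greedy left-to-right running-mean merge: a bin joins the
current segment iff its value is within `merge_tol` of the running mean,
never crossing chromosome boundaries, followed by a collapse of adjacent
segments still within tolerance — this post-pass makes segmentation
idempotent and guarantees adjacent segments are distinguishable.  It is
deliberately the minimal merge rule (no CBS/HMM; the interface accepts any
pre-segmented input).

For clonal fingerprinting, segmentation runs on **purity/ploidy-corrected
per-bin copy numbers** (`segment_absolute`, tolerance 0.5 CN units) rather
than raw ratios: on the ratio scale the footprint of a one-copy event
shrinks proportionally to purity (rho/D), so a fixed ratio tolerance
silently drops events from low-purity samples, whereas on the CN scale the
tolerance is a copy-number quantity.  Because the correlation distance
below is invariant to per-sample affine maps, clustering is additionally
robust to residual purity misestimation.

A **transition point** is an internal segment boundary with a copy-number
change; chromosome ends are excluded.  The transition matrix has one
column per boundary in the union over a patient's samples (exact bin-edge
matching — all samples share one grid) and entry (s, b) equal to the copy
number of the segment of sample s covering position b, i.e. the value
immediately right of the boundary (a documented convention; the original
description is silent on the side).

## SCRATCH clustering

Distances are 1 − Pearson correlation between matrix rows (Spearman
available); zero-variance rows get the maximal distance 2 with a warning.
Agglomerative clustering uses complete linkage by default (configurable:
average, Ward).  The number of clusters k* maximizes the mean silhouette
width over k = 2 … min(k_max, n−1), smallest k on ties; any cluster with
fewer than two samples is then merged into the cluster sharing its most
recent common ancestor on the dendrogram, repeated until all clusters have
≥ 2 members or one remains.  Transition-point sharing statistics
(query-in-targets fractions, pairwise |intersection|/min-size matrix with
<20% / 20–80% / >80% binning) operate on the same boundary keys,
optionally requiring the change direction to match.

## Congruence of autosome and chrX dendrograms

**Baker's Gamma** is the rank correlation (Goodman–Kruskal gamma by
default, Spearman optional) between the two trees' merge-level vectors:
for each leaf pair, the number of clusters present when the pair first
co-clusters, scanning cuts from n down to 1.  Merges at tied heights are
counted together, so mirror-image trees score exactly 1.

**Congruence index.**  The rooted maximum agreement subtree (MAST) of the
two dendrograms is computed by exact dynamic programming over node pairs
(O(n1·n2); multifurcations are binarized deterministically, left-leaning
by smallest leaf label; n is capped at 64).  I_cong is the observed MAST
size divided by its mean over random leaf-label permutations of the second
tree, and the p-value comes from the same permutation distribution
(declared congruent at p < 0.01).  Rooted MAST is used because dendrograms
are rooted.  The permutation null replaces pre-compiled expected-MAST
tables with an exact Monte-Carlo null, self-contained at this scale.

Because MAST takes few integer values, the plain Monte-Carlo p-value
`(1 + #{perm >= obs})/(B+1)` is badly conservative under heavy ties; the
congruence index therefore defaults to the standard randomized (tie-broken)
p-value `(#{perm > obs} + U*(#{perm = obs} + 1))/(B+1)`, U ~ Uniform(0,1),
which is exactly uniform under the null — verified by the type-I
calibration test.  `permutation_p` keeps the conservative rule as its
default for users who prefer a guaranteed-valid p.

Statistical power: with 3 clusters the congruence test needs both trees to
recover within-cluster structure; at fewer than ~20 leaves the rooted-MAST
statistic has little margin over its null even for perfectly matching
cluster labels.  The bundled congruence demonstration therefore uses 24
samples (3 clusters × 8), matching the sample counts of patients to which
such congruence analysis is realistically applied.

## AR activity score

Expression counts are filtered (≥ 10 reads in ≥ 90% of samples),
converted to log2 counts-per-million (+0.5 offset) and quantile-normalized
to the mean empirical distribution.  Precision weights are omitted: they
do not alter the per-gene z-scores that the score consumes.  Per-gene
z-scores across samples are ternarized — up-genes score +1 at z ≥ 1, −1 at
z ≤ −1, else 0; down-genes the negation — and summed per sample over the
signature genes present (absent genes are logged and skipped, and the
number aggregated is logged).  The bundled 27-gene signature
(`data/ar_signature_synthetic.tsv`, 20 up / 7 down) is a synthetic
stand-in built from canonical androgen-response genes; it is data, not
code, and should be replaced by the user's preferred signature for real
analyses.  Group comparisons use the Mann–Whitney U test with the exact
null for small tie-free groups.

## Clonality statistics

Breakpoint cancer cell fraction adjusts the allelic fraction for tumor
content and local copy number:

    CCF = AF * (rho*CN_t + c_n*(1-rho)) / (rho*m),

with multiplicity m defaulting to 1 (the conservative choice when shallow
data cannot resolve it) and values capped at 1.0 with the raw value
retained.  Clonal-mutation overlap between two samples is
|intersection| / min(set sizes); the same-cluster vs cross-cluster
comparison is a one-sided Wilcoxon rank-sum test (exact for small tie-free
groups).  AR-locus breakpoints are counted per patient as unique positions
inside a half-open 30-Mb chrX window centered on the AR bin; Fisher's
exact test wraps the exact hypergeometric tail with degenerate margins
returning p = 1 with a warning.

## Numerical choices and degenerate inputs

- Copy-number thresholds (the ≥ 2 gain rule, per-bin gain proportions)
  tolerate 1e-9 of float error so that exactly reconstructed integer copy
  numbers are classified correctly.
- The AR copy number over the gene interval is an overlap-length-weighted
  median; an exact half-mass tie returns the midpoint of the two straddling
  segment values.
- The "gained fraction of Xq" is the fraction of Xq bins at CN ≥ 2, and
  the gain rule is total copy number ≥ 2 on the one-copy male X (the
  alternative ≥ 2-fold reading is available by changing `cn_threshold`).
- n < 3 samples: clustering returns a single cluster with a warning; 3-leaf
  trees are flagged degenerate in congruence results.
- All simulators, permutation tests and the pipeline take explicit seeds;
  no wall-clock seeding anywhere.

## Problem sizes used in the validation suite

The bundled validation experiments use desk-scale configurations chosen to
exercise each claim: cluster recovery on 20 patients of 3 clusters × 4
samples at 100 reads/bin; purity recovery on planted purities 0.2–0.9 with
3 LOH anchors × 300 SNPs at depth 30 over 20 seeds; MAST oracle agreement
on 100 random tree pairs with n ≤ 8; null calibration on 1,000 random tree
pairs with 99 permutations each; and the congruent-patient demonstration at
24 samples with 999 permutations.

## Known limitations

- The greedy segmenter has no statistical control of the false-split rate;
  heavily overdispersed data fragment into many small segments (harmless
  for correlation-based clustering, noisy for boundary-level statistics).
- Grid purity fitting is unreliable below ~0.4 purity with only one-copy
  events; the consensus leans on the haplotype-BAF estimate there.
- Rooted MAST congruence has limited power below ~20 leaves.
- The simulator omits GC bias, FFPE damage and within-sample subclonal
  mixtures, and chrX anchor regions are not modeled (anchors are autosomal).
- Bin-level breakpoint resolution: transition points are bin-edge
  positions, so events closer than one bin are merged.
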