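# Methods

## Scope and design

The package decomposes a staged differentiation study (five ordered stages,
two ATAC replicates per stage, ~90 single cells per stage) into seven
modules: synthetic data generation, single-cell preprocessing, peak-set
algebra, motif/target/network analysis, lineage-path inference,
communication-network inference, and orchestration. All interchange is
plain text (BED 0-based half-open, FASTA, TSV, JSON) so each stage is
independently runnable and diffable. Everything is deterministic given a
seed; the pipeline manifest records input and output SHA-256 hashes so
reruns are verifiable byte for byte.

## Quality control

A cell passes the metric filter iff genome mapping rate > 0.70,
mitochondrial fraction < 0.20, mRNA mapping rate > 0.80, ERCC ratio < 0.10
and detected genes > 5,000 — all comparisons strict, so a cell sitting
exactly on a threshold fails. Every failing cell reports all violated
criteria.

The ERCC correlation filter compares each cell's log2(count+1) spike-in
vector with the leave-one-out mean log profile of the remaining cells and
requires Pearson r ≥ 0.9. The reference profile is a design choice — the
source procedure says only "correlation of ERCC among cells" — and a
`pairwise_mean` mode (mean of pairwise cell–cell correlations) is provided
as the alternative reading. Zero-variance spike-in vectors fail with
reason `degenerate`; fewer than 8 spike-in channels or 3 cells is an
error.

## Normalization

RPKM(g,c) = counts·1e9/(length·libsize); TPM renormalizes per-cell
length-corrected rates to 1e6. Library sizes are computed over endogenous
genes only; ERCC rows are scaled with the same per-cell factor (nominal
100 bp length when no length is supplied). Zero library sizes are an
error naming the cell.

## Differential expression

The per-gene test is a two-sided Mann–Whitney rank-sum on
log2(normalized+1) (normal approximation with tie correction), BH-adjusted
over the tested genes. This is a deliberate stand-in for the original
study's Bayesian per-cell error-model test: it preserves the same contract
(statistic → two-tailed p → FDR; significance at adjusted p < 0.01 and
fold change > 2) while being distribution-free and dependency-light.
Genes expressed in neither group are excluded before testing; constant
genes get p = 1. Fold change is computed on group means of the normalized
values with pseudocount 1, so a gene planted at exactly 2-fold straddles
the strict FC > 2 cutoff — recovery guarantees are therefore stated for
4-fold effects.

## Peak-set algebra

Overlap means ≥ 1 shared bp between half-open intervals (configurable);
this is the most permissive consistent reading and all classifications
reduce to it. Novelty is assessed against the cumulative union of all
earlier stages; gained/lost only against the immediate neighbor;
stage-specificity against all other stages. Reproducible peaks widen each
rep1 peak to the union interval with its rep2 partners and merge the
result — a replicate-overlap stand-in for the IDR procedure, which is out
of scope. Summits of merged intervals sit at midpoints.

Peak centers (start + summit) are classified with precedence promoter >
exon > intron > distal. The promoter is [TSS − 2 kb, TSS + 2 kb) in strand
orientation. Without an exon table the gene body counts as a single exon
(a single-exon transcript model), so intronic calls require explicit exon
annotations. Nearest-TSS target assignment breaks exact distance ties by
the lexicographically smaller gene id, documented because real annotations
contain equidistant TSSs; signed distances are negated on the minus
strand.

## Motif scanning

Position-frequency matrices are converted to probabilities with a
pseudocount of 0.25/√n (n = column total). Scores are sums of per-position
log2 odds against an i.i.d. background; zero-probability bases are floored
at −30 bits per position so maximal-information matrices stay finite and
the exact-p-value recursion stays tractable. P-values are exact tail
probabilities of the score discretized on a 10⁻³-bit grid (configurable),
obtained by convolving per-position score distributions; brute-force
enumeration of all 4^k k-mers reproduces them to ≤ 1e-9 for k ≤ 6. The
minus strand is scored with the reverse-complemented matrix against the
complemented background, which makes hit sets and p-values exactly
strand-symmetric even under skewed backgrounds.

A consequence of exactness worth noting: a length-L consensus cannot beat
p = 4⁻ᴸ under a uniform background, so length-4..6 motifs are unreportable
at the default scan threshold of 1e-4 (conventional for short PWMs).
`PWM.min_attainable_pvalue` exposes this floor; recall statements are
restricted to motifs whose floor clears the threshold.

## Regulatory network

The network is the subgraph of the supplied TF–TF edge table induced on
differential TFs (adjusted p < 0.05 between neighboring stages, |log2FC| >
1 in the pipeline), with self-loops dropped, duplicate edges collapsed and
isolated nodes removed. Key regulators have degree strictly above 5.
Degree is counted on the induced subgraph by default — the network under
study contains only differential TFs — with a `full` scope option that
counts degree in the complete edge table instead.

## Lineage inference

Subpopulation profiles are per-TF means of log2(normalized+1) over member
cells (≥ 3 cells required). Adjacent stages are fully connected by
Pearson r over the TF vector; the dominant path is greedy — from the
first-stage node, repeatedly take the maximal-r edge into the next stage —
matching the sequential pairwise description of the study rather than a
global maximum-weight path. When the first stage holds several
subpopulations and no start is given, the one carrying the strongest
single edge into stage two starts the path. Variable genes are selected
by within-bin z-scores of log dispersion (variance/mean) after binning on
mean expression — a deterministic dispersion-based stand-in for the
original graph-based selection.

## Communication networks

Expression calls use the arithmetic mean TPM over member cells with a
strict > 1 cutoff ("above the threshold"). Directed edges (i, j, ligand,
receptor) are enumerated within each stage, autocrine edges included by
default. Specificity is one-vs-rest DE restricted to ligand/receptor
genes at adjusted p < 0.05. Interaction counts are directed distinct
tuples; a deduplication flag is available via the edge table itself.

## Synthetic data generator

The generator emulates the study design, not read-level realism: i.i.d.
background sequence, uniform peak-boundary jitter of ≤ 10 bp between
replicates, negative-binomial counts (gene-level dispersion uniform in
[2, 10]) with Bernoulli dropout (default 0.2) on endogenous genes, and
ERCC concentrations log-uniform over four orders of magnitude. Defaults
mirror the emulated experiment: five stages, 3 subpopulations × 30 cells
per stage, 300 peaks per stage, 70% peak carry-over between neighbors,
4-fold (2 log2 units) planted effects.

Peak truth is exact by construction: carried intervals are copied from the
previous stage; new intervals are placed overlapping nothing placed
before, with a guard gap larger than twice the replicate jitter, so
novel/conserved/gained/lost/stage-specific labels are recoverable with
zero error. The planted lineage path makes consecutive path
subpopulations share ~80% of their TF program while off-path
subpopulations share ~25%, so the maximal-correlation chain is unique by
construction. Ligand/receptor genes receive a moderate baseline floor
(2^U(3,5) mean counts) because a fold-change plant on a near-zero baseline
is not expressible above the +1 pseudocount. QC failures are planted one
criterion per designated cell; ERCC-failure cells get an independently
permuted concentration vector.

What passing tests do *not* show about real data: the generator has no
batch structure, no sequence composition bias, no doublets, no ambient
RNA, no correlated gene programs beyond the planted ones, and a gene
universe of 300 — so, e.g., the TPM > 1 expression call saturates (mean
TPM per gene is ~3,000 at this scale) and the communication network's
discriminative signal comes from the specificity calls rather than the
expression calls. Thresholds calibrated for genome-scale data keep their
stated values here rather than being rescaled.

## Numerical choices and problem sizes

Score grid 1e-3 bits; Pearson correlations via scipy; BH via statsmodels;
all randomness through `numpy.random.default_rng` seeded per generator
stream from the study seed. Tests and the acceptance script run the
default study (450 cells, 660 distinct peaks, 6 motifs) and scaled-down
property fixtures (≤ 500 peaks, ≤ 200 ligand–receptor pairs, 20-seed
recovery panels), sizes chosen so the whole suite completes in about a
minute while keeping every oracle exhaustive at its scale.

## Known limitations

No IDR copula model, no Bayesian error model, no graph-based clustering or
trajectory embedding (subpopulation labels are inputs), no motif
enrichment statistics, no GO/KEGG enrichment, and no enhancer annotation
(the category set stops at promoter/exon/intron/distal). The
communication module does not score edge strength or compute permutation
p-values.
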