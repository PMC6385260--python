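# Methods

This note records the models, conventions and numerical choices behind
each pipeline stage, what the synthetic-data generators do and do not
emulate, and the limitations a user should know before trusting a result
on real data.

## Sequence primitives

Identity and coverage come from an exact global (Needleman–Wunsch)
alignment with match = +1, mismatch = 0, and gap open/extend = −1/−1
(end gaps penalized), computed by Biopython's `PairwiseAligner`. Identity
is matches over aligned columns excluding terminal-gap columns; coverage
is the fraction of the query's residues inside that trimmed window. The
query is the shorter sequence in `global` mode, the first argument in
`query_cover` mode. When several alignments are co-optimal the aligner's
first is used; tests therefore compare against the *set* of identities
achievable by optimal alignments. This is a deliberate stand-in for
word-heuristic tools (Cd-hit, BLAST) at desk scale: exact, deterministic,
and affordable up to a few thousand sequences, but quadratic per pair —
do not point it at a million-sequence library.

Greedy clustering visits sequences longest-first (ties by id) and joins
the first existing cluster whose representative matches at or above the
identity and coverage cutoffs, else founds a new cluster. This mirrors
the order-dependence of Cd-hit while being fully reproducible.

Alignment trimming treats gap characters plus `X`/`N` as missing, drops
columns with missing fraction ≥ the column threshold, then rows ≥ the
row threshold — and repeats the two passes to a fixed point, because
removing rows changes column fractions. The fixed point makes trimming
idempotent and equals the single pass whenever one pass suffices.
Thresholds use ≥ (a column exactly at the threshold is dropped).

Neighbor joining delegates to scikit-bio's `nj`; additive distance
matrices are recovered exactly (patristic distances equal the input).
No maximum-likelihood inference is provided: production trees should
come from an external ML tool, and the NJ builder exists so the HGT
screen and the tests have a deterministic, dependency-light tree source.

## Assembly QC

Genome size from coverage is integer floor division of total mapped
bases by mean coverage — floor because an assembly size is a base count.
The allele-frequency spectrum uses 50 equal bins on [0, 1], half-open
except the final closed bin, and reports the modal bin; a diploid single
genotype peaks in the bin containing 0.5, a haploid contaminant at 1.0.
The whole-genome-duplication test clusters the proteome at 90/70/50%
identity with 70% minimum query coverage and reports the dominant
cluster size (ties resolved toward the smaller size); dominant size 1
argues against recent WGD, dominant size 2 is the duplication signature.

## Gene-model reconciliation

Overlap between predictions means: same contig, same strand, gene-extent
intervals intersecting by ≥1 bp — the most permissive reading, chosen so
that fragmented predictions cannot escape rule (a) by falling between
exons. Homology models are processed in (contig, start, id) order;
ab initio models consumed by an earlier decision are unavailable to
later ones, which makes the procedure deterministic and independent of
input file order. Rule (a) fires when the surviving ab initio partners
contain at least one mutually non-overlapping pair ("two or more
non-overlapping" read as pairwise disjointness); all partners at that
locus are then consumed. When rule (b) faces several mutually
overlapping partners, the longest-extent one stands for the locus.
Completeness is reference-normalized: aligned reference positions inside
the terminal-gap-trimmed window divided by reference length, and the
">5%" gain threshold is an absolute difference of 0.05 in these
fractions. Every decision is logged (`fragment_join`,
`completeness_swap`, `completeness_keep`, `novel_homology`,
`abinitio_passthrough`) so a merged annotation can be audited locus by
locus.

Model filtering discards CDSs with in-frame stops, CDS lengths not
divisible by 3, repeat-library overlap ≥ 50% of the CDS, and atypical
codon usage. Atypicality is the Pearson correlation between a gene's
61-sense-codon relative-frequency vector and the genome-wide vector,
with a default cutoff of r < 0.5. This definition is only informative
when the genome has real codon bias; on a hypothetical genome with
uniform usage the genome-wide vector is constant and the correlation
degenerate, which is why the synthetic generator plants a skewed codon
distribution (see below).

Family statistics: fold change is floor(count_a / count_b) and is
undefined (typed error) at a zero denominator. The clade partition
counts four disjoint cells — gains (present only in the focal clade),
losses (absent from focal, present in ≥2 other named groups, so the
family predates the split), shared (focal plus ≥1 other), other (absent
from focal, exactly 1 other group) — which sum to the families touching
any partition species. The ≥2-group requirement for losses is a
declared, configurable reading of "loss"; with a single outgroup it
would undercount.

## Repeats

Masked fraction is the union length of hit intervals per contig
(overlaps counted once) over assembly length, reported rounded to whole
percent in summaries and at full precision in machine output. A repeat
copy's compartment is decided by its midpoint — a copy straddling an
exon/intron boundary gets one label — with UTR labels only when UTR
intervals are supplied (otherwise UTR space counts with exons). The
repeat-vs-intron-size relation is a Spearman rank correlation (mid-rank
ties, two-sided p) of per-gene total intron length against repeat copy
count; constant input is a typed error since ranks are undefined.

## HGT screen

Queries whose single best hit (bitscore, ties by subject id) is metazoan
are removed; hitless queries are not candidates. Representative subjects
come from two first-come-first-served sweeps with a per-phylum cap of 6:
one by bitscore, one by identity restricted to alignments ≥ 200 aa; the
deduplicated union always contains the globally best hit and is bounded
by 2 × cap × phyla. The same cap applies to both sweeps (configurable).

Provenance is the package's automation of what is usually a manual tree
inspection, so it is deliberately simple and auditable: midpoint-root
the gene tree (unit branch lengths when none are given), take the
non-query leaves of the query's smallest containing clade as the sister
group, and call non-metazoan/metazoan only when the sister is pure;
anything mixed is ambiguous. Every call carries the sister leaf list so
a human can re-check it. Midpoint rooting is the default because input
trees are unrooted; outgroup rooting can be emulated by re-rooting
upstream.

The four GTA hallmarks are scored independently: (1) cluster span
(first gene start to last gene end) within 4–14 kbp, the size a
gene-transfer-agent particle packages; (2) every candidate gene
single-exon; (3) no non-candidate gene interleaved; (4) nearest
non-candidate neighbor on each side exists and is metazoan. A cluster at
a contig end fails (4) rather than being excused — absence of a flank is
absence of evidence for host context.

The bundled end-to-end `run_screen` builds trees by neighbor joining on
pairwise p-distances (1 − global identity) between the query protein
and its representatives. On real data, externally built ML trees should
be passed through `classify_provenance` instead.

## Selection scan

Back-translation threads each CDS onto its protein alignment row codon
by codon (protein gaps become `---`, a terminal stop codon is
tolerated); a CDS that does not translate to its row is a typed error
naming the first offending position, and arbitrary nucleotide-level gaps
are rejected rather than repaired. Gap stripping removes every codon
column gapped in either row.

The dN/dS estimator is Nei–Gojobori (1986): synonymous sites per codon
are the per-position fractions of synonymous single-nucleotide changes,
averaged over the two sequences; a change to a stop codon is never
synonymous but stays in the denominator. Multi-hit codons average
substitution counts over mutational pathways with equal weights,
excluding pathways through stop codons unless all pathways pass through
one. Jukes–Cantor corrects each class; dS (and dN) are flagged undefined
— not an exception — when the corresponding proportion reaches 3/4.
Hand-checked anchor: TTT→TTA has S = (1/3 + 2/3)/2 = 0.5 and N = 2.5
per codon, giving dN = −0.75·ln(1 − 0.4·4/3) ≈ 0.5716 and dS = 0. The
estimator is symmetric in its two sequences, and synonymous-only
divergence yields dN = 0 exactly. This counting estimator replaces
model-averaged ML estimation: it is exact, dependency-free and
oracle-checkable, and ranking by dN is robust to the estimator choice;
absolute dN/dS ratios from NG86 should not be over-interpreted under
strong codon bias or transition/transversion asymmetry.

Ranking keeps pairs with defined dN, reports the number excluded, sizes
the set as round-half-up(fraction × n) — 12,196 pairs at 10% gives
exactly 1,220 — sorts by dN descending, and breaks boundary ties by id.
Enrichment is the one-sided hypergeometric upper tail on the 2×2 table
(test-set members with the term vs reference members with the term),
significant at a single-test p < 0.05 with no multiple-testing
correction; a two-sided Fisher variant is available by flag. The
fast×DE intersection preserves the up/down split per contrast and also
reports the union across contrasts.

## DE and co-expression

DE calls require BH-adjusted p < 0.05 (strict) and |log2FC| ≥ 1
(inclusive); when adjusted p-values are absent they are computed from
the raw ones over the supplied list. BH is the `statsmodels` step-up
implementation, verified in tests against a hand-written textbook
oracle. The correlation graph is Pearson on log2(x+1) values, edge iff
|r| ≥ threshold, weight |r|; zero-variance genes are dropped with a
warning. Hubs are nodes in the top ⌈fraction·n⌉ of both degree and
unnormalized Brandes betweenness (components handled independently,
endpoints excluded), with boundary ties included so results are
order-independent; a union-mode flag relaxes AND to OR. Module
enrichment is the same one-sided hypergeometric test with all
module-assigned genes as background. Soft thresholding, topological
overlap and dynamic tree cutting are explicitly out of scope: module
labels may be supplied from an external WGCNA run.

## Synthetic data: what is emulated, and what is not

One integer seed drives an independent named stream per generator, so
adding a generator never perturbs another and equal seeds give
byte-identical outputs.

**Genome.** One contig (default 160 kbp) with 24 host genes of 2–5
codon-aligned exons, intron lengths 80–600 bp, intergenic gaps
200–800 bp, both strands; CDSs start ATG, end at a stop, and draw sense
codons from a fixed exponentially skewed usage distribution so that
codon-bias-based filtering has signal. A 4-gene intronless cluster with
CDSs of 310–380 codons and 120–300 bp internal gaps sits mid-contig —
sized so its span always falls inside the 4–14 kbp GTA window — with
host genes on both flanks. The two predicted gene sets derive from the
truth by planted perturbations (20% split in two, 20% truncated with
completeness reduced accordingly, 15% missed by the ab initio
predictor, the HGT genes homology-missed), chosen so reconciliation has
a known correct answer. Repeat families (5 families, 100–400 bp) are
overwritten into introns and intergenic gaps — insertion point chosen
uniformly along the eligible DNA, so longer introns accumulate more
copies — without shifting coordinates and without overlapping one
another; partial copies arise naturally when a family is longer than its
target interval. Not emulated: sequencing error, heterozygosity in the
assembly itself, nested/decayed repeats, alternative splicing, UTRs.

**Hit tables.** Subjects are substitution-mutated copies of each query
protein at controlled divergence, with identity and bitscore set
consistently (bitscore ≈ 2 × length × identity). Host genes get
metazoan-topped lists (coral hits nearest) plus distant bacterial hits;
planted HGT genes get bacterial-topped lists across three phyla, with
eight Proteobacteria hits so the per-phylum cap of 6 demonstrably
binds, and distant metazoan hits. No indels, no paralogy, no chimeras.

**SNPs.** Alt counts are Binomial(depth = 30, p = 0.5) at heterozygous
sites (clamped to show both alleles), with an optional haploid fraction
at p = 1 as a negative control. The default 50,000 sites are a
down-sample of the million-SNP scale of a real assembly check, sized so
the spectrum's central bin is stable against multinomial noise across
seeds; depth variation, mapping bias and linkage are not modeled.

**Expression.** The sample layout mirrors a 21-library stress study:
3 baselines plus {ambient, high-CO2, heated} × {1 h, 6 h} × 3
replicates. Counts are negative binomial (var = μ + 0.02·μ²,
baselines 2^7–2^10) — dispersion at the technical-replicate end of the
RNA-seq range, appropriate for clonal nubbins in controlled tanks and
for a planted-effect generator whose recovery contract (below) uses a
plain t-test rather than a shrinkage estimator. 100 planted DE genes
shift by ±3 log2 units in the heated samples. Four correlation modules
of 25 genes each follow one latent factor per module; the factor is
standardized to unit sample variance and member noise is made
sample-orthogonal to it at exactly its nominal sd (loadings 0.85–0.95,
noise sd 0.45, hub loading 1.0 with sd 0.05). That construction pins the
realized hub–member correlations to their design values instead of the
luck of a 21-sample draw — with so few samples, raw latent draws let a
"hot" module's members outrank another module's hub — and it is
calibrated for an edge threshold of 0.8 (`coexpression_edge_threshold`),
at which chance correlations between unrelated genes essentially never
produce edges. The per-contrast statistics shipped with the counts are a
log2(x+1) two-group pooled t-test with BH — fixture machinery so the DE
filter is exercisable end to end, *not* a DESeq2 claim; the null type-I
rate quoted by tests and the acceptance script is the raw p < 0.05 rate,
which is the quantity a t-test calibrates.

What passing the planted-truth suites shows: the *rules* (merge,
filters, rankings, hallmarks, hub definition) are implemented correctly
and recover clean planted signals. What it does not show: robustness to
the noise real data adds — misassembly, annotation error, paralogy,
batch effects, overdispersion beyond NB — none of which the generators
model.

## Problem sizes and determinism

The test suite and acceptance script run on one CPU in a few minutes:
genomes of 160 kbp / 28 genes, proteomes of 30–60 proteins, graphs up to
60 nodes for exact betweenness oracles, 10–20 seeds per planted-truth
suite, 12,196 simulated dN values for set sizing, and 1,000-term null
panels for type-I rates. All randomness flows from explicit seeds;
hypothesis-based property tests are derandomized. Every brute-force
oracle (exhaustive alignment enumeration, BFS path counting,
hypergeometric summation, textbook BH, literal merge-rule application,
independent NG86 tally) lives in the test tree and shares no code with
the implementation it checks.
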