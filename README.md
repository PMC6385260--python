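# genomescape

Desk-scale, tested re-implementations of the bespoke computational steps
behind a coral (*Montipora capitata*-style) genome project: assembly QC,
gene-model reconciliation, repeat landscape analytics, phylogenomic
screening for horizontal gene transfer (HGT) with gene-transfer-agent
(GTA) hallmark scoring, a dN-ranked diversifying-selection scan, and
differential-expression / co-expression hub analysis. Every stage is
exercisable on synthetic data with planted ground truth, so the whole
pipeline can be validated without downloading a genome.

The audience is genome-project bioinformaticians who need the *glue*
analyses — the merge rules, filters, rankings and counts that sit between
the big external tools (assemblers, aligners, DESeq2, RepeatModeler) —
as reusable, auditable library functions rather than one-off scripts.

## What's inside

| module | core operations |
| --- | --- |
| `sequtil` | global-alignment identity, Cd-hit-style greedy clustering, alignment trimming/concatenation, neighbor joining |
| `assembly_qc` | genome size from coverage, SNP allele-frequency spectrum, haplotig scan, WGD cluster-size spectrum |
| `gene_models` | ab initio x homology gene-model reconciliation, completeness, codon-usage/stop/repeat filtering, orthogroup fold changes and Venn partitions |
| `repeats` | repeat-family dedupe (85% identity), unknown-family protein filter, masked-fraction, intron/exon/UTR/intergenic compartments, repeat-vs-intron-length correlation |
| `hgt_screen` | metazoan top-hit prefilter, taxon-capped representative selection, midpoint-rooted sister-clade provenance calls, GTA hallmark scoring |
| `selection_scan` | protein-guided codon back-translation, gap-codon stripping, Nei–Gojobori dN/dS, top-10% ranking, Fisher GO enrichment, fast×DE intersection |
| `de_network` | BH adjustment, FDR/log2FC DE filter, correlation graphs, degree+betweenness hub detection, module enrichment |
| `synthetic_data` | seeded generators for genomes, hit tables, SNPs and expression, each carrying its planted truth |

## The statistics, briefly

**Gene-model merge.** For each homology model *H*: if ≥2 mutually
non-overlapping ab initio models overlap *H*, emit *H* (they were
fragments); if exactly one ab initio model *A* shares the locus, emit *H*
only when completeness(*H*) − completeness(*A*) > 0.05; if nothing
overlaps, *H* is a novel gene. Untouched ab initio models pass through.

**NG86 dN/dS.** Per codon, each position contributes its fraction of
synonymous single-nucleotide changes to the synonymous site count *S*
(averaged over both sequences); multi-hit codons average substitution
counts over all stop-free mutational pathways. With proportions
*p<sub>N</sub>* = N<sub>d</sub>/N and *p<sub>S</sub>* = S<sub>d</sub>/S, the
Jukes–Cantor correction *d* = −(3/4)·ln(1 − (4/3)·p) gives dN and dS; dS
is undefined at *p<sub>S</sub>* ≥ 3/4. Fast-evolving proteins are the top
10% by dN alone (round-half-up), because dS is unstable between closely
related genomes.

**HGT provenance.** Gene trees are midpoint-rooted; the non-query leaves
of the query's smallest containing clade are its sister group. An
all-non-metazoan sister calls the gene non-metazoan; an all-metazoan
sister calls it metazoan; mixed is ambiguous. Candidate clusters are
scored against four GTA hallmarks: span within 4–14 kbp, no introns,
physical contiguity, metazoan genes on both flanks.

**Hubs.** In the co-expression graph (edge iff |Pearson r| ≥ threshold on
log2(x+1) values), hubs are nodes in the top ⌈10%⌉ of *both* degree and
unnormalized Brandes betweenness, boundary ties included.

## Worked example

`examples/04_hgt_screen.py` generates a ~160 kbp synthetic contig with 24
host genes and one planted intronless bacterial 4-gene cluster, then runs
the full screen:

```
queries surviving the metazoan top-hit prefilter: 4
  hgt1: non_metazoan (sister: hgt1|prot1, ...)
  hgt2: non_metazoan (sister: hgt2|prot3, ...)
  hgt3: non_metazoan (sister: hgt3|prot2, ...)
  hgt4: non_metazoan (sister: hgt4|prot4, ...)
candidate cluster ('hgt1', 'hgt2', 'hgt3', 'hgt4') on contig1, span 4,606 bp
  span_in_range: pass
  all_intronless: pass
  contiguous: pass
  metazoan_flanks: pass
  hallmarks passed: 4/4
planted cluster: ('hgt1', 'hgt2', 'hgt3', 'hgt4')
```

All 24 host genes are removed by the prefilter (their best hits are
metazoan); the four planted genes survive, their trees place them inside
bacteria, and the cluster passes all four GTA hallmarks — exactly the
planted truth, with no false positives. The other `examples/*.py` scripts
walk the remaining capabilities the same way, one per stage.

## Scope

External tools are inputs, not dependencies: assemblies, hit tables
(BLAST outfmt-6 extended with taxonomy columns), alignments, trees,
DESeq2 statistics and module assignments are read from standard formats.
The package deliberately does not re-implement read mapping, gene
prediction, repeat discovery, ML tree inference, DESeq2's model, or
WGCNA's module detection. See `docs/methods.md` for the model
assumptions, parameter defaults, and known limitations.
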