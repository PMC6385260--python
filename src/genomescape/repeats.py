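"""Repeat-library curation and repeat landscape analytics.

Covers the post-discovery steps of a repeat annotation: collapsing
near-duplicate consensus families, dropping "unknown" families that hit a
protein database (likely unmasked genes), measuring the repeat-masked
fraction of the assembly, assigning each repeat copy to a genomic
compartment (intron / exon / UTR / intergenic), and testing whether
repeat prevalence per gene tracks intron length — the signature of
intron-hosted repeat families such as the coral-specific SCORs.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, replace

from scipy import stats

from .errors import CoordinateError, DegenerateInputError
from .gene_models import GeneModel
from .sequtil import SeqRecord, greedy_cluster


@dataclass(frozen=True)
class RepeatFamily:
    id: str
    consensus: SeqRecord
    classification: str = "unknown"  # e.g. 'LTR', 'DNA', 'unknown'

    @property
    def length(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class RepeatHit:
    family_id: str
    contig: str
    start: int  # 1-based inclusive
    end: int
    compartment: str = "unassigned"

    def __post_init__(self):
        if self.start > self.end or self.start < 1:
            raise CoordinateError(f"bad repeat hit ({self.start},{self.end})")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def dedupe_repeat_families(
    families: list[RepeatFamily], identity_cutoff: float = 0.85,
    min_coverage: float = 0.7,
) -> list[RepeatFamily]:
    """Collapse families whose consensi cluster at the identity cutoff.

    The longest consensus of each cluster is retained. Idempotent.
    """
    by_id = {f.id: f for f in families}
    seqs = [replace(f.consensus, id=f.id) for f in families]
    clusters = greedy_cluster(seqs, identity_cutoff, min_coverage)
    kept = sorted(c.representative for c in clusters)
    return [by_id[k] for k in kept]


def filter_unknown_families(
    families: list[RepeatFamily], protein_hits: set[str]
) -> list[RepeatFamily]:
    """Drop 'unknown' families with a protein-database hit.

    Classified families are kept regardless (a transposase hit on an LTR
    family is expected, not evidence of a mis-called gene).
    """
    known_ids = {f.id for f in families}
    stray = protein_hits - known_ids
    if stray:
        warnings.warn(f"protein hits for unknown family ids ignored: {sorted(stray)}")
    return [
        f
        for f in families
        if not (f.classification == "unknown" and f.id in protein_hits)
    ]


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def repeat_genome_fraction(
    hits: list[RepeatHit],
    assembly_length: int,
    contig_lengths: dict[str, int] | None = None,
) -> tuple[int, float]:
    """Union length of repeat hits and its fraction of the assembly.

    Overlapping hits are counted once. When contig lengths are supplied,
    hits running past a contig end raise an error.
    """
    if assembly_length <= 0:
        raise ValueError("assembly_length must be positive")
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        if contig_lengths is not None:
            clen = contig_lengths.get(h.contig)
            if clen is not None and h.end > clen:
                raise CoordinateError(
                    f"hit {h.family_id} ends at {h.end} > contig {h.contig} ({clen} bp)"
                )
        by_contig.setdefault(h.contig, []).append((h.start, h.end))
    masked = sum(
        e - s + 1
        for ivals in by_contig.values()
        for s, e in _merge_intervals(ivals)
    )
    return masked, masked / assembly_length


@dataclass(frozen=True)
class CompartmentSummary:
    hits: list[RepeatHit]  # with compartments filled in
    counts: dict[str, int]  # compartment -> hits
    per_family: dict[str, dict[str, int]]
    genes_with_intronic_hits: int


def annotate_compartments(
    hits: list[RepeatHit],
    genes: list[GeneModel],
    utr_annotations: dict[str, list[tuple[int, int]]] | None = None,
) -> CompartmentSummary:
    """Label each hit by the compartment holding its midpoint.

    A midpoint inside a gene extent falls in an exon or an intron of that
    gene; UTR labels are used only when UTR intervals are supplied
    (otherwise UTR space counts with exons). Anything outside every gene
    is intergenic. A hit straddling a boundary gets the single label of
    its midpoint.
    """
    utr_annotations = utr_annotations or {}
    genes_by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_contig.setdefault(g.contig, []).append(g)
    labeled: list[RepeatHit] = []
    genes_with_intronic: set[str] = set()
    for h in hits:
        mid = h.midpoint
        label = "intergenic"
        for g in genes_by_contig.get(h.contig, []):
            if not (g.start <= mid <= g.end):
                continue
            in_utr = any(s <= mid <= e for s, e in utr_annotations.get(g.id, []))
            if in_utr:
                label = "utr"
            elif any(s <= mid <= e for s, e in g.exons):
                label = "exon"
            else:
                label = "intron"
                genes_with_intronic.add(g.id)
            break
        labeled.append(replace(h, compartment=label))
    counts = Counter(h.compartment for h in labeled)
    per_family: dict[str, dict[str, int]] = {}
    for h in labeled:
        per_family.setdefault(h.family_id, Counter())[h.compartment] += 1
    assert sum(counts.values()) == len(hits)
    return CompartmentSummary(
        hits=labeled,
        counts=dict(counts),
        per_family={k: dict(v) for k, v in per_family.items()},
        genes_with_intronic_hits=len(genes_with_intronic),
    )


def scor_intron_correlation(
    gene_stats: list[tuple[int, int]],
) -> tuple[float, float]:
    """Spearman rank correlation of (total intron length, repeat copies).

    Returns (rho, two-sided p). Raises on constant input, where the rank
    correlation is undefined.
    """
    if len(gene_stats) < 3:
        raise DegenerateInputError("need at least 3 genes")
    lengths = [x for x, _ in gene_stats]
    counts = [y for _, y in gene_stats]
    if len(set(lengths)) == 1 or len(set(counts)) == 1:
        raise DegenerateInputError("constant input; correlation undefined")
    res = stats.spearmanr(lengths, counts)
    return float(res.statistic), float(res.pvalue)


def read_repeat_hits_bed(path) -> list[RepeatHit]:
    """BED (0-based half-open): contig, start, end, family_id."""
    import pandas as pd

    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["contig", "start", "end", "family_id"],
    )
    return [
        RepeatHit(str(r.family_id), str(r.contig), int(r.start) + 1, int(r.end))
        for r in df.itertuples()
    ]


def write_repeat_hits_bed(hits: list[RepeatHit], path) -> None:
    lines = [
        f"{h.contig}\t{h.start - 1}\t{h.end}\t{h.family_id}" for h in hits
    ]
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)
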