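"""Lineage-specific HGT screening and GTA-hallmark scoring.

The screen looks for genes acquired horizontally from non-metazoan (here,
bacterial) donors: queries whose best database hit is metazoan are removed
up front; survivors get a taxonomically balanced set of representative
subjects, a gene tree, and an automated provenance call based on the
composition of the query's sister clade. Candidate genes are then scored
against the hallmarks of a gene-transfer-agent (GTA) mediated insertion:
a 4–14 kbp span, absence of spliceosomal introns, physical contiguity,
and host (metazoan) genes on both flanks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    MissingGeneError,
    MultiContigError,
    QueryNotInTreeError,
)
from .gene_models import GeneModel
from .sequtil import SeqRecord, nj_tree, pairwise_identity


@dataclass(frozen=True)
class HomologyHit:
    """One query->subject similarity record with subject taxonomy."""

    query_id: str
    subject_id: str
    bitscore: float
    identity: float  # percent
    align_len: int  # aa
    phylum: str
    is_metazoan: bool
    is_coral: bool = False

    def __post_init__(self):
        if self.is_coral and not self.is_metazoan:
            raise ValueError("a coral subject must be metazoan")
        if not (0 < self.identity <= 100):
            raise ValueError("identity must be in (0, 100]")


def group_hits_by_query(hits: list[HomologyHit]) -> dict[str, list[HomologyHit]]:
    """Hits per query, sorted by bitscore desc (ties: subject id asc)."""
    grouped: dict[str, list[HomologyHit]] = {}
    for h in hits:
        grouped.setdefault(h.query_id, []).append(h)
    for q in grouped:
        grouped[q].sort(key=lambda h: (-h.bitscore, h.subject_id))
    return grouped


def prefilter_queries(hits_by_query: dict[str, list[HomologyHit]]) -> list[str]:
    """Queries whose top hit is non-metazoan; hitless queries are dropped."""
    return sorted(
        q for q, hits in hits_by_query.items()
        if hits and not hits[0].is_metazoan
    )


def select_representatives(
    hits: list[HomologyHit],
    per_phylum_cap: int = 6,
    min_align_len: int = 200,
) -> list[HomologyHit]:
    """Two first-come-first-served taxon-capped sweeps, then their union.

    Sweep 1 scans by bitscore (desc), accepting a hit while its phylum has
    fewer than ``per_phylum_cap`` accepted. Sweep 2 restricts to hits with
    alignment length >= ``min_align_len``, re-sorts by identity (desc), and
    repeats the capped scan. The union is deduplicated preserving
    first-seen order, so the globally best-scoring hit is always included.
    """

    def fcfs(ordered: list[HomologyHit]) -> list[HomologyHit]:
        taken: dict[str, int] = {}
        out = []
        for h in ordered:
            if taken.get(h.phylum, 0) < per_phylum_cap:
                taken[h.phylum] = taken.get(h.phylum, 0) + 1
                out.append(h)
        return out

    set1 = fcfs(sorted(hits, key=lambda h: (-h.bitscore, h.subject_id)))
    long_enough = [h for h in hits if h.align_len >= min_align_len]
    set2 = fcfs(sorted(long_enough, key=lambda h: (-h.identity, h.subject_id)))
    seen: set[str] = set()
    union = []
    for h in set1 + set2:
        if h.subject_id not in seen:
            seen.add(h.subject_id)
            union.append(h)
    return union


@dataclass(frozen=True)
class ProvenanceCall:
    call: str  # 'non_metazoan' | 'metazoan' | 'ambiguous'
    sister_leaves: tuple[str, ...]


def classify_provenance(
    newick: str, query_leaf: str, is_metazoan: dict[str, bool]
) -> ProvenanceCall:
    """Call the query's origin from the composition of its sister clade.

    The (unrooted) gene tree is rooted at its midpoint; the non-query
    leaves of the smallest clade containing the query are its sister
    group. A sister of only non-metazoan leaves calls the gene
    non-metazoan, only metazoan leaves calls it metazoan, and a mixed
    sister is ambiguous. The sister leaves are reported so every call can
    be audited. Invariant to rotations of the newick string.
    """
    import io

    from skbio import TreeNode

    tree = TreeNode.read(io.StringIO(newick))
    for node in tree.traverse():
        if node.length is None:
            node.length = 0.0 if node.is_root() else 1.0
    tips = list(tree.tips())
    if len(tips) < 3:
        raise QueryNotInTreeError("tree must have at least 3 leaves")
    rooted = tree.root_at_midpoint()
    query_tips = [t for t in rooted.tips() if t.name == query_leaf]
    if not query_tips:
        raise QueryNotInTreeError(f"query leaf {query_leaf!r} not in tree")
    anc = query_tips[0].parent
    sister = [t.name for t in anc.tips() if t.name != query_leaf]
    while not sister and anc.parent is not None:
        anc = anc.parent
        sister = [t.name for t in anc.tips() if t.name != query_leaf]
    flags = {bool(is_metazoan.get(name, False)) for name in sister}
    if flags == {False}:
        call = "non_metazoan"
    elif flags == {True}:
        call = "metazoan"
    else:
        call = "ambiguous"
    return ProvenanceCall(call=call, sister_leaves=tuple(sorted(sister)))


@dataclass(frozen=True)
class HgtCandidate:
    gene_ids: tuple[str, ...]  # ordered along the contig
    contig: str
    span: int  # bp, first gene start -> last gene end
    intron_counts: tuple[int, ...]
    flank_left: str | None  # provenance of nearest non-candidate genes
    flank_right: str | None
    provenance_call: str
    criteria: dict[str, bool]
    expressed: dict[str, tuple[float, bool]] = field(default_factory=dict)

    @property
    def n_criteria_passed(self) -> int:
        return sum(self.criteria.values())


def gta_hallmarks(
    candidate_ids: list[str],
    contig_genes: list[GeneModel],
    provenance: dict[str, str],
    span_range: tuple[int, int] = (4000, 14000),
) -> HgtCandidate:
    """Score a candidate gene cluster against the four GTA hallmarks.

    (1) span within ``span_range`` (GTA particles package ~4–14 kbp),
    (2) every candidate gene intronless (single exon),
    (3) candidates physically contiguous (no host gene interleaved),
    (4) the nearest non-candidate gene on each side exists and is of
        metazoan provenance.
    """
    by_id = {g.id: g for g in contig_genes}
    missing = [c for c in candidate_ids if c not in by_id]
    if missing:
        raise MissingGeneError(f"candidate genes absent from contig set: {missing}")
    cand = [by_id[c] for c in candidate_ids]
    contigs = {g.contig for g in cand}
    if len(contigs) != 1:
        raise MultiContigError(f"candidates span contigs {sorted(contigs)}")
    contig = contigs.pop()
    ordered = sorted(
        (g for g in contig_genes if g.contig == contig),
        key=lambda g: (g.start, g.id),
    )
    cand_sorted = sorted(cand, key=lambda g: (g.start, g.id))
    cand_ids = {g.id for g in cand}
    span = cand_sorted[-1].end - cand_sorted[0].start + 1
    idx = {g.id: i for i, g in enumerate(ordered)}
    first, last = idx[cand_sorted[0].id], idx[cand_sorted[-1].id]
    contiguous = all(g.id in cand_ids for g in ordered[first : last + 1])
    left = ordered[first - 1] if first > 0 else None
    right = ordered[last + 1] if last + 1 < len(ordered) else None
    flank_left = provenance.get(left.id) if left else None
    flank_right = provenance.get(right.id) if right else None
    criteria = {
        "span_in_range": span_range[0] <= span <= span_range[1],
        "all_intronless": all(g.n_exons == 1 for g in cand),
        "contiguous": contiguous,
        "metazoan_flanks": flank_left == "metazoan" and flank_right == "metazoan",
    }
    return HgtCandidate(
        gene_ids=tuple(g.id for g in cand_sorted),
        contig=contig,
        span=span,
        intron_counts=tuple(g.n_exons - 1 for g in cand_sorted),
        flank_left=flank_left,
        flank_right=flank_right,
        provenance_call="non_metazoan",
        criteria=criteria,
    )


def hgt_expression_lookup(
    gene_ids: list[str], counts
) -> dict[str, tuple[float, bool]]:
    """Mean normalized count and an expressed flag (mean > 0) per gene.

    ``counts`` is a pandas DataFrame with genes as the index.
    """
    out = {}
    for gid in gene_ids:
        if gid not in counts.index:
            raise MissingGeneError(f"{gid} absent from counts matrix")
        mean = float(np.asarray(counts.loc[gid], dtype=float).mean())
        out[gid] = (mean, mean > 0)
    return out


# ---------------------------------------------------------------------------
# end-to-end screen


@dataclass
class ScreenResult:
    calls: dict[str, ProvenanceCall]  # per candidate query
    provenance: dict[str, str]  # per gene (incl. prefiltered hosts)
    candidates: list[HgtCandidate]  # non-metazoan clusters, hallmark-scored


def run_screen(
    genes: list[GeneModel],
    proteins: dict[str, SeqRecord],
    hits: list[HomologyHit],
    subject_seqs: dict[str, SeqRecord],
    counts=None,
    per_phylum_cap: int = 6,
    min_align_len: int = 200,
    span_range: tuple[int, int] = (4000, 14000),
) -> ScreenResult:
    """Run the full screen: prefilter, representatives, tree, hallmarks.

    Trees are neighbor-joining on global-alignment p-distances between the
    query protein and its representative subjects; production runs may
    substitute externally built trees via :func:`classify_provenance`.
    """
    by_query = group_hits_by_query(hits)
    candidates = prefilter_queries(by_query)
    provenance: dict[str, str] = {}
    for g in genes:
        qhits = by_query.get(g.id)
        if not qhits:
            provenance[g.id] = "unknown"
        elif qhits[0].is_metazoan:
            provenance[g.id] = "metazoan"
    calls: dict[str, ProvenanceCall] = {}
    for q in candidates:
        reps = select_representatives(
            by_query[q], per_phylum_cap=per_phylum_cap, min_align_len=min_align_len
        )
        leaf_seqs = [proteins[q]] + [subject_seqs[h.subject_id] for h in reps]
        ids = [q] + [h.subject_id for h in reps]
        n = len(ids)
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ident, _ = pairwise_identity(leaf_seqs[i], leaf_seqs[j])
                dist[i, j] = dist[j, i] = 1.0 - ident
        newick = nj_tree(dist, ids)
        taxonomy = {h.subject_id: h.is_metazoan for h in reps}
        call = classify_provenance(newick, q, taxonomy)
        calls[q] = call
        provenance[q] = call.call
    results: list[HgtCandidate] = []
    by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    for contig, contig_genes in sorted(by_contig.items()):
        ordered = sorted(contig_genes, key=lambda g: (g.start, g.id))
        run: list[str] = []
        for g in ordered + [None]:
            if g is not None and provenance.get(g.id) == "non_metazoan":
                run.append(g.id)
                continue
            if run:
                cand = gta_hallmarks(run, ordered, provenance, span_range)
                if counts is not None:
                    cand = HgtCandidate(
                        **{
                            **cand.__dict__,
                            "expressed": hgt_expression_lookup(list(run), counts),
                        }
                    )
                results.append(cand)
                run = []
    return ScreenResult(calls=calls, provenance=provenance, candidates=results)


# ---------------------------------------------------------------------------
# hit-table I/O

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "phylum", "is_metazoan", "is_coral",
]


def read_hit_table(path, min_identity: float | None = None) -> list[HomologyHit]:
    """Extended outfmt-6 TSV with phylum/is_metazoan/is_coral columns.

    ``min_identity`` (percent) applies the upstream search's identity
    floor when the table has not already been filtered.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", names=HIT_COLUMNS, comment="#")
    hits = []
    for r in df.itertuples():
        if min_identity is not None and float(r.pident) < min_identity:
            continue
        hits.append(
            HomologyHit(
                query_id=str(r.qseqid),
                subject_id=str(r.sseqid),
                bitscore=float(r.bitscore),
                identity=float(r.pident),
                align_len=int(r.length),
                phylum=str(r.phylum),
                is_metazoan=_as_bool(r.is_metazoan),
                is_coral=_as_bool(r.is_coral),
            )
        )
    return hits


def write_hit_table(hits: list[HomologyHit], path) -> None:
    lines = []
    for h in hits:
        lines.append(
            "\t".join(
                str(x)
                for x in [
                    h.query_id, h.subject_id, f"{h.identity:.2f}", h.align_len,
                    0, 0, 1, h.align_len, 1, h.align_len, "1e-10",
                    f"{h.bitscore:.1f}", h.phylum, int(h.is_metazoan),
                    int(h.is_coral),
                ]
            )
        )
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "t", "yes")
    return bool(int(v))
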