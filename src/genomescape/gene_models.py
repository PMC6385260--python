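"""Gene-model reconciliation and gene-family statistics.

The reconciliation merges two predicted gene sets — an ab initio set and a
homology-based set — giving priority to the ab initio models. For each
homology model H, in order:

(a) if two or more mutually non-overlapping ab initio models overlap H,
    the ab initio models are taken to be fragments of one locus: H is
    emitted and those ab initio models are consumed;
(b) if exactly one ab initio model A shares the locus, H replaces A only
    when its completeness (alignment coverage of a reference homolog)
    exceeds A's by more than ``min_completeness_gain``;
(c) a homology model overlapping nothing is added as a novel gene.

Ab initio models never consumed by (a)/(b) pass through unchanged. Every
decision is logged so the merged annotation can be audited gene by gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .errors import (
    CoordinateError,
    DuplicateIdError,
    EmptySequenceError,
    MissingCompletenessError,
    SpeciesMismatchError,
    UndefinedFoldError,
)
from .sequtil import SeqRecord, _gapped_rows, _first_residue, _last_residue

STOP_CODONS = {"TAA", "TAG", "TGA"}

_CODON_TABLE = {}


def _build_codon_table():
    from Bio.Data.CodonTable import standard_dna_table

    _CODON_TABLE.update(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        _CODON_TABLE[stop] = "*"


_build_codon_table()

SENSE_CODONS = sorted(c for c, aa in _CODON_TABLE.items() if aa != "*")


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard code; '*' marks stops."""
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    return "".join(_CODON_TABLE.get(cds[i : i + 3], "X") for i in range(0, len(cds), 3))


@dataclass(frozen=True)
class GeneModel:
    """A stranded, exon-structured gene prediction on one contig.

    Exons are 1-based inclusive (start, end) pairs, sorted and
    non-overlapping. ``source`` records the predictor ('abinitio' or
    'homology'); ``completeness`` is reference-homolog coverage in [0, 1].
    """

    id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    source: str = "abinitio"
    completeness: float | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        last_end = 0
        for s, e in exons:
            if s > e or s < 1:
                raise CoordinateError(f"{self.id}: bad exon ({s},{e})")
            if s <= last_end:
                raise CoordinateError(f"{self.id}: exons overlap or unsorted")
            last_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> list[tuple[int, int]]:
        """1-based inclusive intron intervals between consecutive exons."""
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        ]

    def total_intron_length(self) -> int:
        return sum(e - s + 1 for s, e in self.introns())

    def overlaps(self, other: "GeneModel") -> bool:
        """Gene-extent overlap: same contig, same strand, spans intersect."""
        return (
            self.contig == other.contig
            and self.strand == other.strand
            and self.start <= other.end
            and other.start <= self.end
        )


def extract_cds(model: GeneModel, contig_seq: str) -> str:
    """Spliced CDS of a model from its contig sequence (+/- strand aware)."""
    parts = [contig_seq[s - 1 : e] for s, e in model.exons]
    cds = "".join(parts)
    if model.strand == "-":
        cds = revcomp(cds)
    return cds.upper()


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# reconciliation


def locus_overlap_graph(
    abinitio: list[GeneModel], homology: list[GeneModel]
) -> dict[str, list[str]]:
    """Map each homology model id to its overlapping ab initio model ids.

    Overlap = same contig, same strand, gene extents intersect by >=1 bp.
    Partners are listed sorted by start (ties by id).
    """
    ids = [m.id for m in abinitio] + [m.id for m in homology]
    if len(set(ids)) != len(ids):
        raise DuplicateIdError("model ids must be unique across both sets")
    by_contig: dict[tuple[str, str], list[GeneModel]] = {}
    for a in abinitio:
        by_contig.setdefault((a.contig, a.strand), []).append(a)
    mapping: dict[str, list[str]] = {}
    for h in homology:
        partners = [
            a for a in by_contig.get((h.contig, h.strand), []) if h.overlaps(a)
        ]
        partners.sort(key=lambda a: (a.start, a.id))
        mapping[h.id] = [a.id for a in partners]
    return mapping


class MergeRule(str, Enum):
    FRAGMENT_JOIN = "fragment_join"  # rule (a)
    COMPLETENESS_SWAP = "completeness_swap"  # rule (b), homology wins
    COMPLETENESS_KEEP = "completeness_keep"  # rule (b), ab initio wins
    NOVEL_HOMOLOGY = "novel_homology"  # rule (c)
    PASSTHROUGH = "abinitio_passthrough"


@dataclass(frozen=True)
class MergeDecision:
    emitted: str
    rule: MergeRule
    consumed: tuple[str, ...] = ()


def reconcile_gene_models(
    abinitio: list[GeneModel],
    homology: list[GeneModel],
    min_completeness_gain: float = 0.05,
) -> tuple[list[GeneModel], list[MergeDecision]]:
    """Merge the two gene sets under the fragment/completeness/novel rules.

    Homology models are processed in (contig, start, id) order; ab initio
    models consumed by an earlier decision are no longer available to later
    ones. Returns the merged models and a per-gene provenance log. The
    result is independent of input file ordering.
    """
    overlap = locus_overlap_graph(abinitio, homology)
    a_by_id = {a.id: a for a in abinitio}
    consumed: set[str] = set()
    emitted: list[GeneModel] = []
    log: list[MergeDecision] = []
    h_by_id = {h.id: h for h in homology}
    for h in sorted(homology, key=lambda m: (m.contig, m.start, m.id)):
        partners = [p for p in overlap[h.id] if p not in consumed]
        if len(partners) >= 2 and _has_disjoint_pair(partners, a_by_id):
            emitted.append(h)
            consumed.update(partners)
            log.append(MergeDecision(h.id, MergeRule.FRAGMENT_JOIN, tuple(partners)))
        elif len(partners) >= 1:
            # single locus partner; with >=2 mutually overlapping partners the
            # longest-extent one stands for the locus
            a = max((a_by_id[p] for p in partners), key=lambda m: (m.span, m.id))
            if h.completeness is None or a.completeness is None:
                raise MissingCompletenessError(
                    f"completeness required to compare {h.id} with {a.id}"
                )
            others = tuple(p for p in partners if p != a.id)
            if h.completeness - a.completeness > min_completeness_gain:
                emitted.append(h)
                consumed.update(partners)
                log.append(
                    MergeDecision(h.id, MergeRule.COMPLETENESS_SWAP, (a.id,) + others)
                )
            else:
                emitted.append(a)
                consumed.update(partners)
                log.append(
                    MergeDecision(a.id, MergeRule.COMPLETENESS_KEEP, (h.id,) + others)
                )
        else:
            emitted.append(h)
            log.append(MergeDecision(h.id, MergeRule.NOVEL_HOMOLOGY))
    for a in sorted(abinitio, key=lambda m: (m.contig, m.start, m.id)):
        if a.id not in consumed and a.id not in {d.emitted for d in log}:
            emitted.append(a)
            log.append(MergeDecision(a.id, MergeRule.PASSTHROUGH))
    emitted.sort(key=lambda m: (m.contig, m.start, m.id))
    return emitted, log


def _has_disjoint_pair(partner_ids: list[str], a_by_id: dict) -> bool:
    models = [a_by_id[p] for p in partner_ids]
    for i in range(len(models)):
        for j in range(i + 1, len(models)):
            if not models[i].overlaps(models[j]):
                return True
    return False


def compute_completeness(
    model_protein: SeqRecord, reference_homolog: SeqRecord
) -> float:
    """Fraction of the reference homolog covered by the query protein.

    Uses the shared global alignment; completeness = reference residues
    inside the terminal-gap-trimmed window / reference length.
    """
    if not model_protein.residues or not reference_homolog.residues:
        raise EmptySequenceError("empty protein")
    row_q, row_r = _gapped_rows(model_protein.residues, reference_homolog.residues)
    start = max(_first_residue(row_q), _first_residue(row_r))
    end = min(_last_residue(row_q), _last_residue(row_r)) + 1
    if end <= start:
        return 0.0
    covered = sum(1 for i in range(start, end) if row_r[i] != "-")
    return covered / len(reference_homolog)


# ---------------------------------------------------------------------------
# model filtering


def codon_usage_vector(cds_list: list[str]) -> np.ndarray:
    """Relative frequencies of the 61 sense codons pooled over CDSs."""
    counts = dict.fromkeys(SENSE_CODONS, 0)
    for cds in cds_list:
        for i in range(0, len(cds) - len(cds) % 3, 3):
            codon = cds[i : i + 3]
            if codon in counts:
                counts[codon] += 1
    vec = np.array([counts[c] for c in SENSE_CODONS], dtype=float)
    total = vec.sum()
    return vec / total if total else vec


def filter_gene_models(
    cds_by_id: dict[str, str],
    repeat_overlap: dict[str, float] | None = None,
    atypicality_cutoff: float = 0.5,
    max_repeat_overlap: float = 0.5,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Drop models with in-frame stops, atypical codon usage, or repeat hits.

    Atypicality is the Pearson correlation between a gene's 61-sense-codon
    relative-frequency vector and the genome-wide vector; genes with
    r < ``atypicality_cutoff`` are discarded. A model whose CDS overlaps
    the repeat library by >= ``max_repeat_overlap`` of its length is
    discarded as repeat-derived. Returns (kept ids, [(id, reason)]).
    """
    repeat_overlap = repeat_overlap or {}
    genome_vec = codon_usage_vector(list(cds_by_id.values()))
    kept: list[str] = []
    discarded: list[tuple[str, str]] = []
    for gid in sorted(cds_by_id):
        cds = cds_by_id[gid].upper()
        if len(cds) % 3:
            discarded.append((gid, "malformed_cds_length"))
            continue
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if any(c in STOP_CODONS for c in codons[:-1]):
            discarded.append((gid, "in_frame_stop"))
            continue
        if repeat_overlap.get(gid, 0.0) >= max_repeat_overlap:
            discarded.append((gid, "repeat_overlap"))
            continue
        gene_vec = codon_usage_vector([cds])
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(gene_vec, genome_vec)[0, 1]
        if not np.isfinite(r) or r < atypicality_cutoff:
            discarded.append((gid, "atypical_codon_usage"))
            continue
        kept.append(gid)
    return kept, discarded


# ---------------------------------------------------------------------------
# gene-family statistics


@dataclass(frozen=True)
class OrthoFamily:
    family_id: str
    counts: dict[str, int]

    def present_in(self, species: str) -> bool:
        return self.counts.get(species, 0) > 0


@dataclass(frozen=True)
class CladePartition:
    """Named, disjoint species groups; the first is the focal lineage."""

    focal: frozenset[str]
    groups: dict[str, frozenset[str]]  # other named groups

    def all_species(self) -> set[str]:
        out = set(self.focal)
        for g in self.groups.values():
            out |= g
        return out


def family_fold_change(family: OrthoFamily, species_a: str, species_b: str) -> int:
    """floor(count_a / count_b); undefined when the denominator is zero."""
    b = family.counts.get(species_b, 0)
    if b == 0:
        raise UndefinedFoldError(
            f"{family.family_id}: {species_b} has zero members"
        )
    return family.counts.get(species_a, 0) // b


def partition_families(
    families: list[OrthoFamily], partition: CladePartition
) -> dict[str, int]:
    """Venn-style partition of families relative to a focal lineage.

    gains   — present only in the focal clade (lineage-specific families);
    losses  — absent from focal but present in >=2 other named groups
              (the family predates the split, so its absence is a loss);
    shared  — present in focal and in at least one other group;
    other   — absent from focal, present in exactly one other group.
    The four cells are disjoint and sum to the number of families
    containing any partition species.
    """
    needed = partition.all_species()
    for fam in families:
        missing = needed - set(fam.counts)
        if missing:
            raise SpeciesMismatchError(
                f"{fam.family_id}: no counts for {sorted(missing)}"
            )
    cells = {"gains": 0, "losses": 0, "shared": 0, "other": 0, "total": 0}
    for fam in families:
        in_focal = any(fam.present_in(s) for s in partition.focal)
        groups_present = sum(
            1
            for members in partition.groups.values()
            if any(fam.present_in(s) for s in members)
        )
        if not in_focal and groups_present == 0:
            continue
        cells["total"] += 1
        if in_focal and groups_present == 0:
            cells["gains"] += 1
        elif in_focal:
            cells["shared"] += 1
        elif groups_present >= 2:
            cells["losses"] += 1
        else:
            cells["other"] += 1
    return cells


# ---------------------------------------------------------------------------
# GFF3 / TSV I/O


def write_gff3(models: list[GeneModel], path, decisions=None) -> None:
    """Write gene/mRNA/exon features; merge provenance in `merge_rule=`."""
    rule_by_id = {d.emitted: d.rule.value for d in (decisions or [])}
    lines = ["##gff-version 3"]
    for m in sorted(models, key=lambda x: (x.contig, x.start, x.id)):
        attrs = f"ID={m.id}"
        if m.completeness is not None:
            attrs += f";completeness={m.completeness:.4f}"
        if m.id in rule_by_id:
            attrs += f";merge_rule={rule_by_id[m.id]}"
        lines.append(
            "\t".join(
                [m.contig, m.source, "gene", str(m.start), str(m.end), ".",
                 m.strand, ".", attrs]
            )
        )
        mrna_id = f"{m.id}.t1"
        lines.append(
            "\t".join(
                [m.contig, m.source, "mRNA", str(m.start), str(m.end), ".",
                 m.strand, ".", f"ID={mrna_id};Parent={m.id}"]
            )
        )
        for k, (s, e) in enumerate(m.exons, 1):
            for ftype in ("exon", "CDS"):
                lines.append(
                    "\t".join(
                        [m.contig, m.source, ftype, str(s), str(e), ".",
                         m.strand, "0" if ftype == "CDS" else ".",
                         f"ID={mrna_id}.{ftype}{k};Parent={mrna_id}"]
                    )
                )
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def read_gff3(path) -> list[GeneModel]:
    """Read gene models (gene + exon features) from GFF3 via gffutils."""
    import gffutils

    if hasattr(path, "read"):
        data = path.read()
    else:
        with open(path) as fh:
            data = fh.read()
    db = gffutils.create_db(
        data, dbfn=":memory:", from_string=True, merge_strategy="create_unique"
    )
    models = []
    for gene in db.features_of_type("gene"):
        exons = []
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = sorted(
                (f.start, f.end) for f in db.children(mrna, featuretype="exon")
            )
        if not exons:
            exons = [(gene.start, gene.end)]
        attrs = gene.attributes
        completeness = (
            float(attrs["completeness"][0]) if "completeness" in attrs else None
        )
        models.append(
            GeneModel(
                id=gene.id,
                contig=gene.seqid,
                strand=gene.strand,
                exons=tuple(exons),
                source=gene.source,
                completeness=completeness,
            )
        )
    models.sort(key=lambda m: (m.contig, m.start, m.id))
    return models


def read_orthogroup_counts(path) -> list[OrthoFamily]:
    """OrthoFinder Orthogroups.GeneCount.tsv dialect (last 'Total' col ok)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    fam_col = df.columns[0]
    species = [c for c in df.columns[1:] if c.lower() != "total"]
    return [
        OrthoFamily(
            family_id=str(row[fam_col]),
            counts={s: int(row[s]) for s in species},
        )
        for _, row in df.iterrows()
    ]
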