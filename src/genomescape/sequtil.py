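"""Sequence, alignment, clustering and tree primitives shared by the pipeline.

Identity and coverage come from a global dynamic-programming alignment
(match=1, mismatch=0, gap open/extend=-1) rather than a word-filter
heuristic: at the scale this package targets (hundreds to a few thousand
sequences) exact alignment is affordable and makes every downstream
clustering decision reproducible and auditable.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import (
    AlphabetMismatchError,
    DegenerateAlignmentError,
    EmptySequenceError,
    InvalidTreeError,
    TaxonSetMismatchError,
)

NT_ALPHABET = set("ACGTN")
#: characters treated as "missing" when trimming alignments (gap, ambiguous)
MISSING_CHARS = set("-.XN")


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence over a declared alphabet ('nt' or 'aa')."""

    id: str
    residues: str
    description: str = ""
    moltype: str = ""  # 'nt' | 'aa'; inferred from content when empty

    def __post_init__(self):
        if not self.id:
            raise EmptySequenceError("sequence id must be non-empty")
        if not self.residues:
            raise EmptySequenceError(f"sequence {self.id!r} is empty")
        res = self.residues.upper()
        object.__setattr__(self, "residues", res)
        if not self.moltype:
            inferred = "nt" if set(res) <= NT_ALPHABET else "aa"
            object.__setattr__(self, "moltype", inferred)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Cluster:
    """A representative plus its members (representative included)."""

    representative: str
    members: frozenset[str]

    def __post_init__(self):
        if self.representative not in self.members:
            raise ValueError("representative must be a member of its cluster")

    def __len__(self) -> int:
        return len(self.members)


class Alignment:
    """An ordered multiple alignment; rows are (id, gapped residue string)."""

    def __init__(self, rows: list[tuple[str, str]]):
        if len(rows) < 2:
            raise DegenerateAlignmentError("alignment needs at least 2 rows")
        lengths = {len(seq) for _, seq in rows}
        if len(lengths) != 1:
            raise DegenerateAlignmentError("rows differ in length")
        self.rows = [(rid, seq.upper()) for rid, seq in rows]
        self.length = lengths.pop()
        if self.length == 0:
            raise DegenerateAlignmentError("alignment has zero columns")

    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, rid: str) -> str:
        for r, seq in self.rows:
            if r == rid:
                return seq
        raise KeyError(rid)

    def ungapped(self, rid: str) -> str:
        return self.row(rid).replace("-", "").replace(".", "")

    def __len__(self) -> int:
        return self.length

    def __eq__(self, other) -> bool:
        return isinstance(other, Alignment) and self.rows == other.rows


# one shared aligner; scores per the declared identity metric
def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def _gapped_rows(a: str, b: str) -> tuple[str, str]:
    aln = _ALIGNER.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def pairwise_identity(
    a: SeqRecord, b: SeqRecord, mode: str = "global"
) -> tuple[float, float]:
    """Identity and coverage of a global alignment of two sequences.

    Identity is matches / aligned columns, excluding terminal-gap columns.
    Coverage is the fraction of the query's residues lying inside the
    terminal-gap-trimmed window; the query is ``a`` in ``query_cover`` mode
    and the shorter of the two in ``global`` mode (symmetric).
    """
    if a.moltype != b.moltype:
        raise AlphabetMismatchError(
            f"{a.id} is {a.moltype} but {b.id} is {b.moltype}"
        )
    if mode not in ("global", "query_cover"):
        raise ValueError(f"unknown mode {mode!r}")
    row_a, row_b = _gapped_rows(a.residues, b.residues)
    n = len(row_a)
    # trim terminal gaps: window where both sequences have started/not ended
    start = max(_first_residue(row_a), _first_residue(row_b))
    end = min(_last_residue(row_a), _last_residue(row_b)) + 1
    if end <= start:  # no overlap at all
        return 0.0, 0.0
    matches = sum(
        1 for i in range(start, end) if row_a[i] == row_b[i] and row_a[i] != "-"
    )
    identity = matches / (end - start)
    query_row = row_a if mode == "query_cover" else (
        row_a if len(a) <= len(b) else row_b
    )
    query_len = len(a) if query_row is row_a else len(b)
    in_window = sum(1 for i in range(start, end) if query_row[i] != "-")
    coverage = in_window / query_len
    assert 0 <= n
    return identity, coverage


def _first_residue(row: str) -> int:
    return len(row) - len(row.lstrip("-"))


def _last_residue(row: str) -> int:
    return len(row.rstrip("-")) - 1


def greedy_cluster(
    seqs: list[SeqRecord], identity_cutoff: float, min_coverage: float
) -> list[Cluster]:
    """Greedy length-ordered clustering against cluster representatives.

    Sequences are visited longest-first (ties by id); each joins the first
    existing cluster whose representative it matches at >=identity_cutoff
    and >=min_coverage (coverage of the incoming, shorter sequence), else it
    founds a new cluster. Deterministic by construction.
    """
    if not (0 < identity_cutoff <= 1) or not (0 < min_coverage <= 1):
        raise ValueError("cutoff and coverage must be in (0, 1]")
    if not seqs:
        return []
    ordered = sorted(seqs, key=lambda s: (-len(s), s.id))
    reps: list[SeqRecord] = []
    members: list[list[str]] = []
    for seq in ordered:
        for idx, rep in enumerate(reps):
            if seq.id == rep.id:
                continue
            ident, cov = pairwise_identity(seq, rep, mode="query_cover")
            if ident >= identity_cutoff and cov >= min_coverage:
                members[idx].append(seq.id)
                break
        else:
            reps.append(seq)
            members.append([seq.id])
    return [
        Cluster(representative=rep.id, members=frozenset(mem))
        for rep, mem in zip(reps, members)
    ]


def _missing_fraction(chars: list[str]) -> float:
    return sum(1 for c in chars if c in MISSING_CHARS) / len(chars)


def trim_alignment(
    aln: Alignment, max_col_missing: float, max_seq_missing: float
) -> Alignment:
    """Drop high-missing columns, then high-missing rows, to a fixed point.

    Missing = gap characters plus 'X'/'N'. A column is dropped when its
    missing fraction is >= max_col_missing; a row when its missing fraction
    over the retained columns is >= max_seq_missing. Because dropping rows
    can change column fractions, the column/row passes repeat until stable,
    which makes the operation idempotent. Row order is preserved.
    """
    rows = [list(seq) for _, seq in aln.rows]
    ids = aln.ids()
    keep_rows = list(range(len(rows)))
    keep_cols = list(range(aln.length))
    while True:
        new_cols = [
            c
            for c in keep_cols
            if _missing_fraction([rows[r][c] for r in keep_rows]) < max_col_missing
        ]
        new_rows = [
            r
            for r in keep_rows
            if new_cols
            and _missing_fraction([rows[r][c] for c in new_cols]) < max_seq_missing
        ]
        if new_cols == keep_cols and new_rows == keep_rows:
            break
        keep_cols, keep_rows = new_cols, new_rows
        if len(keep_rows) < 2 or not keep_cols:
            raise DegenerateAlignmentError(
                "trimming left fewer than 2 rows or 0 columns"
            )
    return Alignment(
        [(ids[r], "".join(rows[r][c] for c in keep_cols)) for r in keep_rows]
    )


def concatenate_alignments(alns: list[Alignment], min_len: int) -> Alignment:
    """Concatenate per-gene alignments (length >= min_len) over one taxon set."""
    if not alns:
        raise EmptySequenceError("no alignments to concatenate")
    taxa = set(alns[0].ids())
    for i, aln in enumerate(alns):
        if set(aln.ids()) != taxa:
            raise TaxonSetMismatchError(
                f"alignment #{i} taxon set differs from the first"
            )
    retained = [a for a in alns if a.length >= min_len]
    if not retained:
        raise DegenerateAlignmentError("no alignment meets the length cutoff")
    order = retained[0].ids()
    rows = [(t, "".join(a.row(t) for a in retained)) for t in order]
    return Alignment(rows)


def nj_tree(dist: np.ndarray, ids: list[str]) -> str:
    """Neighbor-joining tree (newick, unrooted) from a distance matrix.

    Additive matrices are recovered exactly: tip-to-tip path lengths on the
    returned tree equal the input distances.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise InvalidTreeError("distance matrix must be square")
    if dist.shape[0] < 3:
        raise InvalidTreeError("need at least 3 taxa")
    if not np.allclose(dist, dist.T):
        raise InvalidTreeError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0):
        raise InvalidTreeError("diagonal must be zero")
    tree = nj(DistanceMatrix(dist, ids))
    return str(tree).strip()


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path_or_handle, moltype: str = "") -> list[SeqRecord]:
    """Read FASTA; ids are the first whitespace-delimited token."""
    records = []
    for rec in SeqIO.parse(path_or_handle, "fasta"):
        records.append(
            SeqRecord(
                id=rec.id,
                residues=str(rec.seq),
                description=rec.description,
                moltype=moltype,
            )
        )
    return records


def write_fasta(records: list[SeqRecord], path_or_handle) -> None:
    """Write FASTA wrapped at 80 columns."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description or "")
        for r in records
    ]
    if hasattr(path_or_handle, "write"):
        SeqIO.write(bio, path_or_handle, "fasta")
    else:
        with open(path_or_handle, "w") as fh:
            SeqIO.write(bio, fh, "fasta")


def read_aligned_fasta(path_or_handle) -> Alignment:
    recs = read_fasta(path_or_handle)
    return Alignment([(r.id, r.residues) for r in recs])


def write_aligned_fasta(aln: Alignment, path_or_handle) -> None:
    text = "\n".join(f">{rid}\n{seq}" for rid, seq in aln.rows) + "\n"
    if hasattr(path_or_handle, "write"):
        path_or_handle.write(text)
    else:
        with open(path_or_handle, "w") as fh:
            fh.write(text)


def alignment_from_string(fasta_text: str) -> Alignment:
    return read_aligned_fasta(_io.StringIO(fasta_text))
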