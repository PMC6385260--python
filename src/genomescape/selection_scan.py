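"""Pairwise dN ranking of single-copy orthologs and GO enrichment.

dN/dS ratios are unstable between closely related genomes because dS is
small and noisy there, so fast-evolving proteins are ranked by dN alone.
Rates come from the Nei–Gojobori (1986) counting estimator: per-codon
synonymous/non-synonymous site fractions averaged over the two sequences,
equal-weight averaging over substitution pathways for multi-hit codons
(pathways through stop codons excluded when any stop-free pathway
exists), and a Jukes–Cantor multiple-hit correction per class,
d = -(3/4)·ln(1 - (4/3)p), undefined when p >= 3/4.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations

from scipy.stats import hypergeom

from .errors import (
    EmptyInputError,
    InternalStopError,
    PartialCodonGapError,
    TranslationMismatchError,
)
from .gene_models import STOP_CODONS, _CODON_TABLE, translate_cds
from .sequtil import Alignment, SeqRecord


@dataclass(frozen=True)
class CodonAlignment:
    """Two aligned CDS rows of equal, codon-multiple length."""

    seq_a: str
    seq_b: str

    def __post_init__(self):
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("rows differ in length")
        if len(self.seq_a) % 3:
            raise PartialCodonGapError("length not divisible by 3")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codon_pairs(self):
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


def backtranslate_alignment(
    protein_aln: Alignment, cds_a: SeqRecord, cds_b: SeqRecord
) -> CodonAlignment:
    """Thread each CDS onto its protein alignment row (gaps become '---')."""
    if len(protein_aln.rows) != 2:
        raise ValueError("need a 2-row protein alignment")
    rows = []
    for (rid, prot_row), cds in zip(protein_aln.rows, (cds_a, cds_b)):
        rows.append(_thread_codons(rid, prot_row, cds.residues))
    return CodonAlignment(seq_a=rows[0], seq_b=rows[1])


def _thread_codons(rid: str, prot_row: str, cds: str) -> str:
    ungapped = prot_row.replace("-", "")
    cds = cds.upper()
    if len(cds) == 3 * (len(ungapped) + 1):  # tolerate a terminal stop codon
        if cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
    if len(cds) != 3 * len(ungapped):
        raise TranslationMismatchError(
            f"{rid}: CDS length {len(cds)} does not match protein length "
            f"{len(ungapped)}"
        )
    translated = translate_cds(cds)
    for pos, (aa_cds, aa_prot) in enumerate(zip(translated, ungapped), 1):
        if aa_cds != aa_prot:
            raise TranslationMismatchError(
                f"{rid}: CDS translates to {aa_cds!r} at protein position "
                f"{pos}, alignment row has {aa_prot!r}"
            )
    out = []
    k = 0
    for aa in prot_row:
        if aa == "-":
            out.append("---")
        else:
            out.append(cds[3 * k : 3 * k + 3])
            k += 1
    return "".join(out)


def strip_gap_codons(aln: CodonAlignment) -> CodonAlignment:
    """Remove every codon column gapped in either row.

    Gaps must occupy whole codons ('---'); a partial-codon gap means the
    alignment was not protein-guided and is rejected rather than repaired.
    """
    keep_a, keep_b = [], []
    for ca, cb in aln.codon_pairs():
        for c in (ca, cb):
            if "-" in c and c != "---":
                raise PartialCodonGapError(f"partial-codon gap in {c!r}")
        if ca != "---" and cb != "---":
            keep_a.append(ca)
            keep_b.append(cb)
    return CodonAlignment(seq_a="".join(keep_a), seq_b="".join(keep_b))


@dataclass(frozen=True)
class DnDsResult:
    ka: float | None  # dN; None when the JC correction is undefined
    ks: float | None  # dS; None likewise
    ratio: float | None  # dN/dS; None when dS is undefined or zero
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float


def _syn_fraction(codon: str) -> list[float]:
    """Per-position fraction of single-nucleotide changes that are synonymous."""
    aa = _CODON_TABLE[codon]
    fracs = []
    for pos in range(3):
        syn = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if _CODON_TABLE[alt] == aa:  # a change to a stop is never synonymous
                syn += 1
        fracs.append(syn / 3)
    return fracs


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average (syn, nonsyn) substitutions over all stop-free pathways."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in permutations(diff_pos):
        cur = c1
        steps = []
        via_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _CODON_TABLE[nxt] == "*" and nxt != c2:
                via_stop = True
            steps.append((cur, nxt))
            cur = nxt
        pathways.append((via_stop, steps))
    usable = [steps for via, steps in pathways if not via]
    if not usable:
        usable = [steps for _, steps in pathways]
    syn = nonsyn = 0.0
    for steps in usable:
        for a, b in steps:
            if _CODON_TABLE[a] == _CODON_TABLE[b]:
                syn += 1
            else:
                nonsyn += 1
    n = len(usable)
    return syn / n, nonsyn / n


def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1 - (4 / 3) * p)


def ng86_dnds(aln: CodonAlignment) -> DnDsResult:
    """Nei–Gojobori (1986) dN and dS for a gap-free codon alignment."""
    if aln.n_codons < 1:
        raise EmptyInputError("empty codon alignment")
    s_sites = [0.0, 0.0]
    sd = nd = 0.0
    for ca, cb in aln.codon_pairs():
        for c in (ca, cb):
            if c in STOP_CODONS:
                raise InternalStopError(f"internal stop codon {c}")
        s_sites[0] += sum(_syn_fraction(ca))
        s_sites[1] += sum(_syn_fraction(cb))
        s, n = _pathway_counts(ca, cb)
        sd += s
        nd += n
    S = (s_sites[0] + s_sites[1]) / 2
    N = 3 * aln.n_codons - S
    p_s = sd / S if S > 0 else 0.0
    p_n = nd / N if N > 0 else 0.0
    ks = _jc_correct(p_s) if S > 0 else None
    ka = _jc_correct(p_n)
    ratio = ka / ks if (ka is not None and ks is not None and ks > 0) else None
    return DnDsResult(
        ka=ka, ks=ks, ratio=ratio,
        syn_sites=S, nonsyn_sites=N, syn_diffs=sd, nonsyn_diffs=nd,
    )


@dataclass(frozen=True)
class FastEvolvingSet:
    """Ordered (by dN desc) ids of the fastest-evolving pairs."""

    ids: tuple[str, ...]
    n_ranked: int
    n_excluded: int  # pairs with undefined dN, not ranked

    def __len__(self):
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)

    def __contains__(self, item):
        return item in self.ids


def rank_fast_evolving(
    results: dict[str, DnDsResult], fraction: float = 0.10
) -> FastEvolvingSet:
    """Top ``fraction`` of pairs by dN (round-half-up sizing).

    Pairs with an undefined dN are excluded before sizing and reported.
    Ties at the cutoff are broken by id ascending.
    """
    if not results:
        raise EmptyInputError("no dN/dS results to rank")
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    defined = {pid: r for pid, r in results.items() if r.ka is not None}
    n = len(defined)
    if n == 0:
        raise EmptyInputError("every pair has undefined dN")
    size = int(math.floor(fraction * n + 0.5))
    ordered = sorted(defined, key=lambda pid: (-defined[pid].ka, pid))
    return FastEvolvingSet(
        ids=tuple(ordered[:size]),
        n_ranked=n,
        n_excluded=len(results) - n,
    )


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # test-set genes with the term
    K: int  # test-set size
    n: int  # reference genes with the term
    N: int  # reference size
    p_value: float
    significant: bool


def fisher_enrichment(
    test_annotations: dict[str, set[str]],
    reference_annotations: dict[str, set[str]],
    alpha: float = 0.05,
    two_sided: bool = False,
) -> list[EnrichmentResult]:
    """Per-term one-sided (over-representation) Fisher exact test.

    The 2x2 table contrasts term membership in the test set against the
    reference set; the p-value is the hypergeometric upper tail. No
    multiple-testing correction is applied (single-test convention);
    significance is p < alpha.
    """
    K, N = len(test_annotations), len(reference_annotations)
    terms = set()
    for anns in test_annotations.values():
        terms |= anns
    for anns in reference_annotations.values():
        terms |= anns
    out = []
    for term in sorted(terms):
        k = sum(1 for anns in test_annotations.values() if term in anns)
        n = sum(1 for anns in reference_annotations.values() if term in anns)
        if k + n == 0:
            warnings.warn(f"term {term} annotates no gene; skipped")
            continue
        p = float(hypergeom.sf(k - 1, K + N, k + n, K))
        if two_sided:
            from scipy.stats import fisher_exact

            p = float(
                fisher_exact([[k, K - k], [n, N - n]], alternative="two-sided")[1]
            )
        out.append(
            EnrichmentResult(
                term=term, k=k, K=K, n=n, N=N,
                p_value=p, significant=p < alpha,
            )
        )
    return out


def intersect_fast_de(
    fast_set, de_sets: dict[str, tuple[set[str], set[str]]]
) -> dict[str, dict[str, int]]:
    """Overlap of the fast-evolving set with per-contrast DE up/down sets.

    Returns per-contrast up/down/total counts plus a 'union' entry with
    the number of fast-evolving genes DE in any contrast.
    """
    fast = set(fast_set)
    out: dict[str, dict[str, int]] = {}
    union: set[str] = set()
    for contrast, (up, down) in sorted(de_sets.items()):
        u = fast & set(up)
        d = fast & set(down)
        union |= u | d
        out[contrast] = {"up": len(u), "down": len(d), "total": len(u | d)}
    out["union"] = {"total": len(union)}
    return out


def read_go_annotations(path) -> dict[str, set[str]]:
    """2-column TSV (gene, term) -> gene -> set of terms."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", names=["gene", "term"], comment="#")
    out: dict[str, set[str]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.gene), set()).add(str(r.term))
    return out
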