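"""Independent brute-force oracles used to check the library implementations.

Everything here is written from the operation definitions with the
dumbest correct algorithm available (exhaustive enumeration, direct
summation, explicit counting), deliberately avoiding the code paths and
libraries the package itself uses.
"""

from __future__ import annotations

import math
from itertools import permutations


# ---------------------------------------------------------------------------
# exhaustive global alignment (tiny sequences only)


def enumerate_global_alignments(a: str, b: str):
    """Yield every global alignment of a and b as (gapped_a, gapped_b)."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ra, rb in enumerate_global_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in enumerate_global_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb
    if a and b:
        for ra, rb in enumerate_global_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb


def score_alignment(row_a: str, row_b: str) -> int:
    """match=+1, mismatch=0, every gap column -1 (end gaps included)."""
    score = 0
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            score -= 1
        elif x == y:
            score += 1
    return score


def identity_excluding_terminal_gaps(row_a: str, row_b: str) -> float:
    start = max(
        len(row_a) - len(row_a.lstrip("-")), len(row_b) - len(row_b.lstrip("-"))
    )
    end = min(len(row_a.rstrip("-")), len(row_b.rstrip("-")))
    if end <= start:
        return 0.0
    matches = sum(
        1
        for i in range(start, end)
        if row_a[i] == row_b[i] and row_a[i] != "-"
    )
    return matches / (end - start)


def optimal_alignment_identities(a: str, b: str) -> tuple[int, set[float]]:
    """(best score, set of identities achieved by optimal alignments)."""
    best = -(10**9)
    idents: set[float] = set()
    for ra, rb in enumerate_global_alignments(a, b):
        s = score_alignment(ra, rb)
        if s > best:
            best = s
            idents = {identity_excluding_terminal_gaps(ra, rb)}
        elif s == best:
            idents.add(identity_excluding_terminal_gaps(ra, rb))
    return best, idents


# ---------------------------------------------------------------------------
# clustering / trimming / concatenation


def greedy_cluster_oracle(seqs, identity_fn, cutoff, min_cov):
    """Literal 'first qualifying representative' scan on the sorted input.

    identity_fn(seq, rep) -> (identity, coverage) is supplied by the
    caller so the oracle checks the clustering logic, not the metric.
    """
    ordered = sorted(seqs, key=lambda s: (-len(s.residues), s.id))
    reps, members = [], []
    for seq in ordered:
        placed = False
        for i, rep in enumerate(reps):
            ident, cov = identity_fn(seq, rep)
            if ident >= cutoff and cov >= min_cov:
                members[i].append(seq.id)
                placed = True
                break
        if not placed:
            reps.append(seq)
            members.append([seq.id])
    return [frozenset(m) for m in members]


def trim_oracle(rows, max_col, max_seq, missing="-.XN"):
    """Explicit per-column/per-row counting, iterated to a fixed point."""
    ids = [r[0] for r in rows]
    mat = [list(r[1]) for r in rows]
    keep_r = list(range(len(mat)))
    keep_c = list(range(len(mat[0])))
    while True:
        new_c = []
        for c in keep_c:
            miss = sum(1 for r in keep_r if mat[r][c] in missing)
            if miss / len(keep_r) < max_col:
                new_c.append(c)
        new_r = []
        for r in keep_r:
            if not new_c:
                continue
            miss = sum(1 for c in new_c if mat[r][c] in missing)
            if miss / len(new_c) < max_seq:
                new_r.append(r)
        if new_c == keep_c and new_r == keep_r:
            break
        keep_c, keep_r = new_c, new_r
        if len(keep_r) < 2 or not keep_c:
            return None  # degenerate
    return [(ids[r], "".join(mat[r][c] for c in keep_c)) for r in keep_r]


# ---------------------------------------------------------------------------
# graph centrality


def bfs_betweenness(adj: dict) -> dict:
    """All-pairs BFS path-counting betweenness (unnormalized, endpoints
    excluded, each unordered pair counted once)."""
    nodes = sorted(adj)
    btw = dict.fromkeys(nodes, 0.0)
    dist = {}
    sigma = {}
    for s in nodes:
        d = {s: 0}
        sg = {s: 1}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in sorted(adj[u]):
                    if v not in d:
                        d[v] = d[u] + 1
                        sg[v] = 0
                        nxt.append(v)
                    if d[v] == d[u] + 1:
                        sg[v] += sg[u]
            frontier = nxt
        dist[s] = d
        sigma[s] = sg
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            if t not in dist[s]:
                continue
            for v in nodes:
                if v in (s, t) or v not in dist[s] or v not in dist[t]:
                    continue
                if dist[s][v] + dist[t][v] == dist[s][t]:
                    btw[v] += sigma[s][v] * sigma[t][v] / sigma[s][t]
    return btw


# ---------------------------------------------------------------------------
# exact statistics


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(total=K+N, successes=k+n, draws=K),
    computed by direct summation of binomial coefficients."""
    total, succ = K + N, k + n
    denom = math.comb(total, K)
    p = 0.0
    for i in range(k, min(K, succ) + 1):
        p += math.comb(succ, i) * math.comb(total - succ, K - i) / denom
    return p


def bh_oracle(pvals):
    """Step-up BH exactly as written in textbooks."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pvals[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


# ---------------------------------------------------------------------------
# codon evolution (independent NG86 tally)

_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
CODON_AA = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def ng86_sites_oracle(codon: str) -> float:
    """Synonymous site count of one codon (stop targets non-synonymous)."""
    aa = CODON_AA[codon]
    syn = 0.0
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if CODON_AA[alt] == aa:
                syn += 1 / 3
    return syn


def ng86_diffs_oracle(c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) differences averaged over stop-free pathways."""
    pos = [i for i in range(3) if c1[i] != c2[i]]
    if not pos:
        return 0.0, 0.0
    all_paths, clean_paths = [], []
    for order in permutations(pos):
        cur, steps, stopped = c1, [], False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if CODON_AA[nxt] == "*" and nxt != c2:
                stopped = True
            steps.append((CODON_AA[cur], CODON_AA[nxt]))
            cur = nxt
        all_paths.append(steps)
        if not stopped:
            clean_paths.append(steps)
    paths = clean_paths or all_paths
    syn = sum(1 for st in paths for a, b in st if a == b) / len(paths)
    non = sum(1 for st in paths for a, b in st if a != b) / len(paths)
    return syn, non


def ng86_oracle(seq_a: str, seq_b: str):
    """(Ka, Ks) by the direct NG86 recipe; None when JC is undefined."""
    n_cod = len(seq_a) // 3
    S = 0.0
    sd = nd = 0.0
    for i in range(n_cod):
        ca, cb = seq_a[3 * i : 3 * i + 3], seq_b[3 * i : 3 * i + 3]
        S += (ng86_sites_oracle(ca) + ng86_sites_oracle(cb)) / 2
        s, n = ng86_diffs_oracle(ca, cb)
        sd += s
        nd += n
    N = 3 * n_cod - S

    def jc(p):
        return None if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    ks = jc(sd / S) if S > 0 else None
    ka = jc(nd / N) if N > 0 else None
    return ka, ks


# ---------------------------------------------------------------------------
# gene-model reconciliation (literal rule application)


def overlap_oracle(m1, m2) -> bool:
    return (
        m1.contig == m2.contig
        and m1.strand == m2.strand
        and m1.start <= m2.end
        and m2.start <= m1.end
    )


def reconcile_oracle(abinitio, homology, gain=0.05):
    """Enumerate every homology model and apply the three rules literally."""
    a_by_id = {a.id: a for a in abinitio}
    consumed: set[str] = set()
    emitted: list[str] = []
    for h in sorted(homology, key=lambda m: (m.contig, m.start, m.id)):
        partners = [
            a.id
            for a in sorted(abinitio, key=lambda m: (m.start, m.id))
            if overlap_oracle(h, a) and a.id not in consumed
        ]
        disjoint_pair = any(
            not overlap_oracle(a_by_id[p], a_by_id[q])
            for i, p in enumerate(partners)
            for q in partners[i + 1 :]
        )
        if len(partners) >= 2 and disjoint_pair:
            emitted.append(h.id)
            consumed.update(partners)
        elif partners:
            best = max(
                (a_by_id[p] for p in partners), key=lambda m: (m.span, m.id)
            )
            if h.completeness - best.completeness > gain:
                emitted.append(h.id)
            else:
                emitted.append(best.id)
            consumed.update(partners)
        else:
            emitted.append(h.id)
    for a in abinitio:
        if a.id not in consumed and a.id not in emitted:
            emitted.append(a.id)
    return sorted(emitted)


# ---------------------------------------------------------------------------
# misc


def interval_union_oracle(intervals) -> int:
    """Union length of 1-based inclusive intervals via a boolean array."""
    if not intervals:
        return 0
    hi = max(e for _, e in intervals)
    covered = [False] * (hi + 1)
    for s, e in intervals:
        for i in range(s, e + 1):
            covered[i] = True
    return sum(covered)


def select_representatives_oracle(hits, cap=6, min_len=200):
    def fcfs(ordered):
        taken, out = {}, []
        for h in ordered:
            if taken.get(h.phylum, 0) < cap:
                taken[h.phylum] = taken.get(h.phylum, 0) + 1
                out.append(h)
        return out

    set1 = fcfs(sorted(hits, key=lambda h: (-h.bitscore, h.subject_id)))
    set2 = fcfs(
        sorted(
            (h for h in hits if h.align_len >= min_len),
            key=lambda h: (-h.identity, h.subject_id),
        )
    )
    out, seen = [], set()
    for h in set1 + set2:
        if h.subject_id not in seen:
            seen.add(h.subject_id)
            out.append(h)
    return [h.subject_id for h in out]
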