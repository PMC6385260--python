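"""Assembly-level diagnostics.

Four checks commonly run on a long-read diploid genome assembly:

* genome size inferred from mapped-read volume divided by mean coverage,
* the SNP alt-allele frequency spectrum (a diploid assembly of a single
  genotype peaks at 0.5),
* a scan of self-alignment hits for residual haplotigs (high-identity
  matches between different contigs), and
* the cluster-size spectrum of an all-vs-all proteome clustering, whose
  dominant size distinguishes a duplicated (WGD) proteome (dominant 2)
  from an unduplicated one (dominant 1).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .errors import EmptyInputError, InvalidCoverageError
from .sequtil import Cluster, SeqRecord, greedy_cluster


@dataclass(frozen=True)
class CoverageSummary:
    total_mapped_bases: int
    mean_coverage: float


@dataclass(frozen=True)
class SnpRecord:
    contig: str
    position: int  # 1-based
    ref_count: int
    alt_count: int

    def __post_init__(self):
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("allele counts must be non-negative")
        if self.ref_count + self.alt_count == 0:
            raise ValueError("total depth must be positive")

    @property
    def alt_frequency(self) -> float:
        return self.alt_count / (self.ref_count + self.alt_count)


@dataclass(frozen=True)
class SelfAlignmentHit:
    contig_a: str
    contig_b: str
    identity: float  # percent
    length: int  # bp


@dataclass(frozen=True)
class AfSpectrum:
    counts: np.ndarray
    bin_edges: np.ndarray

    @property
    def modal_bin(self) -> tuple[float, float]:
        """(low, high) edges of the bin holding the most SNPs."""
        i = int(np.argmax(self.counts))
        return float(self.bin_edges[i]), float(self.bin_edges[i + 1])

    def modal_bin_contains(self, freq: float) -> bool:
        lo, hi = self.modal_bin
        last = np.isclose(hi, self.bin_edges[-1])
        return (lo <= freq < hi) or (last and np.isclose(freq, hi)) or (
            last and lo <= freq <= hi
        )


def estimate_genome_size(cov: CoverageSummary) -> int:
    """Genome size = floor(total mapped bases / mean coverage)."""
    if cov.mean_coverage <= 0:
        raise InvalidCoverageError("mean coverage must be > 0")
    return int(cov.total_mapped_bases // cov.mean_coverage)


def allele_frequency_spectrum(snps: list[SnpRecord], bins: int = 50) -> AfSpectrum:
    """Histogram of alt-allele frequencies over [0, 1].

    Bins are half-open [lo, hi) except the final bin, which is closed,
    so a frequency of exactly 1.0 is counted.
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    if not snps:
        raise EmptyInputError("no SNP records")
    freqs = np.array([s.alt_frequency for s in snps])
    counts, edges = np.histogram(freqs, bins=bins, range=(0.0, 1.0))
    assert counts.sum() == len(snps)
    return AfSpectrum(counts=counts, bin_edges=edges)


def haplotig_scan(
    hits: list[SelfAlignmentHit], min_identity: float = 99.0
) -> tuple[list[SelfAlignmentHit], int]:
    """Self-alignment hits above an identity floor, on distinct contigs.

    Returns the retained hits sorted by length (desc) and the maximum
    length (0 when nothing passes).
    """
    kept = [
        h
        for h in hits
        if h.identity > min_identity and h.contig_a != h.contig_b
    ]
    kept.sort(key=lambda h: (-h.length, h.contig_a, h.contig_b))
    return kept, (kept[0].length if kept else 0)


@dataclass(frozen=True)
class WgdSpectrum:
    level: float
    size_histogram: dict[int, int]  # cluster size -> number of clusters
    dominant_size: int
    clusters: list[Cluster]


def wgd_cluster_spectrum(
    proteome: list[SeqRecord],
    identity_levels: tuple[float, ...] = (0.9, 0.7, 0.5),
    min_coverage: float = 0.7,
) -> list[WgdSpectrum]:
    """Cluster-size spectrum of the proteome at several identity levels.

    The dominant size is the most frequent cluster size (ties -> smaller).
    A recently genome-duplicated proteome shows a dominant size of 2 at
    high identity; a singleton-dominated spectrum argues against WGD.
    """
    if not proteome:
        raise EmptyInputError("empty proteome")
    out = []
    for level in identity_levels:
        clusters = greedy_cluster(proteome, level, min_coverage)
        hist = Counter(len(c) for c in clusters)
        total = sum(size * n for size, n in hist.items())
        assert total == len(proteome)
        max_count = max(hist.values())
        dominant = min(s for s, n in hist.items() if n == max_count)
        out.append(
            WgdSpectrum(
                level=level,
                size_histogram=dict(sorted(hist.items())),
                dominant_size=dominant,
                clusters=clusters,
            )
        )
    return out


# ---------------------------------------------------------------------------
# readers


def read_snp_tsv(path) -> list[SnpRecord]:
    """4-column TSV: contig, position (1-based), ref_count, alt_count."""
    import pandas as pd

    df = pd.read_csv(
        path,
        sep="\t",
        names=["contig", "position", "ref_count", "alt_count"],
        comment="#",
    )
    return [
        SnpRecord(r.contig, int(r.position), int(r.ref_count), int(r.alt_count))
        for r in df.itertuples()
    ]


def read_self_alignment_hits(path) -> list[SelfAlignmentHit]:
    """Tabular (BLAST outfmt-6 dialect): cols 1,2 contigs, 3 identity, 4 length."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [
        SelfAlignmentHit(str(row[0]), str(row[1]), float(row[2]), int(row[3]))
        for _, row in df.iterrows()
    ]
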