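"""Differential-expression filtering and co-expression hub analysis.

DE calls follow the usual two-threshold rule: FDR-adjusted p < 0.05
(Benjamini–Hochberg) and |log2 fold change| >= 1. The co-expression graph
connects genes whose Pearson correlation on log2(x+1) values clears a
threshold; hubs are nodes ranking in the top fraction of BOTH degree and
betweenness centrality — genes that are widely connected and also sit on
many shortest paths between other genes, the profile of a putative
regulator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import DegenerateInputError, EmptyInputError, InvalidPValueError


@dataclass(frozen=True)
class DeStat:
    gene: str
    log2fc: float
    p_raw: float
    p_adj: float | None = None
    contrast: str = ""

    def __post_init__(self):
        for p in (self.p_raw, self.p_adj):
            if p is not None and not (0 < p <= 1):
                raise InvalidPValueError(f"{self.gene}: p={p} outside (0,1]")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise EmptyInputError("no p-values")
    if np.any((p <= 0) | (p > 1)):
        raise InvalidPValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_filter(
    stats: list[DeStat], alpha: float = 0.05, min_abs_lfc: float = 1.0
) -> tuple[set[str], set[str]]:
    """(up, down) gene sets at p_adj < alpha and |log2FC| >= min_abs_lfc.

    Missing adjusted p-values are computed from the raw ones by BH over
    the supplied list.
    """
    if not stats:
        return set(), set()
    if any(s.p_adj is None for s in stats):
        adj = bh_adjust([s.p_raw for s in stats])
    else:
        adj = np.array([s.p_adj for s in stats])
    up, down = set(), set()
    for s, pa in zip(stats, adj):
        if pa < alpha and s.log2fc >= min_abs_lfc:
            up.add(s.gene)
        elif pa < alpha and s.log2fc <= -min_abs_lfc:
            down.add(s.gene)
    return up, down


def build_coexpression_graph(
    expr: pd.DataFrame, min_abs_corr: float = 0.7
) -> nx.Graph:
    """Correlation graph on log2(x+1) expression (genes = rows).

    Edge iff |Pearson r| >= min_abs_corr; edge weight is |r|. Genes with
    zero variance are excluded with a warning.
    """
    if expr.shape[1] < 3:
        raise DegenerateInputError("need at least 3 samples")
    logx = np.log2(expr.to_numpy(dtype=float) + 1.0)
    variances = logx.var(axis=1)
    keep = variances > 0
    dropped = list(expr.index[~keep])
    if dropped:
        warnings.warn(f"{len(dropped)} zero-variance genes excluded")
    genes = list(expr.index[keep])
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    if len(genes) >= 2:
        corr = np.corrcoef(logx[keep])
        iu, ju = np.where(np.triu(np.abs(corr) >= min_abs_corr, k=1))
        for i, j in zip(iu, ju):
            graph.add_edge(genes[i], genes[j], weight=float(abs(corr[i, j])))
    return graph


@dataclass(frozen=True)
class HubResult:
    hubs: frozenset[str]
    degree: dict[str, int]
    betweenness: dict[str, float]
    top_by_degree: frozenset[str]
    top_by_betweenness: frozenset[str]


def _top_with_ties(values: dict[str, float], k: int) -> frozenset[str]:
    if k <= 0 or not values:
        return frozenset()
    ordered = sorted(values.values(), reverse=True)
    cutoff = ordered[min(k, len(ordered)) - 1]
    return frozenset(n for n, v in values.items() if v >= cutoff)


def hub_detection(
    graph: nx.Graph, top_fraction: float = 0.10, union: bool = False
) -> HubResult:
    """Hubs = nodes in the top fraction of degree AND betweenness.

    Cutoff size is ceil(fraction * n); ties at the boundary are included,
    so the result is independent of node ordering. Betweenness is
    unnormalized Brandes on unweighted shortest paths, components handled
    independently. ``union=True`` relaxes AND to OR.
    """
    if graph.number_of_nodes() == 0:
        raise EmptyInputError("empty graph")
    n = graph.number_of_nodes()
    k = math.ceil(top_fraction * n)
    degree = dict(graph.degree())
    betweenness = nx.betweenness_centrality(graph, normalized=False)
    top_deg = _top_with_ties({g: float(d) for g, d in degree.items()}, k)
    top_btw = _top_with_ties(betweenness, k)
    hubs = (top_deg | top_btw) if union else (top_deg & top_btw)
    return HubResult(
        hubs=frozenset(hubs),
        degree=degree,
        betweenness=betweenness,
        top_by_degree=top_deg,
        top_by_betweenness=top_btw,
    )


@dataclass(frozen=True)
class ModuleEnrichment:
    module: str
    k: int  # DE genes in module
    module_size: int
    p_value: float
    significant: bool


def module_de_enrichment(
    modules: dict[str, str],  # gene -> module label
    de_genes: set[str],
    alpha: float = 0.05,
) -> list[ModuleEnrichment]:
    """One-sided Fisher test of DE membership per module.

    Background is the set of all module-assigned genes. Empty modules are
    skipped with a warning.
    """
    by_module: dict[str, set[str]] = {}
    for gene, label in modules.items():
        by_module.setdefault(label, set()).add(gene)
    background = set(modules)
    de_in_background = de_genes & background
    N = len(background)
    out = []
    for label in sorted(by_module):
        members = by_module[label]
        if not members:
            warnings.warn(f"module {label} is empty; skipped")
            continue
        k = len(members & de_in_background)
        p = float(hypergeom.sf(k - 1, N, len(de_in_background), len(members)))
        out.append(
            ModuleEnrichment(
                module=label, k=k, module_size=len(members),
                p_value=p, significant=p < alpha,
            )
        )
    return out


# ---------------------------------------------------------------------------
# I/O


def read_de_stats(path, contrast: str = "") -> list[DeStat]:
    """DESeq2-style TSV: gene, baseMean, log2FoldChange, pvalue, padj."""
    df = pd.read_csv(path, sep="\t")
    gene_col = df.columns[0]
    out = []
    for _, row in df.iterrows():
        padj = row.get("padj")
        out.append(
            DeStat(
                gene=str(row[gene_col]),
                log2fc=float(row["log2FoldChange"]),
                p_raw=float(row["pvalue"]),
                p_adj=None if pd.isna(padj) else float(padj),
                contrast=contrast,
            )
        )
    return out


def read_expression_matrix(path) -> pd.DataFrame:
    """TSV with genes as rows, samples as columns."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_edge_list(graph: nx.Graph, path) -> None:
    """Weighted edge list TSV: gene_a, gene_b, weight."""
    lines = [
        f"{a}\t{b}\t{d.get('weight', 1.0):.4f}"
        for a, b, d in sorted(graph.edges(data=True))
    ]
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)
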