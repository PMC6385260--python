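"""Synthetic genomes, hit tables, SNPs and expression with planted truth.

Every generator emulates one input the pipeline consumes in production —
a small diploid coral-like genome with intron-rich genes and an inserted
intronless bacterial gene cluster, taxonomy-annotated homology-hit
tables, binomial read-depth SNPs peaking at allele frequency 0.5, and
negative-binomial expression with planted differentially expressed genes
and correlation modules built around a single strongly loaded hub gene.
The planted truth travels with the data so recovery can be asserted, not
eyeballed.

One integer seed drives a named pseudo-random stream per generator
(``default_rng([seed, stream])``), so adding a generator never perturbs
the output of another. Same seed, same bytes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd

from .assembly_qc import SnpRecord
from .de_network import DeStat, bh_adjust
from .errors import InfeasiblePackingError
from .gene_models import (
    SENSE_CODONS,
    GeneModel,
    extract_cds,
    revcomp,
    translate_cds,
)
from .hgt_screen import HomologyHit
from .repeats import RepeatFamily, RepeatHit
from .sequtil import SeqRecord

_STREAMS = {"genome": 1, "hits": 2, "snps": 3, "expression": 4}

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SyntheticSpec:
    """All knobs of the synthetic study, serializable round-trip."""

    seed: int
    # genome layout
    contig_length: int = 160_000
    n_decoy_genes: int = 24
    cds_codons_range: tuple[int, int] = (120, 300)
    exon_count_range: tuple[int, int] = (2, 5)
    intron_length_range: tuple[int, int] = (80, 600)
    intergenic_range: tuple[int, int] = (200, 800)
    # perturbations applied to derive the two predicted gene sets
    frac_split: float = 0.2
    frac_truncated: float = 0.2
    frac_missed: float = 0.15
    truncation_fraction: float = 0.35
    # planted horizontally transferred cluster
    hgt_gene_count: int = 4
    # sized so the 4-gene cluster span always lands inside the 4-14 kbp
    # window a gene-transfer-agent particle can package
    hgt_cds_codons_range: tuple[int, int] = (310, 380)
    hgt_gap_range: tuple[int, int] = (120, 300)
    # repeats
    n_repeat_families: int = 5
    repeat_length_range: tuple[int, int] = (100, 400)
    copies_per_family: int = 12
    intronic_fraction: float = 0.4
    # SNPs: a down-sample of the million-SNP scale of a real diploid
    # assembly check, large enough that the spectrum's central bin is
    # stable against multinomial noise
    n_snps: int = 50_000
    snp_depth: int = 30
    het_frequency: float = 0.5
    haploid_fraction: float = 0.0
    # expression
    n_expr_genes: int = 2_000
    n_de_genes: int = 100
    de_log2fc: float = 3.0
    nb_dispersion: float = 0.02
    treatments: tuple[str, ...] = ("ATAC", "ATHC", "HTAC")
    timepoints: tuple[int, ...] = (1, 6)
    replicates: int = 3
    baseline_replicates: int = 3
    module_count: int = 4
    module_size: int = 25
    hub_noise_sd: float = 0.05
    member_loading_range: tuple[float, float] = (0.85, 0.95)
    member_noise_sd: float = 0.45
    # edge threshold the planted modules are calibrated for: hub-member
    # correlations sit safely above it, member-member mostly below, and
    # chance correlations between unrelated genes essentially never reach
    # it at this sample count
    coexpression_edge_threshold: float = 0.8

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        raw = json.loads(text)
        kwargs = {}
        for f in fields(cls):
            v = raw[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


@dataclass
class SyntheticTruth:
    hgt_gene_ids: tuple[str, ...] = ()
    hgt_flanks: tuple[str, str] | None = None
    repeat_placements: list[RepeatHit] = field(default_factory=list)
    de_genes: dict[str, str] = field(default_factory=dict)  # gene -> up/down
    hubs: tuple[str, ...] = ()
    modules: dict[str, str] = field(default_factory=dict)  # gene -> module


@dataclass
class SyntheticGenome:
    contigs: dict[str, str]
    true_genes: list[GeneModel]
    abinitio: list[GeneModel]
    homology: list[GeneModel]
    repeat_families: list[RepeatFamily]
    repeat_hits: list[RepeatHit]  # compartments per the planting plan
    truth: SyntheticTruth

    def cds_of(self, gene_id: str) -> str:
        gene = next(g for g in self.true_genes if g.id == gene_id)
        return extract_cds(gene, self.contigs[gene.contig])

    def proteins(self) -> dict[str, SeqRecord]:
        out = {}
        for g in self.true_genes:
            prot = translate_cds(self.cds_of(g.id)).rstrip("*")
            out[g.id] = SeqRecord(id=g.id, residues=prot, moltype="aa")
        return out


def _random_nt(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


# skewed codon usage shared by all synthetic host genes, so the
# genome-wide codon-frequency vector is informative (a uniform usage
# would make the atypicality correlation degenerate)
_CODON_P = np.exp(-np.arange(len(SENSE_CODONS)) / 8.0)
_CODON_P /= _CODON_P.sum()


def _random_cds(rng, n_codons: int) -> str:
    """ATG + (n-2) biased sense codons + a stop: n_codons codons total."""
    body = "".join(rng.choice(SENSE_CODONS, size=n_codons - 2, p=_CODON_P))
    stop = str(rng.choice(["TAA", "TAG", "TGA"]))
    return "ATG" + body + stop


@dataclass
class _GenePlan:
    gene_id: str
    strand: str
    cds: str
    exon_codons: list[int]  # codons per exon, transcription order
    intron_lengths: list[int]
    is_hgt: bool = False
    perturbation: str = "exact"  # exact|split|truncated|missed|abonly


def _plan_decoy(rng, spec: SyntheticSpec, gene_id: str) -> _GenePlan:
    n_codons = int(rng.integers(*spec.cds_codons_range))
    n_exons = int(rng.integers(spec.exon_count_range[0], spec.exon_count_range[1] + 1))
    n_exons = min(n_exons, max(1, n_codons // 30))
    cuts = sorted(rng.choice(np.arange(1, n_codons), size=n_exons - 1, replace=False))
    bounds = [0, *cuts, n_codons]
    exon_codons = [bounds[i + 1] - bounds[i] for i in range(n_exons)]
    introns = [int(rng.integers(*spec.intron_length_range)) for _ in range(n_exons - 1)]
    return _GenePlan(
        gene_id=gene_id,
        strand=str(rng.choice(["+", "-"])),
        cds=_random_cds(rng, n_codons),
        exon_codons=exon_codons,
        intron_lengths=introns,
    )


def _realize(plan: _GenePlan, rng, offset: int) -> tuple[str, GeneModel]:
    """Build the genomic block for a plan; return (block, model at offset)."""
    pieces = []
    local_exons = []  # 0-based half-open in block, transcription order
    pos = 0
    codon_i = 0
    for k, n_cod in enumerate(plan.exon_codons):
        exon_seq = plan.cds[3 * codon_i : 3 * (codon_i + n_cod)]
        codon_i += n_cod
        pieces.append(exon_seq)
        local_exons.append((pos, pos + len(exon_seq)))
        pos += len(exon_seq)
        if k < len(plan.intron_lengths):
            ilen = plan.intron_lengths[k]
            pieces.append(_random_nt(rng, ilen))
            pos += ilen
    block = "".join(pieces)
    if plan.strand == "-":
        L = len(block)
        block = revcomp(block)
        local_exons = [(L - e, L - s) for s, e in local_exons]
        local_exons.sort()
    exons = tuple((offset + s + 1, offset + e) for s, e in local_exons)
    model = GeneModel(
        id=plan.gene_id, contig="contig1", strand=plan.strand, exons=exons,
        source="truth",
    )
    return block, model


def _perturbed_models(
    plan: _GenePlan, model: GeneModel, spec: SyntheticSpec
) -> tuple[list[GeneModel], list[GeneModel]]:
    """Derive (ab initio, homology) predictions for one true gene."""

    def as_source(m, mid, source, completeness, exons=None):
        return GeneModel(
            id=mid, contig=m.contig, strand=m.strand,
            exons=exons or m.exons, source=source, completeness=completeness,
        )

    p = plan.perturbation
    if p == "abonly":
        return [as_source(model, f"{model.id}.a", "abinitio", 0.95)], []
    if p == "missed":
        return [], [as_source(model, f"{model.id}.h", "homology", 0.98)]
    if p == "split" and model.n_exons >= 2:
        j = model.n_exons // 2
        a1 = as_source(
            model, f"{model.id}.a1", "abinitio", 0.5, exons=model.exons[:j]
        )
        a2 = as_source(
            model, f"{model.id}.a2", "abinitio", 0.5, exons=model.exons[j:]
        )
        return [a1, a2], [as_source(model, f"{model.id}.h", "homology", 0.98)]
    if p == "truncated":
        keep = 1.0 - spec.truncation_fraction
        if model.n_exons >= 2:
            exons = model.exons[:-1] if model.strand == "+" else model.exons[1:]
        else:
            (s, e), = model.exons
            cut = int((e - s + 1) * keep) // 3 * 3
            exons = ((s, s + max(cut, 3) - 1),)
        a = as_source(model, f"{model.id}.a", "abinitio", round(keep, 3), exons=exons)
        return [a], [as_source(model, f"{model.id}.h", "homology", 0.98)]
    # exact: both predictors found the same structure; ab initio retained
    a = as_source(model, f"{model.id}.a", "abinitio", 0.95)
    h = as_source(model, f"{model.id}.h", "homology", 0.95)
    return [a], [h]


def generate_genome(spec: SyntheticSpec) -> SyntheticGenome:
    """One contig carrying decoy host genes, a planted intronless bacterial
    cluster with host genes on both flanks, and repeat copies overwritten
    into introns and intergenic gaps per the compartment mix."""
    rng = spec.rng("genome")
    n = spec.n_decoy_genes
    if n < 2:
        raise InfeasiblePackingError("need >=2 decoy genes to flank the cluster")
    # decide perturbation classes up front (classes are decoy-only)
    classes = []
    for _ in range(n):
        u = rng.random()
        if u < spec.frac_split:
            classes.append("split")
        elif u < spec.frac_split + spec.frac_truncated:
            classes.append("truncated")
        elif u < spec.frac_split + spec.frac_truncated + spec.frac_missed:
            classes.append("missed")
        else:
            classes.append("exact")
    hgt_after = n // 2  # cluster sits mid-contig, flanked by decoys
    plans: list[_GenePlan] = []
    for i in range(n):
        plan = _plan_decoy(rng, spec, f"g{i + 1:04d}")
        plan.perturbation = classes[i]
        plans.append(plan)
        if i + 1 == hgt_after and spec.hgt_gene_count:
            for k in range(spec.hgt_gene_count):
                n_codons = int(rng.integers(*spec.hgt_cds_codons_range))
                plans.append(
                    _GenePlan(
                        gene_id=f"hgt{k + 1}",
                        strand="+",
                        cds=_random_cds(rng, n_codons),
                        exon_codons=[n_codons],
                        intron_lengths=[],
                        is_hgt=True,
                        perturbation="abonly",
                    )
                )
    # lay out the contig
    cursor = 0
    segments: list[str] = []
    true_genes: list[GeneModel] = []
    abinitio: list[GeneModel] = []
    homology: list[GeneModel] = []
    prev_was_hgt = False
    for plan in plans:
        if plan.is_hgt and prev_was_hgt:
            gap = int(rng.integers(*spec.hgt_gap_range))
        else:
            gap = int(rng.integers(*spec.intergenic_range))
        segments.append(_random_nt(rng, gap))
        cursor += gap
        block, model = _realize(plan, rng, cursor)
        segments.append(block)
        cursor += len(block)
        true_genes.append(model)
        a, h = _perturbed_models(plan, model, spec)
        abinitio.extend(a)
        homology.extend(h)
        prev_was_hgt = plan.is_hgt
    tail = int(rng.integers(*spec.intergenic_range))
    segments.append(_random_nt(rng, tail))
    cursor += tail
    if cursor > spec.contig_length:
        raise InfeasiblePackingError(
            f"layout needs {cursor} bp > contig_length {spec.contig_length}"
        )
    segments.append(_random_nt(rng, spec.contig_length - cursor))
    contig = "".join(segments)
    hgt_ids = tuple(g.id for g in true_genes if g.id.startswith("hgt"))
    flanks = None
    if hgt_ids:
        ordered = sorted(true_genes, key=lambda g: g.start)
        idx = [i for i, g in enumerate(ordered) if g.id in hgt_ids]
        flanks = (ordered[idx[0] - 1].id, ordered[idx[-1] + 1].id)
    # plant repeat copies by overwriting intron/intergenic sequence
    contig_list = list(contig)
    families, hits = _plant_repeats(rng, spec, contig_list, true_genes)
    contig = "".join(contig_list)
    truth = SyntheticTruth(
        hgt_gene_ids=hgt_ids, hgt_flanks=flanks, repeat_placements=list(hits)
    )
    return SyntheticGenome(
        contigs={"contig1": contig},
        true_genes=true_genes,
        abinitio=abinitio,
        homology=homology,
        repeat_families=families,
        repeat_hits=hits,
        truth=truth,
    )


def _plant_repeats(rng, spec, contig_list, true_genes):
    families = []
    for i in range(spec.n_repeat_families):
        length = int(rng.integers(*spec.repeat_length_range))
        fid = f"rnd-family-{i + 1}"
        families.append(
            RepeatFamily(
                id=fid,
                consensus=SeqRecord(id=fid, residues=_random_nt(rng, length),
                                    moltype="nt"),
                classification="unknown" if i % 2 else "LTR/unknown-like",
            )
        )
    introns = [
        (s, e) for g in true_genes for s, e in g.introns() if e - s + 1 >= 30
    ]
    ordered = sorted(true_genes, key=lambda g: g.start)
    gaps = []
    prev_end = 1
    for g in ordered:
        if g.start - prev_end >= 60:
            gaps.append((prev_end + 10, g.start - 10))
        prev_end = g.end
    def _weighted_pick(intervals):
        # insertion lands uniformly along the DNA, so an interval's chance
        # is proportional to its length
        lengths = np.array([e - s + 1 for s, e in intervals], dtype=float)
        return intervals[int(rng.choice(len(intervals), p=lengths / lengths.sum()))]

    hits = []
    occupied: list[tuple[int, int]] = []
    for fam in families:
        for _ in range(spec.copies_per_family):
            if introns and rng.random() < spec.intronic_fraction:
                s, e = _weighted_pick(introns)
                compartment = "intron"
            else:
                s, e = _weighted_pick(gaps)
                compartment = "intergenic"
            room = e - s + 1
            length = min(fam.length, room - 2)
            if length < 20:
                continue
            start = s + int(rng.integers(0, room - length + 1))
            end = start + length - 1
            # two copies landing on the same bases would overwrite each
            # other and falsify the recorded placement; skip collisions
            if any(start <= oe and os <= end for os, oe in occupied):
                continue
            occupied.append((start, end))
            seq = fam.consensus.residues[:length]
            contig_list[start - 1 : start - 1 + length] = list(seq)
            hits.append(
                RepeatHit(
                    family_id=fam.id, contig="contig1",
                    start=start, end=end,
                    compartment=compartment,
                )
            )
    return families, hits


# ---------------------------------------------------------------------------
# homology-hit tables


_HOST_PHYLA = ["Cnidaria", "Chordata", "Arthropoda"]
_BACT_PHYLA = ["Proteobacteria", "Firmicutes", "Bacteroidetes"]


def _mutate_protein(rng, prot: str, divergence: float) -> str:
    seq = list(prot)
    n_mut = int(round(divergence * len(seq)))
    sites = rng.choice(len(seq), size=min(n_mut, len(seq)), replace=False)
    for i in sites:
        choices = [a for a in _AA if a != seq[i]]
        seq[i] = choices[int(rng.integers(len(choices)))]
    return "".join(seq)


@dataclass
class SyntheticHits:
    hits: list[HomologyHit]
    subject_seqs: dict[str, SeqRecord]


def generate_hits(
    spec: SyntheticSpec, genome: SyntheticGenome
) -> SyntheticHits:
    """Taxonomy-annotated hit lists per gene: metazoan-topped for host
    genes, bacterial-topped (>=3 phyla, one exceeding the per-phylum cap)
    for the planted cluster. Subject sequences are mutated copies of the
    query at the divergence implied by the reported identity."""
    rng = spec.rng("hits")
    proteins = genome.proteins()
    hgt = set(genome.truth.hgt_gene_ids)
    hits: list[HomologyHit] = []
    subjects: dict[str, SeqRecord] = {}

    def add(query, tag, phylum, metazoan, coral, divergence):
        prot = proteins[query].residues
        sid = f"{query}|{tag}"
        sseq = _mutate_protein(rng, prot, divergence)
        subjects[sid] = SeqRecord(id=sid, residues=sseq, moltype="aa")
        identity = max(1.0, 100.0 * (1 - divergence))
        hits.append(
            HomologyHit(
                query_id=query, subject_id=sid,
                bitscore=round(2.0 * len(prot) * (1 - divergence), 1),
                identity=round(identity, 2), align_len=len(prot),
                phylum=phylum, is_metazoan=metazoan, is_coral=coral,
            )
        )

    for gid in sorted(proteins):
        if gid in hgt:
            for i in range(8):  # exercises the per-phylum FCFS cap of 6
                add(gid, f"prot{i}", "Proteobacteria", False, False,
                    rng.uniform(0.08, 0.30))
            for i in range(3):
                add(gid, f"firm{i}", "Firmicutes", False, False,
                    rng.uniform(0.15, 0.35))
            for i in range(3):
                add(gid, f"bact{i}", "Bacteroidetes", False, False,
                    rng.uniform(0.15, 0.35))
            for i in range(4):
                add(gid, f"met{i}", _HOST_PHYLA[i % 3], True, False,
                    rng.uniform(0.55, 0.68))
        else:
            for i in range(4):
                add(gid, f"cni{i}", "Cnidaria", True, i < 2,
                    rng.uniform(0.05, 0.20))
            for i in range(3):
                add(gid, f"met{i}", _HOST_PHYLA[1 + i % 2], True, False,
                    rng.uniform(0.25, 0.40))
            for i in range(3):
                add(gid, f"bac{i}", _BACT_PHYLA[i % 3], False, False,
                    rng.uniform(0.50, 0.65))
    return SyntheticHits(hits=hits, subject_seqs=subjects)


# ---------------------------------------------------------------------------
# SNPs


def generate_snps(spec: SyntheticSpec) -> list[SnpRecord]:
    """Heterozygous-site read counts: alt ~ Binomial(depth, het_frequency),
    with an optional contaminating haploid fraction at frequency 1."""
    if spec.snp_depth < 10:
        raise ValueError("snp_depth must be >= 10")
    rng = spec.rng("snps")
    n_haploid = int(round(spec.haploid_fraction * spec.n_snps))
    alt = rng.binomial(spec.snp_depth, spec.het_frequency, size=spec.n_snps)
    alt = np.clip(alt, 1, spec.snp_depth - 1)  # het sites show both alleles
    alt[:n_haploid] = spec.snp_depth
    return [
        SnpRecord(
            contig="contig1", position=1000 + i * 50,
            ref_count=int(spec.snp_depth - a), alt_count=int(a),
        )
        for i, a in enumerate(alt)
    ]


# ---------------------------------------------------------------------------
# expression


@dataclass
class SyntheticExpression:
    counts: pd.DataFrame  # genes x samples
    de_stats: dict[str, list[DeStat]]  # contrast -> per-gene stats
    truth: SyntheticTruth


def _nb_sample(rng, mean, dispersion):
    """Negative binomial with var = mu + dispersion * mu^2."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-8)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_expression(spec: SyntheticSpec) -> SyntheticExpression:
    """Counts for a treatments x timepoints x replicates design.

    Planted DE genes shift by ±de_log2fc in the heated (HTAC) samples;
    module genes share a per-sample latent factor with the planted hub
    carrying the strongest loading. The per-contrast statistics are a
    log2(x+1) two-group t-test with BH adjustment — deliberately simple
    fixture machinery, not a DESeq2 reimplementation.
    """
    from scipy.stats import ttest_ind

    rng = spec.rng("expression")
    samples = [f"ATAC_0_r{r + 1}" for r in range(spec.baseline_replicates)]
    for treat in spec.treatments:
        for tp in spec.timepoints:
            samples += [f"{treat}_{tp}_r{r + 1}" for r in range(spec.replicates)]
    n_module_genes = spec.module_count * spec.module_size
    n_total = spec.n_expr_genes
    if spec.n_de_genes + n_module_genes > n_total:
        raise ValueError("more planted genes than genes")
    genes = [f"gene{i + 1:05d}" for i in range(n_total)]
    # planted assignments: DE genes first, module genes next, rest background
    de_ids = genes[: spec.n_de_genes]
    module_ids = genes[spec.n_de_genes : spec.n_de_genes + n_module_genes]
    base_log2 = rng.uniform(7, 10, size=n_total)
    heat = np.array([s.startswith("HTAC") for s in samples])
    signal = np.zeros((n_total, len(samples)))
    de_truth: dict[str, str] = {}
    for j, gid in enumerate(de_ids):
        direction = "up" if j % 2 == 0 else "down"
        de_truth[gid] = direction
        lfc = spec.de_log2fc if direction == "up" else -spec.de_log2fc
        signal[j, heat] += lfc
    modules: dict[str, str] = {}
    hubs: list[str] = []

    def _unit(v):
        v = v - v.mean()
        return v / v.std()

    def _noise(z, sd):
        # module-factor-orthogonal noise at exactly the requested sd, so
        # hub-member sample correlations are set by the loadings, not by
        # the luck of the 21-sample factor draw
        e = rng.normal(size=len(samples))
        e = e - (e @ z) / (z @ z) * z
        e = e - e.mean()
        return sd * e / e.std() if e.std() > 0 else e

    for m in range(spec.module_count):
        label = f"module{m + 1}"
        z = _unit(rng.normal(size=len(samples)))
        block = module_ids[m * spec.module_size : (m + 1) * spec.module_size]
        for k, gid in enumerate(block):
            modules[gid] = label
            if k == 0:  # the hub: regulator driving the module
                hubs.append(gid)
                loading, noise_sd = 1.0, spec.hub_noise_sd
            else:
                loading = rng.uniform(*spec.member_loading_range)
                noise_sd = spec.member_noise_sd
            row = spec.n_de_genes + m * spec.module_size + k
            signal[row] += loading * z + _noise(z, noise_sd)
    mu = 2.0 ** (base_log2[:, None] + signal)
    counts = _nb_sample(rng, mu, spec.nb_dispersion)
    df = pd.DataFrame(counts, index=genes, columns=samples)
    # per-contrast stats: treatment vs ambient control at the same timepoint
    de_stats: dict[str, list[DeStat]] = {}
    logx = np.log2(df.to_numpy(dtype=float) + 1.0)
    col = {s: i for i, s in enumerate(samples)}
    for treat in spec.treatments:
        if treat == "ATAC":
            continue
        for tp in spec.timepoints:
            contrast = f"{treat}_{tp}_vs_ATAC_{tp}"
            g1 = [col[s] for s in samples if s.startswith(f"{treat}_{tp}_")]
            g0 = [col[s] for s in samples if s.startswith(f"ATAC_{tp}_")]
            x1, x0 = logx[:, g1], logx[:, g0]
            lfc = x1.mean(axis=1) - x0.mean(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                p = ttest_ind(x1, x0, axis=1).pvalue
            p = np.where(np.isfinite(p), p, 1.0)
            p = np.clip(p, np.nextafter(0, 1), 1.0)
            padj = bh_adjust(p)
            de_stats[contrast] = [
                DeStat(gene=g, log2fc=float(lfc[i]), p_raw=float(p[i]),
                       p_adj=float(padj[i]), contrast=contrast)
                for i, g in enumerate(genes)
            ]
    truth = SyntheticTruth(de_genes=de_truth, hubs=tuple(hubs), modules=modules)
    return SyntheticExpression(counts=df, de_stats=de_stats, truth=truth)


# ---------------------------------------------------------------------------
# proteome helpers (WGD test)


def duplicate_proteome(proteome: list[SeqRecord]) -> list[SeqRecord]:
    """Verbatim whole-proteome duplication (synthetic WGD)."""
    dupes = [
        SeqRecord(id=f"{p.id}_dup", residues=p.residues, moltype=p.moltype)
        for p in proteome
    ]
    return list(proteome) + dupes
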