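"""Gene-model reconciliation, completeness, filtering, family statistics."""

import io

import numpy as np
import pytest

from genomescape.errors import (
    DuplicateIdError,
    MissingCompletenessError,
    SpeciesMismatchError,
    UndefinedFoldError,
)
from genomescape.gene_models import (
    CladePartition,
    GeneModel,
    MergeRule,
    OrthoFamily,
    compute_completeness,
    family_fold_change,
    filter_gene_models,
    locus_overlap_graph,
    partition_families,
    read_gff3,
    read_orthogroup_counts,
    reconcile_gene_models,
    translate_cds,
    write_gff3,
)
from genomescape.sequtil import SeqRecord
from oracles import overlap_oracle, reconcile_oracle


def _gm(gid, start, end, strand="+", contig="c1", source="abinitio",
        completeness=None, exons=None):
    return GeneModel(
        id=gid, contig=contig, strand=strand,
        exons=exons or ((start, end),), source=source, completeness=completeness,
    )


def _random_models(rng, n, prefix, contig_count=2, completeness=True):
    models = []
    for i in range(n):
        start = int(rng.integers(1, 5_000))
        n_ex = int(rng.integers(1, 4))
        exons, pos = [], start
        for _ in range(n_ex):
            length = int(rng.integers(50, 300))
            exons.append((pos, pos + length - 1))
            pos += length + int(rng.integers(20, 200))
        models.append(
            GeneModel(
                id=f"{prefix}{i:03d}",
                contig=f"c{int(rng.integers(contig_count))}",
                strand="+-"[int(rng.integers(2))],
                exons=tuple(exons),
                source="abinitio" if prefix == "a" else "homology",
                completeness=round(float(rng.uniform(0.4, 1.0)), 3)
                if completeness else None,
            )
        )
    return models


class TestLocusOverlapGraph:
    def test_disjoint_contigs_empty_mapping(self):
        mapping = locus_overlap_graph(
            [_gm("a1", 1, 100, contig="c1")], [_gm("h1", 1, 100, contig="c2",
                                                  source="homology")]
        )
        assert mapping == {"h1": []}

    def test_spanning_homology_model_maps_to_both_fragments(self):
        a1, a2 = _gm("a1", 100, 200), _gm("a2", 400, 500)
        h = _gm("h1", 50, 600, source="homology")
        assert locus_overlap_graph([a1, a2], [h]) == {"h1": ["a1", "a2"]}

    def test_matches_all_pairs_interval_oracle(self):
        rng = np.random.default_rng(12)
        abinitio = _random_models(rng, 100, "a")
        homology = _random_models(rng, 100, "h")
        mapping = locus_overlap_graph(abinitio, homology)
        for h in homology:
            expected = sorted(
                (a.id for a in abinitio if overlap_oracle(h, a)),
                key=lambda aid: next(
                    (m.start, m.id) for m in abinitio if m.id == aid
                ),
            )
            assert mapping[h.id] == expected

    def test_duplicate_ids_rejected(self):
        with pytest.raises(DuplicateIdError):
            locus_overlap_graph([_gm("x", 1, 10)], [_gm("x", 1, 10, source="homology")])


class TestReconcileGeneModels:
    def test_fragment_join_replaces_partial_predictions(self):
        a1, a2 = _gm("a1", 100, 200), _gm("a2", 400, 500)
        h = _gm("h1", 50, 600, source="homology")
        merged, log = reconcile_gene_models([a1, a2], [h])
        assert [m.id for m in merged] == ["h1"]
        assert log[0].rule is MergeRule.FRAGMENT_JOIN
        assert set(log[0].consumed) == {"a1", "a2"}

    def test_completeness_gain_at_boundary_keeps_abinitio(self):
        a = _gm("a1", 100, 500, completeness=0.86)
        h = _gm("h1", 120, 520, source="homology", completeness=0.90)
        merged, log = reconcile_gene_models([a], [h])
        assert [m.id for m in merged] == ["a1"]  # gain 0.04 <= 0.05
        assert log[0].rule is MergeRule.COMPLETENESS_KEEP

    def test_clear_completeness_gain_swaps_in_homology(self):
        a = _gm("a1", 100, 500, completeness=0.60)
        h = _gm("h1", 120, 520, source="homology", completeness=0.95)
        merged, _ = reconcile_gene_models([a], [h])
        assert [m.id for m in merged] == ["h1"]

    def test_novel_homology_added(self):
        merged, log = reconcile_gene_models(
            [_gm("a1", 100, 200, completeness=0.9)],
            [_gm("h1", 5_000, 6_000, source="homology", completeness=0.9)],
        )
        assert sorted(m.id for m in merged) == ["a1", "h1"]
        rules = {d.emitted: d.rule for d in log}
        assert rules["h1"] is MergeRule.NOVEL_HOMOLOGY
        assert rules["a1"] is MergeRule.PASSTHROUGH

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_literal_rule_oracle_on_random_loci(self, seed):
        rng = np.random.default_rng(seed)
        abinitio = _random_models(rng, 30, "a")
        homology = _random_models(rng, 20, "h")
        merged, _ = reconcile_gene_models(abinitio, homology)
        assert sorted(m.id for m in merged) == reconcile_oracle(abinitio, homology)

    def test_conservation_every_model_accounted_once(self):
        rng = np.random.default_rng(77)
        abinitio = _random_models(rng, 25, "a")
        homology = _random_models(rng, 15, "h")
        merged, log = reconcile_gene_models(abinitio, homology)
        emitted = {d.emitted for d in log}
        consumed = {c for d in log for c in d.consumed}
        assert emitted == {m.id for m in merged}
        all_ids = {m.id for m in abinitio} | {m.id for m in homology}
        assert emitted | consumed == all_ids

    def test_invariant_to_input_ordering(self):
        rng = np.random.default_rng(13)
        abinitio = _random_models(rng, 20, "a")
        homology = _random_models(rng, 12, "h")
        merged1, _ = reconcile_gene_models(abinitio, homology)
        merged2, _ = reconcile_gene_models(abinitio[::-1], homology[::-1])
        assert [m.id for m in merged1] == [m.id for m in merged2]

    def test_missing_completeness_raises(self):
        a = _gm("a1", 100, 500)
        h = _gm("h1", 120, 520, source="homology")
        with pytest.raises(MissingCompletenessError):
            reconcile_gene_models([a], [h])


class TestCompleteness:
    def test_identical_proteins(self):
        p = SeqRecord("p", "MKLVADERQSTWYHNF" * 5, moltype="aa")
        assert compute_completeness(p, p) == 1.0

    def test_n_terminal_half_covers_half(self):
        ref = SeqRecord("r", "MKLVADERQSTWYHNFCGIP" * 5, moltype="aa")
        half = SeqRecord("q", ref.residues[:50], moltype="aa")
        assert abs(compute_completeness(half, ref) - 0.5) <= 0.02

    @pytest.mark.parametrize("frac", [0.2, 0.4, 0.6, 0.8, 0.9])
    def test_truncation_fraction_recovered(self, frac):
        rng = np.random.default_rng(int(frac * 10))
        ref = SeqRecord(
            "r", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200)),
            moltype="aa",
        )
        q = SeqRecord("q", ref.residues[: int(200 * frac)], moltype="aa")
        assert abs(compute_completeness(q, ref) - frac) <= 0.02


class TestFilterGeneModels:
    def test_internal_stop_discarded(self):
        kept, discarded = filter_gene_models({"g1": "ATGTAAGGGTGA"})
        assert kept == [] and discarded[0] == ("g1", "in_frame_stop")

    def test_typical_codon_usage_kept(self):
        from genomescape.synthetic_data import _random_cds

        rng = np.random.default_rng(8)
        cds = {f"g{i}": _random_cds(rng, 102) for i in range(20)}
        kept, discarded = filter_gene_models(cds)
        assert not discarded and sorted(kept) == sorted(cds)

    def test_planted_biased_codon_genes_discarded(self):
        from genomescape.synthetic_data import _random_cds

        rng = np.random.default_rng(21)
        typical = {f"t{i:03d}": _random_cds(rng, 82) for i in range(90)}
        # transposon-like genes: a single rare codon repeated throughout
        biased = {f"b{i:02d}": "ATG" + "GCG" * 80 + "TAA" for i in range(10)}
        kept, discarded = filter_gene_models({**typical, **biased})
        assert {gid for gid, _ in discarded} == set(biased)
        assert all(reason == "atypical_codon_usage" for _, reason in discarded)

    def test_repeat_overlap_discarded(self):
        cds = "ATGAAAGGGCCCTGA"
        kept, discarded = filter_gene_models(
            {"g1": cds, "g2": cds}, repeat_overlap={"g1": 0.6}
        )
        assert kept == ["g2"] and discarded[0] == ("g1", "repeat_overlap")

    def test_malformed_length_logged(self):
        _, discarded = filter_gene_models({"g1": "ATGAA"})
        assert discarded[0] == ("g1", "malformed_cds_length")


class TestFamilyStatistics:
    def test_fold_changes_from_printed_orthogroup_counts(self):
        # the two most-expanded coral orthogroups: 110/2 and 286/6 copies
        og159 = OrthoFamily("OG0000159", {"mcap": 110, "adig": 2})
        og016 = OrthoFamily("OG0000016", {"mcap": 286, "adig": 6})
        assert family_fold_change(og159, "mcap", "adig") == 55
        assert family_fold_change(og016, "mcap", "adig") == 47  # floor of 47.67
        assert family_fold_change(OrthoFamily("f", {"a": 5, "b": 5}), "a", "b") == 1

    def test_zero_denominator_is_undefined(self):
        with pytest.raises(UndefinedFoldError):
            family_fold_change(OrthoFamily("f", {"a": 5, "b": 0}), "a", "b")

    def test_fold_ge_one_iff_counts_ge(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            ca, cb = int(rng.integers(0, 50)), int(rng.integers(1, 50))
            fam = OrthoFamily("f", {"a": ca, "b": cb})
            assert (family_fold_change(fam, "a", "b") >= 1) == (ca >= cb)

    @staticmethod
    def _partition():
        return CladePartition(
            focal=frozenset({"mcap"}),
            groups={
                "acropora": frozenset({"adig", "aten"}),
                "robust": frozenset({"spis", "ofav"}),
                "anemone": frozenset({"nvec"}),
            },
        )

    def test_ubiquitous_families_are_shared_not_gains_or_losses(self):
        fams = [
            OrthoFamily(f"f{i}", {s: 1 for s in
                                  ["mcap", "adig", "aten", "spis", "ofav", "nvec"]})
            for i in range(5)
        ]
        cells = partition_families(fams, self._partition())
        assert cells["gains"] == 0 and cells["losses"] == 0
        assert cells["shared"] == 5

    def test_focal_only_family_counts_once_as_gain(self):
        fam = OrthoFamily("f", {"mcap": 3, "adig": 0, "aten": 0, "spis": 0,
                                "ofav": 0, "nvec": 0})
        cells = partition_families([fam], self._partition())
        assert cells == {"gains": 1, "losses": 0, "shared": 0, "other": 0, "total": 1}

    def test_hand_enumerated_venn_counts(self):
        sp = ["mcap", "adig", "aten", "spis", "ofav", "nvec"]

        def fam(fid, *present):
            return OrthoFamily(fid, {s: (1 if s in present else 0) for s in sp})

        fams = [
            fam("f1", "mcap"),                       # gain
            fam("f2", "mcap", "adig"),               # shared
            fam("f3", "adig", "spis"),               # loss (2 other groups)
            fam("f4", "adig", "aten"),               # other (1 group only)
            fam("f5", "mcap", "nvec", "spis"),       # shared
            fam("f6", "spis", "ofav", "nvec"),       # loss
            fam("f7", "mcap"),                       # gain
            fam("f8", "nvec"),                       # other
        ]
        cells = partition_families(fams, self._partition())
        assert cells == {"gains": 2, "losses": 2, "shared": 2, "other": 2, "total": 8}

    def test_cells_sum_to_total(self):
        rng = np.random.default_rng(17)
        sp = ["mcap", "adig", "aten", "spis", "ofav", "nvec"]
        fams = [
            OrthoFamily(f"f{i}", {s: int(rng.integers(0, 3)) for s in sp})
            for i in range(200)
        ]
        fams = [f for f in fams if any(f.counts.values())]
        cells = partition_families(fams, self._partition())
        assert (
            cells["gains"] + cells["losses"] + cells["shared"] + cells["other"]
            == cells["total"]
        )

    def test_species_mismatch_raises(self):
        fam = OrthoFamily("f", {"mcap": 1})
        with pytest.raises(SpeciesMismatchError):
            partition_families([fam], self._partition())

    def test_orthogroup_tsv_reader(self):
        text = "Orthogroup\tmcap\tadig\tTotal\nOG01\t110\t2\t112\n"
        fams = read_orthogroup_counts(io.StringIO(text))
        assert fams[0].counts == {"mcap": 110, "adig": 2}


class TestGff3Roundtrip:
    def test_models_roundtrip_with_provenance(self, genome):
        from genomescape.gene_models import reconcile_gene_models

        merged, log = reconcile_gene_models(genome.abinitio, genome.homology)
        buf = io.StringIO()
        write_gff3(merged, buf, decisions=log)
        buf.seek(0)
        back = read_gff3(buf)
        assert sorted((m.contig, m.strand, m.exons) for m in back) == sorted(
            (m.contig, m.strand, m.exons) for m in merged
        )
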