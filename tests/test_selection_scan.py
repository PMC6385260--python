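"""dN/dS estimation, fast-evolving ranking, and enrichment statistics."""

import numpy as np
import pytest

from genomescape.errors import (
    EmptyInputError,
    InternalStopError,
    PartialCodonGapError,
    TranslationMismatchError,
)
from genomescape.gene_models import SENSE_CODONS, translate_cds
from genomescape.selection_scan import (
    CodonAlignment,
    backtranslate_alignment,
    fisher_enrichment,
    intersect_fast_de,
    ng86_dnds,
    rank_fast_evolving,
    strip_gap_codons,
)
from genomescape.sequtil import Alignment, SeqRecord, _gapped_rows
from oracles import hypergeom_tail, ng86_oracle


def _aa(seq, i="p"):
    return SeqRecord(i, seq, moltype="aa")


def _nt(seq, i="c"):
    return SeqRecord(i, seq, moltype="nt")


def _random_cds_pair(rng, n_codons, n_sub):
    """A stop-free CDS and a substituted copy, both stop-free."""
    while True:
        cds = "".join(rng.choice(SENSE_CODONS, size=n_codons))
        other = list(cds)
        for i in rng.choice(len(cds), size=n_sub, replace=False):
            other[i] = "ACGT"[int(rng.integers(4))]
        other = "".join(other)
        if "*" not in translate_cds(other):
            return cds, other


class TestBacktranslate:
    def test_gap_free_pair(self):
        aln = Alignment([("a", "MK"), ("b", "ML")])
        out = backtranslate_alignment(aln, _nt("ATGAAA"), _nt("ATGCTT"))
        assert out.seq_a == "ATGAAA" and out.seq_b == "ATGCTT"

    def test_protein_gap_becomes_triple_gap(self):
        aln = Alignment([("a", "M-K"), ("b", "MRK")])
        out = backtranslate_alignment(aln, _nt("ATGAAA"), _nt("ATGCGTAAA"))
        assert out.seq_a == "ATG---AAA"
        assert out.seq_b == "ATGCGTAAA"

    def test_terminal_stop_tolerated(self):
        aln = Alignment([("a", "MK"), ("b", "MK")])
        out = backtranslate_alignment(aln, _nt("ATGAAATGA"), _nt("ATGAAG"))
        assert out.seq_a == "ATGAAA"

    def test_translation_mismatch_names_position(self):
        aln = Alignment([("a", "MK"), ("b", "MK")])
        with pytest.raises(TranslationMismatchError, match="position 2"):
            backtranslate_alignment(aln, _nt("ATGCCC"), _nt("ATGAAA"))

    @pytest.mark.parametrize("seed", range(10))
    def test_roundtrip_translate_backtranslated_rows(self, seed):
        rng = np.random.default_rng(seed)
        cds_a, cds_b = _random_cds_pair(rng, 60, int(rng.integers(5, 40)))
        prot_a, prot_b = translate_cds(cds_a), translate_cds(cds_b)
        ra, rb = _gapped_rows(prot_a, prot_b)
        aln = Alignment([("a", ra), ("b", rb)])
        out = backtranslate_alignment(aln, _nt(cds_a), _nt(cds_b))
        assert translate_cds(out.seq_a.replace("-", "")) == prot_a
        assert translate_cds(out.seq_b.replace("-", "")) == prot_b


class TestStripGapCodons:
    def test_identity_on_gap_free(self):
        aln = CodonAlignment("ATGAAA", "ATGAAG")
        out = strip_gap_codons(aln)
        assert (out.seq_a, out.seq_b) == ("ATGAAA", "ATGAAG")

    def test_single_gap_column_removed(self):
        aln = CodonAlignment("ATG" + "---" + "AAA", "ATG" + "CGT" + "AAA")
        out = strip_gap_codons(aln)
        assert out.n_codons == 2 and "-" not in out.seq_a

    def test_matches_column_filter_oracle(self):
        rng = np.random.default_rng(2)
        codons_a, codons_b = [], []
        for _ in range(40):
            roll = rng.random()
            ca = "".join(rng.choice(list("ACGT"), size=3))
            cb = "".join(rng.choice(list("ACGT"), size=3))
            if roll < 0.15:
                ca = "---"
            elif roll < 0.3:
                cb = "---"
            codons_a.append(ca)
            codons_b.append(cb)
        out = strip_gap_codons(CodonAlignment("".join(codons_a), "".join(codons_b)))
        keep = [
            (ca, cb)
            for ca, cb in zip(codons_a, codons_b)
            if ca != "---" and cb != "---"
        ]
        assert out.seq_a == "".join(ca for ca, _ in keep)
        assert out.seq_b == "".join(cb for _, cb in keep)

    def test_partial_codon_gap_rejected(self):
        with pytest.raises(PartialCodonGapError):
            strip_gap_codons(CodonAlignment("A-GAAA", "ATGAAA"))


class TestNg86:
    def test_identical_sequences_zero_rates(self):
        res = ng86_dnds(CodonAlignment("ATGAAACCC", "ATGAAACCC"))
        assert res.ka == 0 and res.ks == 0

    def test_phe_to_leu_hand_tally(self):
        # TTT (Phe) -> TTA (Leu): one non-synonymous difference.
        # Sites: TTT has 1/3 synonymous (TTT->TTC), TTA has 2/3 (CTA, TTG),
        # averaged S = 0.5, N = 2.5; pN = 0.4 -> Ka = -3/4 ln(1 - 4/3*0.4)
        res = ng86_dnds(CodonAlignment("TTT", "TTA"))
        assert res.syn_sites == pytest.approx(0.5)
        assert res.nonsyn_sites == pytest.approx(2.5)
        assert res.ka == pytest.approx(0.571605, abs=1e-6)
        assert res.ks == 0

    def test_synonymous_only_divergence_has_zero_ka(self):
        # GGT->GGC is glycine->glycine; the other codons are untouched
        res = ng86_dnds(CodonAlignment("GGTAAACCC", "GGCAAACCC"))
        assert res.ka == 0 and res.ks > 0

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b = _random_cds_pair(rng, 30, 12)
            fwd = ng86_dnds(CodonAlignment(a, b))
            rev = ng86_dnds(CodonAlignment(b, a))
            assert fwd.ka == pytest.approx(rev.ka)
            assert fwd.ks == pytest.approx(rev.ks)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_independent_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = _random_cds_pair(rng, 40, int(rng.integers(3, 50)))
        res = ng86_dnds(CodonAlignment(a, b))
        ka_o, ks_o = ng86_oracle(a, b)
        if ka_o is None:
            assert res.ka is None
        else:
            assert res.ka == pytest.approx(ka_o, abs=1e-12)
        if ks_o is None:
            assert res.ks is None
        else:
            assert res.ks == pytest.approx(ks_o, abs=1e-12)

    def test_equal_rate_mutation_gives_ratio_near_one(self):
        # evolve both classes at the same per-site rate: dN/dS ~ 1
        rng = np.random.default_rng(4)
        ratios = []
        for _ in range(20):
            a, b = _random_cds_pair(rng, 300, 90)
            res = ng86_dnds(CodonAlignment(a, b))
            if res.ratio is not None:
                ratios.append(res.ratio)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.15)

    def test_internal_stop_rejected(self):
        with pytest.raises(InternalStopError):
            ng86_dnds(CodonAlignment("TAAAAA", "TAAAAA"))


class TestRankFastEvolving:
    @staticmethod
    def _results(kas):
        from genomescape.selection_scan import DnDsResult

        return {
            f"og{i:05d}": DnDsResult(ka, 0.1, None, 1, 2, 0, 0)
            for i, ka in enumerate(kas)
        }

    def test_study_scale_sizing(self):
        # 12,196 single-copy ortholog pairs -> top 10% is 1,220 pairs
        rng = np.random.default_rng(5)
        fast = rank_fast_evolving(self._results(rng.uniform(0, 2, size=12_196)))
        assert len(fast) == 1_220
        assert fast.n_ranked == 12_196

    def test_small_input_keeps_the_maximum(self):
        kas = [0.1, 0.9, 0.2, 0.3, 0.05, 0.4, 0.15, 0.25, 0.35, 0.45]
        fast = rank_fast_evolving(self._results(kas))
        assert len(fast) == 1
        assert fast.ids[0] == "og00001"  # the ka=0.9 pair

    def test_matches_sort_and_slice_oracle(self):
        rng = np.random.default_rng(6)
        kas = rng.uniform(0, 3, size=237)
        results = self._results(kas)
        fast = rank_fast_evolving(results, fraction=0.2)
        expected = sorted(results, key=lambda k: (-results[k].ka, k))
        size = int(np.floor(0.2 * 237 + 0.5))
        assert list(fast.ids) == expected[:size]

    def test_undefined_ka_excluded_and_reported(self):
        from genomescape.selection_scan import DnDsResult

        results = self._results([0.1] * 9)
        results["undef"] = DnDsResult(None, None, None, 1, 2, 3, 3)
        fast = rank_fast_evolving(results)
        assert fast.n_excluded == 1 and fast.n_ranked == 9

    def test_sizing_formula_round_half_up(self):
        rng = np.random.default_rng(7)
        for n in [1, 4, 5, 9, 10, 14, 15, 99, 100, 1001]:
            fast = rank_fast_evolving(self._results(rng.uniform(0, 1, n)))
            assert len(fast) == int(np.floor(0.1 * n + 0.5))

    def test_empty_input_raises(self):
        with pytest.raises(EmptyInputError):
            rank_fast_evolving({})


class TestFisherEnrichment:
    def test_term_exclusive_to_test_set_is_significant(self):
        test = {f"t{i}": {"GO:1"} for i in range(10)}
        ref = {f"r{i}": {"GO:2"} for i in range(50)}
        results = {r.term: r for r in fisher_enrichment(test, ref)}
        assert results["GO:1"].significant
        assert results["GO:1"].p_value < 1e-6

    def test_small_table_matches_summation_oracle(self):
        # k=3 of K=10 test genes vs n=5 of N=50 reference genes
        test = {f"t{i}": ({"GO:x"} if i < 3 else set()) for i in range(10)}
        ref = {f"r{i}": ({"GO:x"} if i < 5 else set()) for i in range(50)}
        (res,) = fisher_enrichment(test, ref)
        assert (res.k, res.K, res.n, res.N) == (3, 10, 5, 50)
        assert res.p_value == pytest.approx(hypergeom_tail(3, 10, 5, 50), rel=1e-9)

    def test_random_tables_match_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            K, N = int(rng.integers(5, 30)), int(rng.integers(30, 120))
            k = int(rng.integers(0, K + 1))
            n = int(rng.integers(0, N + 1))
            if k + n == 0:
                continue
            test = {f"t{i}": ({"T"} if i < k else set()) for i in range(K)}
            ref = {f"r{i}": ({"T"} if i < n else set()) for i in range(N)}
            (res,) = fisher_enrichment(test, ref)
            assert res.p_value == pytest.approx(hypergeom_tail(k, K, n, N), rel=1e-9)

    def test_p_monotone_in_overlap(self):
        prev = 1.0
        for k in range(0, 11):
            test = {f"t{i}": ({"T"} if i < k else set()) for i in range(10)}
            ref = {f"r{i}": ({"T"} if i < 20 - k else set()) for i in range(90)}
            (res,) = fisher_enrichment(test, ref)
            assert res.p_value <= prev + 1e-12
            prev = res.p_value

    def test_null_draws_keep_nominal_type_one_rate(self):
        # genes annotated at random: ~5% of terms reach p < 0.05
        rng = np.random.default_rng(9)
        n_terms = 1000
        test_genes = [f"g{i}" for i in range(100)]
        ref_genes = [f"g{i}" for i in range(100, 1100)]
        test_ann = {g: set() for g in test_genes}
        ref_ann = {g: set() for g in ref_genes}
        for t in range(n_terms):
            term = f"GO:{t:04d}"
            for g in rng.choice(test_genes + ref_genes, size=220, replace=False):
                (test_ann if g in test_ann else ref_ann)[g].add(term)
        results = fisher_enrichment(test_ann, ref_ann)
        rate = np.mean([r.significant for r in results])
        assert 0.03 <= rate <= 0.07


class TestIntersectFastDe:
    def test_disjoint_sets_all_zero(self):
        out = intersect_fast_de({"a", "b"}, {"c1": ({"x"}, {"y"})})
        assert out["c1"] == {"up": 0, "down": 0, "total": 0}
        assert out["union"]["total"] == 0

    def test_full_overlap_counts_set_sizes(self):
        fast = {"a", "b", "c"}
        out = intersect_fast_de(fast, {"c1": ({"a", "b"}, {"c"})})
        assert out["c1"] == {"up": 2, "down": 1, "total": 3}
        assert out["union"]["total"] == 3

    def test_random_planted_overlaps_match_set_algebra(self):
        rng = np.random.default_rng(10)
        genes = [f"g{i}" for i in range(500)]
        fast = set(rng.choice(genes, size=50, replace=False))
        de_sets = {}
        for c in ("heat_1h", "heat_6h"):
            up = set(rng.choice(genes, size=60, replace=False))
            down = set(rng.choice(sorted(set(genes) - up), size=40, replace=False))
            de_sets[c] = (up, down)
        out = intersect_fast_de(fast, de_sets)
        union = set()
        for c, (up, down) in de_sets.items():
            assert out[c]["up"] == len(fast & up)
            assert out[c]["down"] == len(fast & down)
            union |= fast & (up | down)
        assert out["union"]["total"] == len(union)
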