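"""dN-ranked selection scan over single-copy ortholog pairs.

Simulates diverged CDS pairs, computes Nei-Gojobori dN/dS through the
protein-guided codon alignment, ranks the top 10% by dN, and tests a GO
term planted on the fast-evolving set for enrichment.
"""

import numpy as np

from genomescape import (
    backtranslate_alignment,
    fisher_enrichment,
    ng86_dnds,
    rank_fast_evolving,
    strip_gap_codons,
)
from genomescape.gene_models import SENSE_CODONS, translate_cds
from genomescape.sequtil import Alignment, SeqRecord, _gapped_rows

rng = np.random.default_rng(11)
results = {}
for i in range(200):
    # fast pairs (first 20) diverge 3x more than the background
    n_sub = 30 if i < 20 else 10
    while True:
        cds_a = "".join(rng.choice(SENSE_CODONS, size=120))
        cds_b = list(cds_a)
        for j in rng.choice(len(cds_a), size=n_sub, replace=False):
            cds_b[j] = "ACGT"[int(rng.integers(4))]
        cds_b = "".join(cds_b)
        if "*" not in translate_cds(cds_b):
            break
    prot_a, prot_b = translate_cds(cds_a), translate_cds(cds_b)
    ra, rb = _gapped_rows(prot_a, prot_b)
    codon_aln = strip_gap_codons(
        backtranslate_alignment(
            Alignment([("a", ra), ("b", rb)]),
            SeqRecord("a", cds_a, moltype="nt"),
            SeqRecord("b", cds_b, moltype="nt"),
        )
    )
    results[f"og{i:04d}"] = ng86_dnds(codon_aln)

fast = rank_fast_evolving(results, fraction=0.10)
print(f"ranked {fast.n_ranked} ortholog pairs; top 10% = {len(fast)} pairs")
planted = {f"og{i:04d}" for i in range(20)}
print(f"planted fast-evolvers recovered in the top set: "
      f"{len(planted & set(fast.ids))}/20")

# plant a GO term on the fast set and test for over-representation
test_ann = {g: ({"GO:stress"} if g in planted else {"GO:house"})
            for g in fast.ids}
ref_ann = {g: {"GO:house"} for g in results if g not in fast}
for r in fisher_enrichment(test_ann, ref_ann):
    flag = "significant" if r.significant else "not significant"
    print(f"  {r.term}: k={r.k}/{r.K} vs {r.n}/{r.N}, p={r.p_value:.3g} ({flag})")
print("  -> dN alone ranks protein divergence; dS is too noisy between"
      " closely related genomes")
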