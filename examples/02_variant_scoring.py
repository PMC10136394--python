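"""Score variants against an offline knowledge snapshot.

The relevance score is w_p*pathogenicity + sum_s w_s*log2(1 + hits_s):
per-source evidence hits, log-saturated and weighted by editorial trust
(in-house historical cases 3.0 > CIViC 2.0 > generic databases 1.0 >
literature 0.5). The availability map shows the board which sources were
checked and how many entries each held.
"""

from mtbkit import (
    Config,
    KnowledgeSnapshot,
    Variant,
    VariantType,
    rank_variants,
    source_availability,
)
from mtbkit.scoring import EvidenceEntry


def entry(source, gene, drug="DRUG-001", protein=None):
    return EvidenceEntry(source_id=source, gene=gene, protein_change=protein,
                         drug=drug, evidence_level="m1A", citation="PMID:1")


snapshot = KnowledgeSnapshot(entries=(
    entry("civic", "KRAS"),
    entry("civic", "KRAS", protein="p.G12D"),
    entry("historical_cases", "KRAS", drug="DRUG-002"),
    entry("cosmic", "TP53"),
    entry("pubmed", "TP53", drug="DRUG-003"),
))

variants = [
    Variant(gene="KRAS", chrom="12", pos=25245350, ref="C", alt="T",
            variant_type=VariantType.SNV, protein_change="p.G12D",
            pathogenicity=0.8),
    Variant(gene="TP53", chrom="17", pos=7675088, ref="G", alt="A",
            variant_type=VariantType.SNV, protein_change="p.R175H",
            pathogenicity=0.9),
    Variant(gene="SETBP1", chrom="18", pos=44951, ref="A", alt="G",
            variant_type=VariantType.SNV, pathogenicity=0.2),
]

config = Config()
print("source availability for the KRAS variant (hits per source):")
for source, hits in sorted(source_availability(variants[0], snapshot, config).items()):
    print(f"  {source:<17} {hits}")

print("\nvariants ranked by relevance (score = pathogenicity + weighted log-hits):")
for i, (v, score) in enumerate(rank_variants(variants, snapshot, config), start=1):
    parts = " + ".join(
        f"{c.weight}*log2(1+{c.hits})"
        for c in score.per_source.values() if c.hits
    ) or "no source hits"
    print(f"  {i}. {score.variant_key:<28} total={score.total:.3f} "
          f"(pathogenicity {score.pathogenicity_component:.1f}; {parts})")
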