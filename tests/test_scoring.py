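"""Evidence matching and relevance scoring, checked against an independent
brute-force oracle."""

import math
import random

import pytest

from mtbkit import (
    Config,
    KnowledgeSnapshot,
    Variant,
    VariantType,
    match_entries,
    rank_variants,
    score_variant,
    source_availability,
    variant_key,
)
from mtbkit.scoring import EvidenceEntry


def brute_force_score(v, snapshot, config):
    """Independent oracle: filter entries, count per source, apply the
    formula term by term."""
    counts = {}
    for e in snapshot.entries:
        if e.gene == v.gene and (e.protein_change is None
                                 or e.protein_change == v.protein_change):
            counts[e.source_id] = counts.get(e.source_id, 0) + 1
    total = config.pathogenicity_weight * (v.pathogenicity or 0.0)
    for src, hits in counts.items():
        total += config.source_weights.get(src, 0.0) * math.log2(1 + hits)
    return total


def _entry(source, gene, protein=None, drug="DRUG-001"):
    return EvidenceEntry(source_id=source, gene=gene, protein_change=protein,
                         drug=drug, evidence_level="m1A", citation="PMID:1")


def _variant(gene="KRAS", protein="p.G12D", pathogenicity=None, pos=100):
    return Variant(gene=gene, chrom="12", pos=pos, ref="C", alt="T",
                   variant_type=VariantType.SNV, protein_change=protein,
                   pathogenicity=pathogenicity)


class TestMatching:
    def test_exact_protein_match(self, snapshot, kras_variant):
        matches = match_entries(kras_variant, snapshot)
        proteins = [e.protein_change for e in matches]
        assert None in proteins and "p.G12D" in proteins and "p.G13D" not in proteins

    def test_gene_level_entry_matches_any_variant(self):
        snap = KnowledgeSnapshot(entries=(_entry("civic", "KRAS"),))
        assert len(match_entries(_variant(protein="p.Q61H"), snap)) == 1

    def test_order_preserved(self, snapshot, kras_variant):
        matches = match_entries(kras_variant, snapshot)
        positions = [snapshot.entries.index(e) for e in matches]
        assert positions == sorted(positions)

    def test_availability_counts_with_zeros(self, snapshot, kras_variant, config):
        counts = source_availability(kras_variant, snapshot, config)
        assert counts["civic"] == 2
        assert counts["historical_cases"] == 1
        assert counts["cosmic"] == 0  # registered source, no matches

    def test_unknown_gene_all_zeros(self, snapshot, config):
        counts = source_availability(_variant(gene="NOPE"), snapshot, config)
        assert set(counts.values()) == {0}


class TestScoreVariant:
    def test_zero_case(self, config):
        score = score_variant(_variant(), KnowledgeSnapshot(), config)
        assert score.total == 0.0

    def test_worked_example(self, config):
        """p=0.8, 2 civic hits, 1 historical hit under default weights:
        0.8 + 2.0*log2(3) + 3.0*log2(2) = 6.9699 (frozen from the oracle)."""
        snap = KnowledgeSnapshot(entries=(
            _entry("civic", "KRAS"), _entry("civic", "KRAS"),
            _entry("historical_cases", "KRAS"),
        ))
        v = _variant(pathogenicity=0.8, protein=None)
        score = score_variant(v, snap, config)
        expected = 0.8 + 2.0 * math.log2(3) + 3.0 * math.log2(2)
        assert score.total == pytest.approx(expected, abs=1e-9)
        assert score.total == pytest.approx(6.969925001442312, abs=1e-6)
        assert score.pathogenicity_component == pytest.approx(0.8)
        assert score.per_source["civic"].hits == 2
        assert score.total == pytest.approx(
            score.pathogenicity_component
            + sum(c.contribution for c in score.per_source.values())
        )

    def test_historical_beats_literature_at_equal_hits(self, config):
        v = _variant(pathogenicity=0.5, protein=None)
        hist = KnowledgeSnapshot(entries=tuple(_entry("historical_cases", "KRAS")
                                               for _ in range(2)))
        pub = KnowledgeSnapshot(entries=tuple(_entry("pubmed", "KRAS")
                                              for _ in range(2)))
        assert score_variant(v, hist, config).total > score_variant(v, pub, config).total

    def test_unknown_source_contributes_zero(self, config):
        snap = KnowledgeSnapshot(entries=(_entry("mystery_db", "KRAS"),))
        score = score_variant(_variant(protein=None), snap, config)
        assert score.total == 0.0
        assert score.per_source["mystery_db"].hits == 1

    def test_entry_order_permutation_invariant(self, config):
        entries = [_entry("civic", "KRAS"), _entry("pubmed", "KRAS"),
                   _entry("cosmic", "KRAS"), _entry("historical_cases", "KRAS")]
        v = _variant(pathogenicity=0.3, protein=None)
        totals = {
            score_variant(v, KnowledgeSnapshot(entries=tuple(p)), config).total
            for p in ([entries[i] for i in order]
                      for order in ([0, 1, 2, 3], [3, 2, 1, 0], [2, 0, 3, 1]))
        }
        assert len(totals) == 1


def _random_draw(rng):
    sources = ["civic", "cosmic", "pubmed", "historical_cases", "mastermind",
               "ascopubs", "mystery"]
    genes = ["KRAS", "TP53", "SETBP1", "LRRK1"]
    entries = tuple(
        _entry(rng.choice(sources), rng.choice(genes),
               protein=rng.choice([None, "p.G12D", "p.R175H"]))
        for _ in range(rng.randint(0, 30))
    )
    v = _variant(gene=rng.choice(genes),
                 protein=rng.choice([None, "p.G12D", "p.R175H"]),
                 pathogenicity=rng.choice([None, round(rng.random(), 3)]))
    return v, KnowledgeSnapshot(entries=entries)


class TestOracleProperties:
    def test_oracle_equivalence_and_monotonicity(self, config):
        """1000 random draws: implementation == brute force within 1e-9, and
        adding one matching positive-weight entry never decreases the total."""
        rng = random.Random(123)
        for _ in range(1000):
            v, snap = _random_draw(rng)
            total = score_variant(v, snap, config).total
            assert total == pytest.approx(brute_force_score(v, snap, config), abs=1e-9)
            src = rng.choice(["civic", "historical_cases", "pubmed"])
            bigger = KnowledgeSnapshot(
                entries=snap.entries + (_entry(src, v.gene, protein=v.protein_change),)
            )
            assert score_variant(v, bigger, config).total >= total


class TestRankVariants:
    def test_descending_with_tie_break(self, config):
        snap = KnowledgeSnapshot(entries=(_entry("civic", "KRAS"),))
        a = _variant(gene="KRAS", protein=None, pathogenicity=0.9)
        zero1 = _variant(gene="AAA", protein=None, pos=1)
        zero2 = _variant(gene="BBB", protein=None, pos=2)
        ranked = rank_variants([zero2, a, zero1], snap, config)
        assert [v.gene for v, _ in ranked] == ["KRAS", "AAA", "BBB"]
        totals = [s.total for _, s in ranked]
        assert totals == sorted(totals, reverse=True)

    def test_input_permutation_invariant(self, config, snapshot):
        variants = [_variant(gene=g, pos=p, protein=None)
                    for g, p in [("KRAS", 5), ("TP53", 9), ("LRRK1", 2)]]
        base = rank_variants(variants, snapshot, config)
        for perm in ([2, 0, 1], [1, 2, 0]):
            assert rank_variants([variants[i] for i in perm], snapshot, config) == base
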