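from datetime import date, datetime, timezone

import pytest

from mtbkit import (
    Annotation,
    Case,
    Config,
    EvidenceScale,
    KnowledgeSnapshot,
    Transition,
    Variant,
    VariantType,
    WorkflowState,
)
from mtbkit.scoring import EvidenceEntry

TS = datetime(2023, 1, 2, 9, 0, tzinfo=timezone.utc)


@pytest.fixture
def scale() -> EvidenceScale:
    return EvidenceScale()


@pytest.fixture
def config() -> Config:
    return Config()


@pytest.fixture
def kras_variant() -> Variant:
    return Variant(
        gene="KRAS",
        chrom="12",
        pos=25245350,
        ref="C",
        alt="T",
        variant_type=VariantType.SNV,
        protein_change="p.G12D",
        pathogenicity=0.8,
    )


@pytest.fixture
def tp53_variant() -> Variant:
    return Variant(
        gene="TP53", chrom="17", pos=7675088, ref="G", alt="A",
        variant_type=VariantType.SNV, protein_change="p.R175H", pathogenicity=0.9,
    )


@pytest.fixture
def valid_case(kras_variant, tp53_variant) -> Case:
    return Case(
        case_id="CASE-0001",
        age_years=61,
        sex="female",
        diagnosis_code="C25.1",
        diagnosis_text="pancreatic adenocarcinoma, body",
        variants=(kras_variant, tp53_variant),
        annotations=(
            Annotation(
                variant_key="12:25245350:C>T|KRAS",
                drug="DRUG-001",
                evidence_level="m1A",
                source_id="civic",
                citation="PMID:12345678",
                reasoning="sensitizing alteration",
                author="expert",
                timestamp=TS,
            ),
        ),
        state=WorkflowState.BACKLOG,
        transitions=(
            Transition(from_state=None, to_state=WorkflowState.BACKLOG, timestamp=TS, actor="t"),
        ),
        group_id="GRP-A",
        panel_size_mb=1.5,
    )


@pytest.fixture
def snapshot() -> KnowledgeSnapshot:
    def entry(source, gene, drug="DRUG-001", protein=None, level="m1A"):
        return EvidenceEntry(
            source_id=source, gene=gene, protein_change=protein, drug=drug,
            evidence_level=level, citation="PMID:1",
        )

    return KnowledgeSnapshot(
        entries=(
            entry("civic", "KRAS"),
            entry("civic", "KRAS", protein="p.G12D"),
            entry("civic", "KRAS", protein="p.G13D"),
            entry("historical_cases", "KRAS"),
            entry("cosmic", "TP53"),
            entry("pubmed", "TP53", drug="DRUG-002"),
        )
    )
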