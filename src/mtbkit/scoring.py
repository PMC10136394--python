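"""Evidence matching and source-weighted variant relevance scoring.

For each variant the engine counts matching entries in every offline
knowledge-source snapshot (the availability matrix shown next to a
variant), then aggregates them into one relevance score:

    total = w_p * pathogenicity + sum_s  w_s * log2(1 + hits_s)

The log2(1 + hits) saturation stops a single chatty source from dominating
the ranking by sheer entry count; the per-source weights express editorial
trust (historical in-house cases > CIViC > generic databases > raw
literature). All weights are configurable per site.
"""

from __future__ import annotations

import math

from pydantic import BaseModel, ConfigDict, model_validator

from .config import Config, DEFAULT_CONFIG
from .model import Variant, variant_key


class EvidenceEntry(BaseModel):
    """One record from an offline knowledge-source snapshot.

    Entries are keyed on gene symbol plus an optional protein change, the
    way public cancer knowledge bases index their content. An entry with no
    protein change is gene-level evidence and matches every variant of the
    gene.
    """

    model_config = ConfigDict(extra="forbid")

    source_id: str
    gene: str
    protein_change: str | None = None
    drug: str
    evidence_level: str
    citation: str
    summary: str | None = None

    @model_validator(mode="after")
    def _nonempty(self) -> "EvidenceEntry":
        if not self.gene or not self.drug:
            raise ValueError("gene and drug must be non-empty")
        return self


class KnowledgeSnapshot(BaseModel):
    model_config = ConfigDict(extra="forbid")

    entries: tuple[EvidenceEntry, ...] = ()

    @property
    def sources(self) -> set[str]:
        return {e.source_id for e in self.entries}


class SourceContribution(BaseModel):
    model_config = ConfigDict(extra="forbid")

    hits: int
    weight: float
    contribution: float


class RelevanceScore(BaseModel):
    model_config = ConfigDict(extra="forbid")

    variant_key: str
    pathogenicity_component: float
    per_source: dict[str, SourceContribution]
    total: float


def match_entries(v: Variant, snapshot: KnowledgeSnapshot) -> list[EvidenceEntry]:
    """Entries matching the variant: same gene, and either gene-level
    evidence (no protein change on the entry) or the exact protein change.
    Snapshot order is preserved."""
    return [
        e
        for e in snapshot.entries
        if e.gene == v.gene
        and (e.protein_change is None or e.protein_change == v.protein_change)
    ]


def source_availability(
    v: Variant, snapshot: KnowledgeSnapshot, config: Config | None = None
) -> dict[str, int]:
    """Per-source match counts; configured sources report 0 even when the
    snapshot holds nothing for them, so the board sees 'checked, empty'
    rather than nothing."""
    config = config or DEFAULT_CONFIG
    counts: dict[str, int] = {s: 0 for s in config.source_weights}
    for e in match_entries(v, snapshot):
        counts[e.source_id] = counts.get(e.source_id, 0) + 1
    return counts


def score_variant(
    v: Variant, snapshot: KnowledgeSnapshot, config: Config | None = None
) -> RelevanceScore:
    """Source-weighted relevance score with full component breakdown."""
    config = config or DEFAULT_CONFIG
    counts = source_availability(v, snapshot, config)
    p = v.pathogenicity if v.pathogenicity is not None else 0.0
    p_component = config.pathogenicity_weight * p
    per_source: dict[str, SourceContribution] = {}
    total = p_component
    for src in sorted(counts):
        hits = counts[src]
        # unregistered sources carry weight 0: visible in the breakdown,
        # silent in the total
        weight = config.source_weights.get(src, 0.0)
        contribution = weight * math.log2(1 + hits)
        per_source[src] = SourceContribution(
            hits=hits, weight=weight, contribution=contribution
        )
        total += contribution
    return RelevanceScore(
        variant_key=variant_key(v),
        pathogenicity_component=p_component,
        per_source=per_source,
        total=total,
    )


def rank_variants(
    variants: list[Variant],
    snapshot: KnowledgeSnapshot,
    config: Config | None = None,
) -> list[tuple[Variant, RelevanceScore]]:
    """Variants in descending relevance order.

    Ties break by (gene, variant key) ascending so the ranking is a pure
    function of the variant set, independent of input order.
    """
    config = config or DEFAULT_CONFIG
    scored = [(v, score_variant(v, snapshot, config)) for v in variants]
    scored.sort(key=lambda pair: (-pair[1].total, pair[0].gene, pair[1].variant_key))
    return scored
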