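"""Annotation capture and the prioritized treatment-recommendation list.

Each expert annotation (variant + drug + evidence level + source +
reasoning) becomes one recommendation row. Rows are ordered by a declared,
fully deterministic key:

    1. evidence rank, strongest first
    2. prior treatment failure of the drug (untried drugs first) — failure
       demotes within an evidence tier, it never hides an option
    3. trial feasibility (feasible sites first)
    4. relevance score of the underlying variant, highest first
    5. drug name, alphabetical

Ranks are assigned 1..n with no gaps.
"""

from __future__ import annotations

from .errors import UnknownVariantError
from .model import (
    Annotation,
    Case,
    DEFAULT_EVIDENCE_SCALE,
    EvidenceScale,
    RecommendationItem,
    evidence_rank,
)


def add_annotation(
    case: Case, annotation: Annotation, scale: EvidenceScale = DEFAULT_EVIDENCE_SCALE
) -> Case:
    """Append an annotation after referential checks: the variant key must
    exist in the case and the evidence level in the scale."""
    evidence_rank(annotation.evidence_level, scale)  # raises on unknown level
    if annotation.variant_key not in case.variant_keys():
        raise UnknownVariantError(
            f"annotation references variant {annotation.variant_key!r}, "
            f"not present in case {case.case_id}"
        )
    return case.model_copy(update={"annotations": case.annotations + (annotation,)})


def _sort_key(item: RecommendationItem, scale: EvidenceScale, relevance: dict[str, float]):
    return (
        evidence_rank(item.evidence_level, scale),
        item.prior_failure,            # False (untried) sorts first
        not item.feasible,             # feasible sorts first
        -relevance.get(item.variant_key, 0.0),
        item.drug,
    )


def rank_recommendations(
    case: Case,
    scale: EvidenceScale = DEFAULT_EVIDENCE_SCALE,
    relevance: dict[str, float] | None = None,
    trial_sites: set[str] | None = None,
) -> list[RecommendationItem]:
    """Build the prioritized recommendation list from the case annotations.

    ``relevance`` maps variant key to relevance-score total (from the
    scoring module). ``trial_sites``, when given, marks an item feasible
    only if its citation is among the listed sites; with no site list every
    item is feasible — geographic feasibility reduces to membership.
    """
    relevance = relevance or {}
    failed_drugs = {drug for drug, failed in case.prior_therapies.items() if failed}
    items = [
        RecommendationItem(
            drug=ann.drug,
            evidence_level=ann.evidence_level,
            variant_key=ann.variant_key,
            source_id=ann.source_id,
            citation=ann.citation,
            prior_failure=ann.drug in failed_drugs,
            feasible=trial_sites is None or ann.citation in trial_sites,
            rationale=ann.reasoning,
            rank=1,  # placeholder, assigned below
        )
        for ann in case.annotations
    ]
    items.sort(key=lambda it: _sort_key(it, scale, relevance))
    return [it.model_copy(update={"rank": i + 1}) for i, it in enumerate(items)]
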