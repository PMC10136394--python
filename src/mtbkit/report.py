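"""Presentation and documentation rendering plus follow-up statistics.

The one-command presentation assembles everything a board needs to discuss
a case into a deterministic Markdown document: case summary, mutation
burden, signature labels, the functional-variant table with per-source
evidence availability, similar cases, annotations and the prioritized
recommendations. Rendering is a pure function of its inputs — identical
inputs give byte-identical output — so decks can be regenerated and
diffed.

Mutational signatures are not computed here: the labels arrive precomputed
on the case and are passed through verbatim, or the section reads "not
available".
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, model_validator

from .config import Config, DEFAULT_CONFIG
from .errors import (
    MissingDocumentationError,
    MissingPanelSizeError,
    WrongStateError,
)
from .model import (
    Case,
    DocumentationRecord,
    RecommendationItem,
    TherapyReceived,
    Variant,
    VariantType,
    WorkflowState,
)
from .scoring import RelevanceScore
from .similarity import SimilarityResult

PRESENTATION_SECTIONS = (
    "Case Summary",
    "Mutation Burden",
    "Tumor Signatures",
    "Functional Variants",
    "Similar Cases",
    "Annotations",
    "Recommendations",
)


class FollowUpStats(BaseModel):
    """Aggregate recommendation-acceptance statistics across cases.

    ``acceptance_rate`` is applied / (applied + not applied) over known
    outcomes; when no outcome is known it is None and
    ``acceptance_rate_defined`` is False.
    """

    model_config = ConfigDict(extra="forbid")

    n_cases: int
    n_applied: int
    n_not_applied: int
    n_unknown: int
    acceptance_rate: float | None = None
    acceptance_rate_defined: bool = False
    side_effect_counts: dict[str, int] = {}

    @model_validator(mode="after")
    def _check(self) -> "FollowUpStats":
        if self.n_applied + self.n_not_applied + self.n_unknown != self.n_cases:
            raise ValueError("outcome counts must sum to n_cases")
        return self


def mutation_burden(variants: tuple[Variant, ...] | list[Variant], panel_size_mb: float | None) -> float:
    """Small-variant count (SNV + INDEL) per megabase of sequenced panel."""
    if panel_size_mb is None or panel_size_mb <= 0:
        raise MissingPanelSizeError(
            f"panel size in megabases must be positive (got {panel_size_mb})"
        )
    n = sum(1 for v in variants if v.variant_type in (VariantType.SNV, VariantType.INDEL))
    return n / panel_size_mb


def render_presentation(
    case: Case,
    ranked_variants: list[tuple[Variant, RelevanceScore]],
    recommendations: list[RecommendationItem],
    similar: list[SimilarityResult],
    config: Config | None = None,
) -> str:
    """Render the meeting deck for a researched or scheduled case."""
    config = config or DEFAULT_CONFIG
    if case.state not in (WorkflowState.RESEARCHED, WorkflowState.SCHEDULED):
        raise WrongStateError(
            "presentation requires a RESEARCHED or SCHEDULED case "
            f"(case is {case.state.value})"
        )
    lines: list[str] = [f"# Case {case.case_id}", ""]

    lines += [f"## {PRESENTATION_SECTIONS[0]}", ""]
    lines.append(f"- Pseudonym: {case.case_id}")
    lines.append(f"- Age: {case.age_years} years, sex: {case.sex.value}")
    lines.append(f"- Diagnosis: {case.diagnosis_code} {case.diagnosis_text}".rstrip())
    if case.clinical_history:
        lines.append("- Clinical history:")
        lines += [f"    - {ev.date.isoformat()}: {ev.description}" for ev in case.clinical_history]
    if case.prior_therapies:
        flagged = ", ".join(
            f"{drug}{' (failed)' if failed else ''}"
            for drug, failed in sorted(case.prior_therapies.items())
        )
        lines.append(f"- Prior therapies: {flagged}")
    lines.append("")

    lines += [f"## {PRESENTATION_SECTIONS[1]}", ""]
    if case.panel_size_mb:
        tmb = mutation_burden(case.variants, case.panel_size_mb)
        lines.append(
            f"{tmb:.2f} mutations/Mb ({sum(1 for v in case.variants if v.variant_type in (VariantType.SNV, VariantType.INDEL))} "
            f"small variants over {case.panel_size_mb} Mb)"
        )
    else:
        lines.append("not available (no panel size recorded)")
    lines.append("")

    lines += [f"## {PRESENTATION_SECTIONS[2]}", ""]
    if case.precomputed_signatures:
        lines += [f"- {sig}" for sig in case.precomputed_signatures]
    else:
        lines.append("not available")
    lines.append("")

    lines += [f"## {PRESENTATION_SECTIONS[3]}", ""]
    if ranked_variants:
        sources = sorted(config.source_weights)
        header = "| # | Variant | Gene | Score | " + " | ".join(sources) + " |"
        lines.append(header)
        lines.append("|" + "---|" * (4 + len(sources)))
        for i, (v, score) in enumerate(ranked_variants, start=1):
            hits = [str(score.per_source[s].hits) if s in score.per_source else "0" for s in sources]
            lines.append(
                f"| {i} | {score.variant_key} | {v.gene} | {score.total:.3f} | "
                + " | ".join(hits)
                + " |"
            )
    else:
        lines.append("no variants")
    lines.append("")

    lines += [f"## {PRESENTATION_SECTIONS[4]}", ""]
    if similar:
        for r in similar:
            lines.append(
                f"- {r.other_case_id} (level {int(r.level)}, score {r.score:.3f}; "
                f"matched: {', '.join(r.matched_features) or 'none'})"
            )
    else:
        lines.append("none found")
    lines.append("")

    lines += [f"## {PRESENTATION_SECTIONS[5]}", ""]
    if case.annotations:
        for ann in case.annotations:
            lines.append(
                f"- {ann.variant_key}: {ann.drug} [{ann.evidence_level}] "
                f"({ann.source_id}, {ann.citation}) — {ann.reasoning or 'no reasoning recorded'}"
            )
    else:
        lines.append("no annotations")
    lines.append("")

    lines += [f"## {PRESENTATION_SECTIONS[6]}", ""]
    if recommendations:
        lines.append("| Rank | Drug | Evidence | Variant | Prior failure | Feasible |")
        lines.append("|---|---|---|---|---|---|")
        for item in recommendations:
            lines.append(
                f"| {item.rank} | {item.drug} | {item.evidence_level} | {item.variant_key} "
                f"| {'yes' if item.prior_failure else 'no'} | {'yes' if item.feasible else 'no'} |"
            )
    else:
        lines.append("no recommendations")
    lines.append("")

    return "\n".join(lines)


def render_documentation(case: Case) -> tuple[DocumentationRecord, str]:
    """Render the board-decision report sent to the treating physician."""
    if case.documentation is None:
        raise MissingDocumentationError(f"case {case.case_id} has no documentation record")
    doc = case.documentation
    lines = [f"# Board Documentation — Case {case.case_id}", ""]
    lines.append(f"Signed by: {doc.signed_by or 'unsigned'}")
    lines.append(f"Documented: {doc.timestamp.isoformat()}")
    lines.append("")
    lines.append("## Treatment Recommendations")
    lines.append("")
    if doc.recommendations:
        for item in doc.recommendations:
            lines.append(
                f"{item.rank}. {item.drug} [{item.evidence_level}] for {item.variant_key} "
                f"({item.source_id}, {item.citation})"
            )
    else:
        lines.append("none")
    lines.append("")
    if doc.clinical_trials:
        lines.append("## Clinical Trials")
        lines.append("")
        lines += [f"- {t}" for t in doc.clinical_trials]
        lines.append("")
    lines.append("## Remarks")
    lines.append("")
    lines.append(doc.remarks or "none")
    lines.append("")
    return doc, "\n".join(lines)


def followup_statistics(cases: list[Case]) -> FollowUpStats:
    """Count therapy uptake and side effects over follow-up records.

    Cases without a follow-up record count as unknown outcome.
    """
    n_applied = n_not = n_unknown = 0
    side_effects: dict[str, int] = {}
    for case in cases:
        fu = case.follow_up
        if fu is None or fu.therapy_received == TherapyReceived.UNKNOWN:
            n_unknown += 1
        elif fu.therapy_received == TherapyReceived.YES:
            n_applied += 1
        else:
            n_not += 1
        if fu is not None:
            for term in fu.side_effects:
                side_effects[term] = side_effects.get(term, 0) + 1
    denom = n_applied + n_not
    return FollowUpStats(
        n_cases=len(cases),
        n_applied=n_applied,
        n_not_applied=n_not,
        n_unknown=n_unknown,
        acceptance_rate=(n_applied / denom) if denom else None,
        acceptance_rate_defined=denom > 0,
        side_effect_counts=dict(sorted(side_effects.items())),
    )
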