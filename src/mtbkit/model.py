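"""Domain types for molecular-tumor-board cases.

A :class:`Case` is a pseudonymized patient record moving through a Kanban
lifecycle (backlog -> researched -> scheduled -> follow-up -> closed) while
accumulating genetic variants, expert annotations and, eventually, a
documented treatment decision and a follow-up record.

Construction is intentionally lenient about *domain* invariants (an age of
-1 constructs fine) so that :func:`validate_case` can report every breach
as a named violation instead of raising on the first one; only structural
typing is enforced by the models themselves. Unknown fields are rejected
everywhere, which is what keeps the case schema a whitelist.
"""

from __future__ import annotations

import re
from datetime import date, datetime
from enum import Enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, field_validator

from .errors import UnknownEvidenceLevelError

DEFAULT_PSEUDONYM_PATTERN = r"^[A-Za-z0-9_-]{4,64}$"

_ALLELE_RE = re.compile(r"^[ACGT]+$")


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"
    OTHER = "other"
    UNKNOWN = "unknown"


class VariantType(str, Enum):
    SNV = "SNV"
    INDEL = "INDEL"
    CNV = "CNV"
    FUSION = "FUSION"


class GeneRole(str, Enum):
    """Gene role in tumorigenesis, Cancer Gene Census style."""

    ONCOGENE = "oncogene"
    TSG = "TSG"
    FUSION = "fusion"
    UNKNOWN = "unknown"


class WorkflowState(str, Enum):
    """Kanban column of a case. CLOSED is the terminal state reached after
    the follow-up has been recorded; the board hides it by default."""

    BACKLOG = "BACKLOG"
    RESEARCHED = "RESEARCHED"
    SCHEDULED = "SCHEDULED"
    FOLLOW_UP = "FOLLOW_UP"
    CLOSED = "CLOSED"


class TherapyReceived(str, Enum):
    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


class NotificationKind(str, Enum):
    CASE_CREATED = "CASE_CREATED"
    CASE_SCHEDULED = "CASE_SCHEDULED"
    FOLLOW_UP_DUE = "FOLLOW_UP_DUE"


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=False)


class EvidenceScale(_Model):
    """Ordered drug-evidence levels, strongest first.

    The default is an eight-level ordinal scale in the style used by
    German precision-oncology programs (m1A strongest ... m4 weakest);
    sites using a different taxonomy configure their own sequence.
    """

    levels: tuple[str, ...] = ("m1A", "m1B", "m1C", "m2A", "m2B", "m2C", "m3", "m4")

    @field_validator("levels")
    @classmethod
    def _unique_nonempty(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if not v:
            raise ValueError("evidence scale must have at least one level")
        if len(set(v)) != len(v):
            raise ValueError("evidence levels must be unique")
        if any(not lvl for lvl in v):
            raise ValueError("evidence levels must be non-empty strings")
        return v


DEFAULT_EVIDENCE_SCALE = EvidenceScale()


def evidence_rank(level: str, scale: EvidenceScale = DEFAULT_EVIDENCE_SCALE) -> int:
    """Position of ``level`` in the scale; 0 is strongest.

    Raises :class:`UnknownEvidenceLevelError` for levels outside the scale,
    so callers can never silently rank an unknown grade.
    """
    try:
        return scale.levels.index(level)
    except ValueError:
        raise UnknownEvidenceLevelError(
            f"unknown evidence level {level!r}; scale is {list(scale.levels)}"
        ) from None


class Variant(_Model):
    """One genetic alteration.

    Coordinates are 1-based and inclusive with VCF-style ref/alt alleles.
    ``pathogenicity`` is an externally computed functional-effect score in
    [0, 1]; it is consumed as data, never recomputed here.
    """

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_type: VariantType
    protein_change: Optional[str] = None
    pathogenicity: Optional[float] = None
    gene_role: Optional[GeneRole] = None


def variant_key(v: Variant) -> str:
    """Deterministic identity key for a variant.

    SNV/INDEL: ``chrom:pos:ref>alt|gene`` (injective over distinct
    coordinate/allele/gene tuples). CNV/FUSION: ``gene|type`` — copy-number
    and fusion events are keyed per gene because public knowledge bases do.
    """
    if v.variant_type in (VariantType.SNV, VariantType.INDEL):
        return f"{v.chrom}:{v.pos}:{v.ref}>{v.alt}|{v.gene}"
    return f"{v.gene}|{v.variant_type.value}"


class Annotation(_Model):
    """Expert-curated link between a variant and a drug with evidence."""

    variant_key: str
    drug: str
    evidence_level: str
    source_id: str
    citation: str
    reasoning: str = ""
    author: str = ""
    timestamp: datetime


class Transition(_Model):
    """One audit-trail entry; ``from_state`` is None for the synthetic
    creation entry (nothing -> BACKLOG)."""

    from_state: Optional[WorkflowState] = None
    to_state: WorkflowState
    timestamp: datetime
    actor: str
    note: Optional[str] = None


class Postponement(_Model):
    reason: str
    open_questions: tuple[str, ...]
    timestamp: datetime


class HistoryEvent(_Model):
    date: date
    description: str


class MeetingRef(_Model):
    meeting_id: str
    date: date
    capacity: int = 10


class Notification(_Model):
    """Emitted workflow event record; delivery is hospital-IT's concern."""

    kind: NotificationKind
    case_id: str
    timestamp: datetime
    recipients: tuple[str, ...] = ()


class FollowUpRecord(_Model):
    """Outcome of the 3-6 month reassessment after the board meeting."""

    therapy_received: TherapyReceived
    medication: Optional[str] = None
    doses: Optional[str] = None
    side_effects: tuple[str, ...] = ()
    vital_status: Optional[str] = None
    recorded_on: date


class RecommendationItem(_Model):
    """One row of the prioritized treatment-recommendation list."""

    drug: str
    evidence_level: str
    variant_key: str
    source_id: str
    citation: str
    prior_failure: bool = False
    feasible: bool = True
    rationale: str = ""
    rank: int


class DocumentationRecord(_Model):
    """The board's documented decision: recommendations, trials, remarks."""

    recommendations: tuple[RecommendationItem, ...] = ()
    clinical_trials: tuple[str, ...] = ()
    remarks: str = ""
    signed_by: str = ""
    timestamp: datetime


class Case(_Model):
    """Pseudonymized patient case.

    ``prior_therapies`` maps drug name to a failed/not-failed flag.
    ``precomputed_signatures`` carries mutational-signature labels computed
    upstream; they are passed through verbatim into presentations.
    """

    case_id: str
    age_years: int
    sex: Sex
    diagnosis_code: str
    diagnosis_text: str = ""
    clinical_history: tuple[HistoryEvent, ...] = ()
    prior_therapies: dict[str, bool] = {}
    lab_flags: tuple[str, ...] = ()
    variants: tuple[Variant, ...] = ()
    annotations: tuple[Annotation, ...] = ()
    state: WorkflowState = WorkflowState.BACKLOG
    transitions: tuple[Transition, ...] = ()
    group_id: str = ""
    scheduled_meeting: Optional[MeetingRef] = None
    postponements: tuple[Postponement, ...] = ()
    documentation: Optional[DocumentationRecord] = None
    follow_up: Optional[FollowUpRecord] = None
    precomputed_signatures: Optional[tuple[str, ...]] = None
    panel_size_mb: Optional[float] = None

    def variant_keys(self) -> set[str]:
        return {variant_key(v) for v in self.variants}


def _validate_variant(v: Variant, prefix: str) -> list[str]:
    out = []
    if v.pos < 1:
        out.append(f"{prefix}.pos: must be >= 1 (got {v.pos})")
    if v.variant_type in (VariantType.SNV, VariantType.INDEL):
        if not _ALLELE_RE.match(v.ref):
            out.append(f"{prefix}.ref: must be a non-empty string over ACGT (got {v.ref!r})")
        if not _ALLELE_RE.match(v.alt):
            out.append(f"{prefix}.alt: must be a non-empty string over ACGT (got {v.alt!r})")
    if v.pathogenicity is not None and not (0.0 <= v.pathogenicity <= 1.0):
        out.append(f"{prefix}.pathogenicity: must lie in [0, 1] (got {v.pathogenicity})")
    if not v.gene:
        out.append(f"{prefix}.gene: must be non-empty")
    return out


def validate_case(
    case: Case,
    *,
    pseudonym_pattern: str = DEFAULT_PSEUDONYM_PATTERN,
    scale: EvidenceScale = DEFAULT_EVIDENCE_SCALE,
) -> list[str]:
    """Check every case invariant; return one description per breach.

    Returns an empty list exactly when the case is valid. Violations name
    the offending field so callers can surface them verbatim.
    """
    violations: list[str] = []
    if not re.match(pseudonym_pattern, case.case_id):
        violations.append(
            f"case_id: {case.case_id!r} does not match pseudonym pattern {pseudonym_pattern!r}"
        )
    if case.age_years < 0:
        violations.append(f"age_years: must be non-negative (got {case.age_years})")
    for i, v in enumerate(case.variants):
        violations.extend(_validate_variant(v, f"variants[{i}]"))
    keys = case.variant_keys()
    for i, ann in enumerate(case.annotations):
        if ann.evidence_level not in scale.levels:
            violations.append(
                f"annotations[{i}].evidence_level: {ann.evidence_level!r} not in scale"
            )
        if ann.variant_key not in keys:
            violations.append(
                f"annotations[{i}].variant_key: {ann.variant_key!r} references no case variant"
            )
    if case.transitions and case.transitions[-1].to_state != case.state:
        violations.append(
            "transitions: final entry target "
            f"{case.transitions[-1].to_state.value} != state {case.state.value}"
        )
    for i, p in enumerate(case.postponements):
        if not p.reason:
            violations.append(f"postponements[{i}].reason: must be non-empty")
        if not p.open_questions or any(not q for q in p.open_questions):
            violations.append(f"postponements[{i}].open_questions: must be non-empty")
    if case.follow_up is not None:
        fu = case.follow_up
        if fu.therapy_received == TherapyReceived.YES and not fu.medication:
            violations.append("follow_up.medication: required when therapy_received is yes")
    if case.documentation is not None:
        doc = case.documentation
        if not doc.recommendations and not doc.remarks:
            violations.append(
                "documentation: at least one of recommendations/remarks must be non-empty"
            )
    if case.panel_size_mb is not None and case.panel_size_mb <= 0:
        violations.append(f"panel_size_mb: must be positive (got {case.panel_size_mb})")
    return violations
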