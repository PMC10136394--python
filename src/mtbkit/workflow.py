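"""Case lifecycle: guarded Kanban transitions, scheduling, follow-up timing.

The board has four working columns (backlog, researched, scheduled,
follow-up) plus a terminal CLOSED state entered once the follow-up record
exists. Exactly six transitions are legal, each protected by a guard
artifact that must be present on the case:

    BACKLOG   -> RESEARCHED   at least one annotation, or an explicit
                              no-actionable-findings flag
    RESEARCHED-> SCHEDULED    only via schedule_case (meeting with capacity)
    SCHEDULED -> FOLLOW_UP    documentation record present
    SCHEDULED -> RESEARCHED   postponement with reason and open questions
    RESEARCHED-> BACKLOG      re-open, note required
    FOLLOW_UP -> CLOSED       follow-up record present

Postponed cases return to RESEARCHED, not BACKLOG: their research exists,
only open questions remain. Every accepted transition appends an
audit-trail entry, so replaying the log reconstructs the current state.
"""

from __future__ import annotations

from datetime import date, datetime, timedelta, timezone

from pydantic import BaseModel, ConfigDict

from .config import Config, DEFAULT_CONFIG
from .errors import (
    CapacityExceededError,
    GuardError,
    IllegalTransitionError,
    MissingMeetingError,
    ValidationFailure,
    WrongStateError,
)
from .model import (
    Case,
    MeetingRef,
    Notification,
    NotificationKind,
    Postponement,
    Sex,
    Transition,
    Variant,
    WorkflowState,
    validate_case,
)

S = WorkflowState

#: the six legal (from, to) pairs; everything else is rejected outright
ALLOWED_TRANSITIONS: frozenset[tuple[WorkflowState, WorkflowState]] = frozenset(
    {
        (S.BACKLOG, S.RESEARCHED),
        (S.RESEARCHED, S.SCHEDULED),
        (S.SCHEDULED, S.FOLLOW_UP),
        (S.SCHEDULED, S.RESEARCHED),
        (S.RESEARCHED, S.BACKLOG),
        (S.FOLLOW_UP, S.CLOSED),
    }
)


class Meeting(BaseModel):
    """A board session with a case roster bounded by capacity."""

    model_config = ConfigDict(extra="forbid")

    meeting_id: str
    date: date
    capacity: int = 10
    case_ids: list[str] = []

    def ref(self) -> MeetingRef:
        return MeetingRef(meeting_id=self.meeting_id, date=self.date, capacity=self.capacity)


def _now() -> datetime:
    return datetime.now(timezone.utc)


def create_case(
    case_id: str,
    *,
    age_years: int,
    sex: Sex | str,
    diagnosis_code: str,
    diagnosis_text: str = "",
    variants: tuple[Variant, ...] | list[Variant] = (),
    group_id: str = "",
    actor: str = "system",
    timestamp: datetime | None = None,
    existing_ids: set[str] | None = None,
    **extra,
) -> tuple[Case, Notification]:
    """Create a case in BACKLOG and emit its CASE_CREATED notification.

    The transition log starts with a synthetic creation entry (nothing ->
    BACKLOG). ``existing_ids`` lets callers backed by a store enforce
    pseudonym uniqueness.
    """
    from .errors import DuplicateCaseError

    if existing_ids is not None and case_id in existing_ids:
        raise DuplicateCaseError(f"case id {case_id!r} already exists")
    ts = timestamp or _now()
    case = Case(
        case_id=case_id,
        age_years=age_years,
        sex=Sex(sex),
        diagnosis_code=diagnosis_code,
        diagnosis_text=diagnosis_text,
        variants=tuple(variants),
        group_id=group_id,
        state=S.BACKLOG,
        transitions=(
            Transition(from_state=None, to_state=S.BACKLOG, timestamp=ts, actor=actor),
        ),
        **extra,
    )
    violations = validate_case(case)
    if violations:
        raise ValidationFailure(violations)
    notification = Notification(
        kind=NotificationKind.CASE_CREATED,
        case_id=case_id,
        timestamp=ts,
        recipients=(group_id,) if group_id else (),
    )
    return case, notification


def transition(
    case: Case,
    target_state: WorkflowState,
    *,
    actor: str = "system",
    timestamp: datetime | None = None,
    note: str | None = None,
    postponement: Postponement | None = None,
    no_actionable_findings: bool = False,
    _meeting: Meeting | None = None,
) -> Case:
    """Move a case to ``target_state`` if the pair is legal and its guard
    holds; returns the updated case with the transition appended."""
    pair = (case.state, target_state)
    if pair not in ALLOWED_TRANSITIONS:
        raise IllegalTransitionError(case.state, target_state)

    updates: dict = {}
    if pair == (S.BACKLOG, S.RESEARCHED):
        if not case.annotations and not no_actionable_findings:
            raise GuardError(
                "BACKLOG->RESEARCHED requires at least one annotation "
                "or an explicit no_actionable_findings flag"
            )
    elif pair == (S.RESEARCHED, S.SCHEDULED):
        if _meeting is None:
            raise GuardError("RESEARCHED->SCHEDULED must go through schedule_case")
        updates["scheduled_meeting"] = _meeting.ref()
    elif pair == (S.SCHEDULED, S.FOLLOW_UP):
        if case.documentation is None:
            raise GuardError("SCHEDULED->FOLLOW_UP requires a documentation record")
    elif pair == (S.SCHEDULED, S.RESEARCHED):
        if postponement is None:
            raise GuardError(
                "SCHEDULED->RESEARCHED requires a postponement with reason "
                "and open questions"
            )
        updates["postponements"] = case.postponements + (postponement,)
    elif pair == (S.RESEARCHED, S.BACKLOG):
        if not note:
            raise GuardError("RESEARCHED->BACKLOG (re-open) requires a note")
    elif pair == (S.FOLLOW_UP, S.CLOSED):
        if case.follow_up is None:
            raise GuardError("FOLLOW_UP->CLOSED requires a follow-up record")

    entry = Transition(
        from_state=case.state,
        to_state=target_state,
        timestamp=timestamp or _now(),
        actor=actor,
        note=note,
    )
    updates["state"] = target_state
    updates["transitions"] = case.transitions + (entry,)
    return case.model_copy(update=updates)


def schedule_case(
    case: Case,
    meeting: Meeting,
    *,
    actor: str = "system",
    timestamp: datetime | None = None,
) -> tuple[Case, Notification]:
    """Put a researched case on a meeting roster and emit CASE_SCHEDULED.

    Rejects non-RESEARCHED cases and full meetings; the roster can never
    exceed capacity through this call.
    """
    if case.state != S.RESEARCHED:
        raise WrongStateError(
            f"only RESEARCHED cases can be scheduled (case is {case.state.value})"
        )
    if len(meeting.case_ids) >= meeting.capacity:
        raise CapacityExceededError(
            f"meeting {meeting.meeting_id} already holds {meeting.capacity} cases"
        )
    ts = timestamp or _now()
    updated = transition(case, S.SCHEDULED, actor=actor, timestamp=ts, _meeting=meeting)
    meeting.case_ids.append(case.case_id)
    notification = Notification(
        kind=NotificationKind.CASE_SCHEDULED,
        case_id=case.case_id,
        timestamp=ts,
        recipients=(case.group_id,) if case.group_id else (),
    )
    return updated, notification


def followup_due(case: Case, config: Config | None = None) -> date:
    """Earliest follow-up date: meeting date + the configured minimum
    (default 90 days; the reassessment window is three to six months)."""
    config = config or DEFAULT_CONFIG
    if case.scheduled_meeting is None:
        raise MissingMeetingError(
            f"case {case.case_id} has no scheduled meeting to anchor follow-up timing"
        )
    return case.scheduled_meeting.date + timedelta(days=config.follow_up_min_days)


def replay_state(transitions: tuple[Transition, ...]) -> WorkflowState:
    """Reconstruct the state a transition log ends in (audit replay)."""
    state = S.BACKLOG
    for t in transitions:
        state = t.to_state
    return state
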