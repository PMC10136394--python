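"""Kanban lifecycle: guarded transitions, scheduling capacity, follow-up
timing, audit-trail replay."""

import itertools
import random
from datetime import date, datetime, timezone

import pytest

from mtbkit import (
    ALLOWED_TRANSITIONS,
    CapacityExceededError,
    Config,
    DocumentationRecord,
    DuplicateCaseError,
    FollowUpRecord,
    GuardError,
    IllegalTransitionError,
    Meeting,
    MissingMeetingError,
    NotificationKind,
    MeetingRef,
    Postponement,
    TherapyReceived,
    ValidationFailure,
    WorkflowState,
    WrongStateError,
    create_case,
    followup_due,
    replay_state,
    schedule_case,
    transition,
)

TS = datetime(2023, 1, 2, 9, 0, tzinfo=timezone.utc)

S = WorkflowState


def _case_in_state(valid_case, state: WorkflowState):
    """Equip a fixture case with every guard artifact and force its state."""
    doc = DocumentationRecord(remarks="board remarks", signed_by="md", timestamp=TS)
    fu = FollowUpRecord(therapy_received=TherapyReceived.YES, medication="DRUG-001",
                        recorded_on=date(2023, 6, 1))
    meeting = MeetingRef(meeting_id="M1", date=date(2023, 1, 10))
    transitions = valid_case.transitions
    if transitions[-1].to_state != state:
        transitions = transitions + (
            transitions[-1].model_copy(update={"from_state": transitions[-1].to_state,
                                               "to_state": state}),
        )
    return valid_case.model_copy(update={
        "state": state, "documentation": doc, "follow_up": fu,
        "scheduled_meeting": meeting, "transitions": transitions,
    })


class TestCreateCase:
    def test_valid_inputs_backlog_plus_notification(self):
        case, note = create_case(
            "CASE-9000", age_years=50, sex="male", diagnosis_code="C34.1",
            group_id="GRP-A", timestamp=TS,
        )
        assert case.state == S.BACKLOG
        assert len(case.transitions) == 1
        assert case.transitions[0].from_state is None
        assert case.transitions[0].to_state == S.BACKLOG
        assert note.kind == NotificationKind.CASE_CREATED
        assert note.case_id == "CASE-9000"

    def test_empty_id_rejected(self):
        with pytest.raises(ValidationFailure, match="case_id"):
            create_case("", age_years=50, sex="male", diagnosis_code="C34.1")

    def test_duplicate_id_rejected(self):
        with pytest.raises(DuplicateCaseError):
            create_case("CASE-0001", age_years=50, sex="male",
                        diagnosis_code="C34.1", existing_ids={"CASE-0001"})


class TestTransitionMatrix:
    def test_exactly_six_pairs_accepted(self, valid_case):
        """All 25 ordered state pairs: the 6 declared transitions pass with
        guards satisfied, the other 19 raise illegal-transition."""
        accepted = set()
        for frm, to in itertools.product(S, S):
            case = _case_in_state(valid_case, frm)
            try:
                if (frm, to) == (S.RESEARCHED, S.SCHEDULED):
                    meeting = Meeting(meeting_id="M1", date=date(2023, 1, 10))
                    updated, _ = schedule_case(case, meeting, timestamp=TS)
                else:
                    updated = transition(
                        case, to, timestamp=TS, note="re-open note",
                        postponement=Postponement(reason="missing data",
                                                  open_questions=("pathology?",),
                                                  timestamp=TS),
                    )
                accepted.add((frm, to))
                assert updated.state == to
            except IllegalTransitionError:
                pass
            except (WrongStateError, GuardError):  # pragma: no cover - defensive
                pytest.fail(f"guarded rejection for satisfiable pair {frm}->{to}")
        assert accepted == set(ALLOWED_TRANSITIONS)
        assert len(accepted) == 6

    @pytest.mark.parametrize(
        "frm,to,strip",
        [
            (S.BACKLOG, S.RESEARCHED, {"annotations": ()}),
            (S.SCHEDULED, S.FOLLOW_UP, {"documentation": None}),
            (S.FOLLOW_UP, S.CLOSED, {"follow_up": None}),
        ],
    )
    def test_removing_guard_artifact_flips_to_rejection(self, valid_case, frm, to, strip):
        case = _case_in_state(valid_case, frm)
        assert transition(case, to, timestamp=TS).state == to
        with pytest.raises(GuardError):
            transition(case.model_copy(update=strip), to, timestamp=TS)

    def test_postponement_required_and_recorded(self, valid_case):
        case = _case_in_state(valid_case, S.SCHEDULED)
        with pytest.raises(GuardError):
            transition(case, S.RESEARCHED, timestamp=TS)
        p = Postponement(reason="awaiting pathology", open_questions=("IHC result?",),
                         timestamp=TS)
        updated = transition(case, S.RESEARCHED, postponement=p, timestamp=TS)
        assert updated.postponements[-1] == p

    def test_reopen_requires_note(self, valid_case):
        case = _case_in_state(valid_case, S.RESEARCHED)
        with pytest.raises(GuardError):
            transition(case, S.BACKLOG, timestamp=TS)
        assert transition(case, S.BACKLOG, note="new sequencing data",
                          timestamp=TS).state == S.BACKLOG

    def test_no_actionable_findings_flag(self, valid_case):
        bare = valid_case.model_copy(update={"annotations": ()})
        with pytest.raises(GuardError):
            transition(bare, S.RESEARCHED, timestamp=TS)
        assert transition(bare, S.RESEARCHED, no_actionable_findings=True,
                          timestamp=TS).state == S.RESEARCHED

    def test_direct_schedule_transition_blocked(self, valid_case):
        case = _case_in_state(valid_case, S.RESEARCHED)
        with pytest.raises(GuardError, match="schedule_case"):
            transition(case, S.SCHEDULED, timestamp=TS)

    def test_log_replay_reconstructs_state(self, valid_case):
        case = _case_in_state(valid_case, S.BACKLOG)
        case = transition(case, S.RESEARCHED, timestamp=TS)
        case, _ = schedule_case(case, Meeting(meeting_id="M1", date=date(2023, 1, 10)),
                                timestamp=TS)
        case = transition(case, S.FOLLOW_UP, timestamp=TS)
        assert replay_state(case.transitions) == case.state == S.FOLLOW_UP


class TestScheduling:
    def _researched(self, valid_case, i):
        return _case_in_state(
            valid_case.model_copy(update={"case_id": f"CASE-1{i:03d}"}), S.RESEARCHED
        )

    def test_capacity_ten_accepts_rejects_eleventh(self, valid_case):
        meeting = Meeting(meeting_id="M1", date=date(2023, 1, 10), capacity=10)
        for i in range(10):
            updated, note = schedule_case(self._researched(valid_case, i), meeting,
                                          timestamp=TS)
            assert updated.state == S.SCHEDULED
            assert note.kind == NotificationKind.CASE_SCHEDULED
        assert len(meeting.case_ids) == 10
        with pytest.raises(CapacityExceededError):
            schedule_case(self._researched(valid_case, 10), meeting, timestamp=TS)

    def test_backlog_case_wrong_state(self, valid_case):
        meeting = Meeting(meeting_id="M1", date=date(2023, 1, 10))
        with pytest.raises(WrongStateError):
            schedule_case(_case_in_state(valid_case, S.BACKLOG), meeting, timestamp=TS)

    def test_random_interleavings_never_exceed_capacity(self, valid_case):
        rng = random.Random(11)
        for _ in range(20):
            meeting = Meeting(meeting_id="M", date=date(2023, 1, 10),
                              capacity=rng.randint(1, 6))
            n_attempts = rng.randint(1, 12)
            scheduled = 0
            for i in rng.sample(range(100), n_attempts):
                try:
                    schedule_case(self._researched(valid_case, i), meeting, timestamp=TS)
                    scheduled += 1
                except CapacityExceededError:
                    pass
            assert len(meeting.case_ids) == scheduled <= meeting.capacity


class TestFollowUpDue:
    def test_default_window_90_days(self, valid_case):
        case = _case_in_state(valid_case, S.FOLLOW_UP).model_copy(
            update={"scheduled_meeting": MeetingRef(meeting_id="M",
                                                    date=date(2023, 1, 10))}
        )
        assert followup_due(case, Config()) == date(2023, 4, 10)

    def test_degenerate_window(self, valid_case):
        case = _case_in_state(valid_case, S.FOLLOW_UP).model_copy(
            update={"scheduled_meeting": MeetingRef(meeting_id="M",
                                                    date=date(2023, 1, 10))}
        )
        cfg = Config(follow_up_min_days=120, follow_up_max_days=120)
        assert followup_due(case, cfg) == date(2023, 5, 10)

    def test_missing_meeting(self, valid_case):
        case = _case_in_state(valid_case, S.FOLLOW_UP).model_copy(
            update={"scheduled_meeting": None})
        with pytest.raises(MissingMeetingError):
            followup_due(case, Config())
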