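"""Text rendering of the Kanban case board.

Columns run backlog -> researched -> scheduled -> follow-up; each card is
one open case. Closed cases leave the board. Within a column cases are
ordered by creation time (first transition timestamp), then id, so the
rendering is deterministic for a fixed store.
"""

from __future__ import annotations

from datetime import datetime, timezone

from pydantic import BaseModel, ConfigDict

from .model import Case, WorkflowState

BOARD_COLUMNS = (
    WorkflowState.BACKLOG,
    WorkflowState.RESEARCHED,
    WorkflowState.SCHEDULED,
    WorkflowState.FOLLOW_UP,
)


class BoardCard(BaseModel):
    model_config = ConfigDict(extra="forbid")

    case_id: str
    diagnosis_code: str
    n_variants: int
    n_annotations: int


class BoardView(BaseModel):
    model_config = ConfigDict(extra="forbid")

    columns: dict[WorkflowState, tuple[BoardCard, ...]]


def _created_at(case: Case) -> datetime:
    if case.transitions:
        ts = case.transitions[0].timestamp
        if ts.tzinfo is None:
            ts = ts.replace(tzinfo=timezone.utc)
        return ts
    return datetime.min.replace(tzinfo=timezone.utc)


def render_board(cases: list[Case], include_closed: bool = False) -> tuple[BoardView, str]:
    """Build the board view and its text rendering."""
    columns: dict[WorkflowState, tuple[BoardCard, ...]] = {}
    states = BOARD_COLUMNS + ((WorkflowState.CLOSED,) if include_closed else ())
    for state in states:
        members = sorted(
            (c for c in cases if c.state == state),
            key=lambda c: (_created_at(c), c.case_id),
        )
        columns[state] = tuple(
            BoardCard(
                case_id=c.case_id,
                diagnosis_code=c.diagnosis_code,
                n_variants=len(c.variants),
                n_annotations=len(c.annotations),
            )
            for c in members
        )
    view = BoardView(columns=columns)

    lines = []
    for state in states:
        cards = columns[state]
        lines.append(f"=== {state.value} ({len(cards)}) ===")
        for card in cards:
            lines.append(
                f"  [{card.case_id}] {card.diagnosis_code} "
                f"variants={card.n_variants} annotations={card.n_annotations}"
            )
        lines.append("")
    return view, "\n".join(lines)
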