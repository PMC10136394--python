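"""Walk one case through the whole board lifecycle.

A case starts in BACKLOG, becomes RESEARCHED once annotated, is scheduled
onto a capacity-limited meeting, documented into FOLLOW_UP, and closed
after the follow-up record arrives. Every move is appended to the audit
trail, which this script prints at the end.
"""

from datetime import date, datetime, timezone

from mtbkit import (
    Annotation,
    DocumentationRecord,
    FollowUpRecord,
    Meeting,
    TherapyReceived,
    Variant,
    VariantType,
    WorkflowState,
    create_case,
    followup_due,
    schedule_case,
    transition,
    variant_key,
)

TS = datetime(2024, 3, 1, 9, 0, tzinfo=timezone.utc)

kras = Variant(gene="KRAS", chrom="12", pos=25245350, ref="C", alt="T",
               variant_type=VariantType.SNV, protein_change="p.G12D",
               pathogenicity=0.8)

case, note = create_case(
    "CASE-0001", age_years=61, sex="female", diagnosis_code="C25.1",
    diagnosis_text="pancreatic adenocarcinoma", variants=(kras,),
    group_id="GRP-A", timestamp=TS,
)
print(f"created: state={case.state.value}, notification={note.kind.value}")

ann = Annotation(variant_key=variant_key(kras), drug="DRUG-001",
                 evidence_level="m1A", source_id="civic", citation="PMID:1",
                 reasoning="sensitizing alteration", author="expert", timestamp=TS)
case = case.model_copy(update={"annotations": (ann,)})
case = transition(case, WorkflowState.RESEARCHED, actor="expert", timestamp=TS)
print(f"annotated and researched: state={case.state.value}")

meeting = Meeting(meeting_id="MTB-2024-03", date=date(2024, 3, 15), capacity=10)
case, note = schedule_case(case, meeting, actor="coordinator", timestamp=TS)
print(f"scheduled: meeting={meeting.meeting_id}, roster={len(meeting.case_ids)}/10, "
      f"notification={note.kind.value}")

doc = DocumentationRecord(remarks="board recommends DRUG-001", signed_by="md",
                          timestamp=TS)
case = transition(case.model_copy(update={"documentation": doc}),
                  WorkflowState.FOLLOW_UP, actor="md", timestamp=TS)
print(f"documented: state={case.state.value}, follow-up due {followup_due(case)} "
      "(90 days after the meeting; the window closes at 180)")

fu = FollowUpRecord(therapy_received=TherapyReceived.YES, medication="DRUG-001",
                    side_effects=("nausea",), recorded_on=date(2024, 6, 20))
case = transition(case.model_copy(update={"follow_up": fu}),
                  WorkflowState.CLOSED, actor="md", timestamp=TS)
print(f"closed: state={case.state.value}")

print("\naudit trail:")
for t in case.transitions:
    frm = t.from_state.value if t.from_state else "-"
    print(f"  {frm:>10} -> {t.to_state.value:<10} by {t.actor}")
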