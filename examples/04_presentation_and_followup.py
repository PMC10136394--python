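"""One-command presentation for a researched case, plus cohort follow-up
statistics.

The presentation bundles the case summary, mutation burden, signature
labels, the scored variant table with per-source availability, similar
cases, annotations and the prioritized recommendations into deterministic
Markdown. Follow-up statistics aggregate whether boards' recommendations
were actually applied.
"""

from datetime import date

from mtbkit import (
    Config,
    FollowUpRecord,
    TherapyReceived,
    WorkflowState,
    followup_statistics,
    rank_recommendations,
    rank_variants,
    render_presentation,
    retrieve_similar,
)
from mtbkit.synth import SynthParams, generate_cohort, generate_snapshot

config = Config()
cases, _ = generate_cohort(SynthParams(n_cases=15, n_planted_pairs=3, seed=4))
snapshot = generate_snapshot(
    sorted({v.gene for c in cases for v in c.variants}), SynthParams(seed=4))

case = cases[0].model_copy(update={"state": WorkflowState.RESEARCHED,
                                   "transitions": ()})
ranked = rank_variants(list(case.variants), snapshot, config)
relevance = {rs.variant_key: rs.total for _, rs in ranked}
recommendations = rank_recommendations(case, config.evidence_scale, relevance)
similar = retrieve_similar(case, cases, level=3, k=3)

deck = render_presentation(case, ranked, recommendations, similar, config)
print(deck[: deck.index("## Similar Cases")])
print("... (similar cases, annotations and recommendations follow)\n")

outcomes = [TherapyReceived.YES] * 6 + [TherapyReceived.NO] * 2 \
    + [TherapyReceived.UNKNOWN] * 2
followed = [
    c.model_copy(update={"follow_up": FollowUpRecord(
        therapy_received=o,
        medication="DRUG-001" if o == TherapyReceived.YES else None,
        side_effects=("nausea",) if o == TherapyReceived.YES else (),
        recorded_on=date(2024, 6, 1))})
    for c, o in zip(cases, outcomes)
]
stats = followup_statistics(followed)
print(f"follow-up over {stats.n_cases} cases: {stats.n_applied} applied, "
      f"{stats.n_not_applied} not applied, {stats.n_unknown} unknown")
print(f"acceptance rate over known outcomes: {stats.acceptance_rate:.2f}")
print(f"side effects: {stats.side_effect_counts}")
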