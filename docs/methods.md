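# Methods

This note describes the models and procedures implemented in `mtbkit`,
their assumptions, the parameters that matter, and the design choices made
where the design was genuinely open.

## The workflow model

A case is a pseudonymized record moving through a Kanban lifecycle. The
board's four working columns mirror how preparation actually proceeds —
non-annotated cases in the backlog, researched molecular profiles,
cases scheduled for the next session, and cases awaiting follow-up — and a
terminal `CLOSED` state is added so the lifecycle has a defined end once
the follow-up record exists. Exactly six transitions are legal, each with
a guard artifact:

| transition | guard |
|---|---|
| BACKLOG → RESEARCHED | ≥ 1 annotation, or an explicit no-actionable-findings flag |
| RESEARCHED → SCHEDULED | only via `schedule_case`, meeting below capacity |
| SCHEDULED → FOLLOW_UP | documentation record present |
| SCHEDULED → RESEARCHED | postponement with reason and open questions |
| RESEARCHED → BACKLOG | re-open note required |
| FOLLOW_UP → CLOSED | follow-up record present |

Two modelling choices deserve mention. Postponed cases return to
`RESEARCHED`, not `BACKLOG`: their research exists, only open questions
remain, and those questions are recorded on the case rather than on paper
notes. And a case may be marked researched without annotations only
through an explicit flag — silence about actionable findings should never
look like an oversight. Every accepted move appends an immutable audit
entry; replaying the log reconstructs the state.

Notifications (`CASE_CREATED`, `CASE_SCHEDULED`, `FOLLOW_UP_DUE`) are
emitted as records; delivering them is hospital-IT integration, out of
scope here.

**Parameters.** `meeting_capacity` (cases per session, default 10 — boards
typically discuss about ten cases in a 60–90 minute session);
`follow_up_min_days`/`follow_up_max_days` (default 90/180 — the customary
three-to-six-month reassessment window). The due date is anchored at the
meeting date plus the minimum, so it always falls inside the window by
construction; the maximum exists for site policies that schedule later.

## Evidence matching and relevance scoring

Knowledge sources are consumed as offline snapshots (JSON-lines, one
evidence entry per line) rather than live APIs: boards need reproducible
preparation, and public sources key their content on gene symbol plus an
optional protein change, which is exactly the matching rule used —
an entry matches a variant when genes agree and the entry either carries
no protein change (gene-level evidence) or the exact same one. Positional
matching against snapshots is deliberately not attempted.

The relevance score of a variant v is

    score(v) = w_p · p(v) + Σ_s w_s · log2(1 + h_s(v))

with `p(v)` the externally computed pathogenicity (0 when absent — the
engine consumes functional-effect predictions, it does not make them),
`h_s` the per-source match count and `w_s` a trust weight. The log2
saturation is a deliberate numerical choice: a source with 60 entries for
a gene should not drown out two independent sources with 3 each, and
log2(1+h) is 0 at h=0, 1 at h=1, and grows slowly after. Default weights
encode editorial trust — historical in-house cases 3.0 (curated by known
experts), CIViC 2.0 (expert-moderated), COSMIC/cBioPortal/Mastermind 1.0,
PubMed/ASCO publications 0.5 (unreviewed breadth), `w_p` = 1.0. Sources
absent from the configuration contribute weight 0 but still appear in the
per-source breakdown, so new sources can be snapshot-ed before they are
trusted. Under these defaults the intended ordering (historical > CIViC >
literature at equal hit counts) holds strictly for any hit count ≥ 1.

Ranking sorts by total descending with (gene, variant key) as the tie
break, making the order a pure function of the variant set.

Variant identity is `chrom:pos:ref>alt|gene` for small variants (1-based,
VCF-style alleles) and `gene|type` for CNV/fusion events, which public
sources key per gene. HGVS strings are stored verbatim, never parsed.

## Similar-case retrieval

Three levels, all deterministic and explainable feature by feature — a
trained similarity model was deliberately rejected because the board must
be able to justify why a historic case was surfaced:

1. **Demographic**: weighted indicator average of age within a tolerance
   (default ±10 years), sex equality (unknown never matches), and ICD-10
   prefix equality (default 3 characters = disease category).
2. **Molecular**: mean of two Jaccard indices, over gene symbols and over
   exact SNV/INDEL keys. Empty-vs-empty sets score 0, not 1 — a case with
   no variants is similar to nothing, which blocks vacuous matches.
3. **Combined**: α·level1 + β·level2 + γ·cosine of binary vectors over the
   union of prior-therapy drugs and lab flags (defaults α, β, γ = 0.25,
   0.5, 0.25, constrained to sum to 1 so scores stay in [0, 1]).

All three are symmetric and bounded in [0, 1]; levels 1 and 2 are
reflexive for cases with known demographics and non-empty variants. The
combined score is reflexive only when the treatment/lab feature vector is
non-empty, because the cosine of two zero vectors is defined as 0 rather
than 1; a case with no recorded history earns no history credit, even
against itself. Retrieval returns the top k by score with case-id
tie-breaking and never returns the query case.

## Recommendation ranking

Each expert annotation (variant + drug + evidence level + source +
reasoning) becomes one recommendation row. The sort key is, in order:
evidence rank on the configured ordinal scale (default m1A, m1B, m1C,
m2A, m2B, m2C, m3, m4 — an eight-level scale in the style of German
precision-oncology programs; sites configure their own); prior treatment
failure of the drug (untried first — failure *demotes within* an evidence
tier rather than excluding, because ranking should weigh medical history,
not hide options from the board); trial feasibility; relevance of the
underlying variant; drug name. Feasibility reduces to set membership: when
a set of reachable trial sites is supplied, an item is feasible iff its
citation token is in that set — geographic distance modelling was judged
out of scope, so the citation field doubles as the site token by
convention.

## Reporting

Presentations are deterministic Markdown: seven fixed sections (case
summary, mutation burden, tumor signatures, functional variants with the
per-source availability matrix, similar cases, annotations,
recommendations). Byte-identical inputs give byte-identical output, so
decks can be regenerated and diffed. Mutational signatures are **not**
computed — they are heavyweight upstream analyses; the engine passes
precomputed labels through verbatim or prints "not available". Tumor
mutational burden is the SNV+INDEL count divided by the panel size in
megabases; it requires a positive panel size as standalone computation,
while the presentation degrades to "not available" for cases without one
so a missing panel size never blocks a board. Follow-up statistics count
therapy uptake per case (cases without a record count as unknown) and
report the acceptance rate over known outcomes only, with an explicit
defined/undefined flag instead of a fake zero.

## Access control and pseudonymization

Access is deny-by-default group membership: a user may act on a case only
when listed in the case's owning group (typically one hospital); unknown
users, groups and actions deny without raising. Pseudonymization is
enforced structurally rather than by NLP de-identification: the case
schema is a strict whitelist (unknown fields are rejected at parse time),
the case identifier must match a configurable pattern (default
`^[A-Za-z0-9_-]{4,64}$`, which forbids whitespace so free-text names
cannot become identifiers), and every free-text surface (diagnosis text,
history descriptions, annotation reasoning, transition notes,
postponement reasons/questions, documentation remarks) is scanned for a
site-configured blacklist of identifying tokens by case-insensitive
substring match. The blacklist ships empty: identifying vocabulary is
inherently site-specific. Sub-resource permissions (different rights on
parts of one case) are a known limitation; granularity is per case.

## Synthetic data

The generators exist so every capability is testable offline. A cohort
draws, per case, a Poisson(8)-sized gene set (minimum 1) from a pool of
200 synthetic symbols plus four real driver genes, one SNV per gene with
random coordinates and pathogenicity, plus demographics, ICD-10 codes from
a small solid-tumor list, prior therapies and lab flags. Planted
near-duplicate pairs are built copy-then-mutate: the partner keeps
`m − r` of its seed's `m` genes and swaps in `r = ⌊m(1−o)/(1+o)⌋` fresh
ones, which guarantees gene-set Jaccard ≥ o (default 0.6) in bounded time.
When planted pairs are requested, *all* other pairs are rejection-sampled
below a background ceiling (default Jaccard ≤ 0.1) so the planted partner
is unambiguous; without planted pairs the ceiling is not enforced — for
large cohorts over the default pool it is combinatorially unsatisfiable
(a ~8-gene profile may share at most one gene with every other case), and
it serves no retrieval purpose there. Bounded resampling raises an
explicit infeasible-parameters error rather than looping forever.

Snapshots draw a Poisson number of entries per gene and source (source
means 0.2–1.2, historical cases rarest), with levels uniform on the
configured scale and synthetic PMID-style citations.

What the generator does **not** emulate: realistic mutation spectra,
hotspot structure, allele frequencies, signature patterns, or correlated
demographics. Passing tests therefore demonstrate the engine's logic —
guards, formulas, rankings, round-trips, detection — not clinical
performance on real cohorts; retrieval quality on real data depends on
profile overlap structure the synthetic cohorts only caricature.

## Numerical and degenerate-input choices

- Scores use double precision; the scoring oracle tolerance in tests is
  1e-9, far above accumulation error at realistic entry counts.
- All orderings carry total, deterministic tie-breaks (lexicographic ids,
  gene symbols, drug names), so outputs are invariant under input
  permutation.
- Empty inputs are defined, not errors: empty snapshot → score is the
  pathogenicity term; empty cohort → no similar cases; no annotations →
  empty recommendation list; zero known follow-up outcomes → undefined
  acceptance rate.
- File writes are atomic (write-temp-then-rename); readers either parse a
  row or raise with its 1-based line number, never dropping rows silently.
- Problem sizes in the test suite and acceptance script (1,000 scoring
  draws, 500 ranking draws, 100 round-trip fixtures, 50-case retrieval
  cohorts, 500-case generator calibration) were chosen as the smallest
  sizes at which the checked properties are statistically meaningful; all
  complete in seconds on one CPU.
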