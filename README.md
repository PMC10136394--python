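# mtbkit

An offline, testable decision-support engine for **molecular tumor boards
(MTBs)** — the multidisciplinary meetings that derive individual treatment
recommendations from a tumor's molecular profile. It is written for the
people who prepare and run those boards (research experts, oncologists,
coordinators) and for the informaticians who support them, and it covers
the preparation workflow end to end on pseudonymized case records:

- **Case lifecycle** on a Kanban board: `BACKLOG → RESEARCHED → SCHEDULED →
  FOLLOW_UP → CLOSED`, with guarded transitions (a case cannot leave the
  backlog without annotations, cannot be documented without a decision
  record, cannot close without a follow-up), postponements tagged with
  reason and open questions, capacity-limited meeting scheduling
  (default 10 cases per session) and an append-only audit trail.
- **Variant evidence lookup** against offline snapshots of knowledge
  sources (CIViC, COSMIC, cBioPortal, Mastermind, PubMed, ASCO
  publications, historical in-house cases), with a per-source availability
  matrix and a **relevance score** per variant:

      score(v) = w_p · p(v) + Σ_s w_s · log2(1 + h_s(v))

  where `p(v)` is an externally computed pathogenicity in [0, 1],
  `h_s(v)` the number of matching entries in source `s`, and `w_s`
  trust weights (historical cases 3.0 > CIViC 2.0 > databases 1.0 >
  literature 0.5 by default; all configurable).
- **Similar-case retrieval** at three levels: demographics (age/sex/ICD-10
  category indicators), molecular profile (mean of gene-set and locus-set
  Jaccard indices), and a transparent weighted combination adding a cosine
  over treatment-history/lab-flag features.
- **Recommendation ranking**: one row per expert annotation, ordered by
  evidence level (m1A…m4 scale by default), prior treatment failure, trial
  feasibility, variant relevance and drug name; ranks 1..n.
- **Reporting**: deterministic Markdown meeting presentations (case
  summary, tumor mutational burden per megabase, signatures, scored
  variant table, similar cases, annotations, recommendations),
  board-decision documentation, and follow-up acceptance statistics.
- **Privacy**: group-based access control (deny by default) and structural
  pseudonymization checks (schema whitelist, pseudonym pattern, free-text
  blacklist scan).
- **Synthetic data**: seeded generators for cohorts with planted
  near-duplicate case pairs and for knowledge snapshots, so everything is
  testable fully offline.

## Worked example

```python
from mtbkit import Config, KnowledgeSnapshot, Variant, VariantType, rank_variants
from mtbkit.scoring import EvidenceEntry

def entry(source, gene, protein=None):
    return EvidenceEntry(source_id=source, gene=gene, protein_change=protein,
                         drug="DRUG-001", evidence_level="m1A", citation="PMID:1")

snapshot = KnowledgeSnapshot(entries=(
    entry("civic", "KRAS"), entry("civic", "KRAS", protein="p.G12D"),
    entry("historical_cases", "KRAS"), entry("cosmic", "TP53"),
))
kras = Variant(gene="KRAS", chrom="12", pos=25245350, ref="C", alt="T",
               variant_type=VariantType.SNV, protein_change="p.G12D",
               pathogenicity=0.8)
tp53 = Variant(gene="TP53", chrom="17", pos=7675088, ref="G", alt="A",
               variant_type=VariantType.SNV, pathogenicity=0.9)

for i, (v, s) in enumerate(rank_variants([tp53, kras], snapshot, Config()), 1):
    print(i, s.variant_key, round(s.total, 3))
```

prints

```
1 12:25245350:C>T|KRAS 6.97
2 17:7675088:G>A|TP53 1.9
```

The KRAS variant scores `0.8 + 2.0·log2(3) + 3.0·log2(2) ≈ 6.970`: its
pathogenicity plus two CIViC hits (the gene-level entry and the exact
p.G12D match) at weight 2.0 and one historical-case hit at weight 3.0. The
TP53 variant has one COSMIC hit (`0.9 + 1.0·log2(2) = 1.9`) and ranks
below it — the board sees the better-supported variant first.

The `examples/` directory holds one narrative script per capability
(lifecycle, scoring, similar cases, presentation/follow-up); each prints
what it computes and what the numbers mean. A thin CLI (`mtb`) wraps the
same library for shell use: `mtb init`, `mtb case create`,
`mtb snapshot load`, `mtb score`, `mtb similar`, `mtb annotate`,
`mtb schedule`, `mtb present`, `mtb document`, `mtb follow-up stats`,
`mtb board`, `mtb synth cohort`, `mtb export` — exit codes distinguish
validation (2), workflow (3) and I/O (4) failures.

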