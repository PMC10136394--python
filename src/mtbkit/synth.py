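"""Seeded generators for synthetic cohorts and knowledge snapshots.

Everything here is test scaffolding for the engine itself: cohorts of
pseudonymized cases with controlled gene-profile overlap, and offline
knowledge-source snapshots with per-source entry densities. Defaults model
a typical board workload — about eight reported variants per case drawn
from a pool of ~200 genes, with a handful of case pairs sharing most of
their molecular profile (the "similar historic case" situation) against a
background of essentially unrelated profiles.

Planted pairs are built by copy-then-mutate: the partner keeps most of its
seed case's gene set, guaranteeing the requested Jaccard overlap in
bounded time, while background pairs are rejection-sampled below the
background ceiling. No attempt is made at realistic mutation spectra,
signatures or allele frequencies.
"""

from __future__ import annotations

import math
from datetime import date, datetime, timedelta, timezone

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .errors import InfeasibleParametersError
from .model import (
    Case,
    DEFAULT_EVIDENCE_SCALE,
    EvidenceScale,
    GeneRole,
    HistoryEvent,
    Sex,
    Transition,
    Variant,
    VariantType,
    WorkflowState,
)
from .scoring import EvidenceEntry, KnowledgeSnapshot

#: real driver genes mixed into the synthetic pool so fixtures read naturally
REAL_GENES = ("KRAS", "TP53", "SETBP1", "LRRK1")

DEFAULT_GENE_POOL: tuple[str, ...] = tuple(
    f"GENE{i:03d}" for i in range(200)
) + REAL_GENES

DEFAULT_ENTRIES_PER_GENE: dict[str, float] = {
    "civic": 0.6,
    "cosmic": 1.0,
    "cbioportal": 0.5,
    "mastermind": 0.5,
    "pubmed": 1.2,
    "ascopubs": 0.3,
    "historical_cases": 0.2,
}

_ICD_CODES = ("C25.1", "C25.9", "C34.1", "C18.7", "C50.9", "C61", "C71.9", "C16.0")
_LAB_FLAGS = ("MSI-high", "TMB-high", "HER2-pos", "PD-L1-pos", "HRD-pos")
_BASES = "ACGT"
_AA = "ARNDCQEGHILKMFPSTWYV"

_MAX_RESAMPLES = 2000


class SynthParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_cases: int = 50
    gene_pool: tuple[str, ...] = DEFAULT_GENE_POOL
    variants_per_case_mean: float = 8.0
    n_planted_pairs: int = 0
    planted_gene_overlap_min: float = 0.6
    background_overlap_max: float = 0.1
    entries_per_gene_by_source: dict[str, float] = dict(DEFAULT_ENTRIES_PER_GENE)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SynthParams":
        if 2 * self.n_planted_pairs > self.n_cases:
            raise InfeasibleParametersError(
                f"need 2*{self.n_planted_pairs} <= {self.n_cases} cases for planted pairs"
            )
        for name in ("planted_gene_overlap_min", "background_overlap_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InfeasibleParametersError(f"{name} must lie in [0, 1] (got {v})")
        if self.variants_per_case_mean <= 0:
            raise InfeasibleParametersError("variants_per_case_mean must be positive")
        return self


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def _background_set(
    rng: np.random.Generator,
    pool: tuple[str, ...],
    mean: float,
    accepted: list[frozenset[str]],
    ceiling: float,
) -> frozenset[str]:
    for _ in range(_MAX_RESAMPLES):
        n = min(max(1, int(rng.poisson(mean))), len(pool))
        idx = rng.choice(len(pool), size=n, replace=False)
        candidate = frozenset(pool[i] for i in idx)
        if all(_jaccard(candidate, other) <= ceiling for other in accepted):
            return candidate
    raise InfeasibleParametersError(
        "could not sample a background gene set below the overlap ceiling; "
        "enlarge the gene pool or relax background_overlap_max"
    )


def _partner_set(
    rng: np.random.Generator,
    seed_set: frozenset[str],
    pool: tuple[str, ...],
    accepted_others: list[frozenset[str]],
    overlap_min: float,
    ceiling: float,
) -> frozenset[str]:
    """Copy the seed gene set and swap out as many genes as the overlap
    floor allows: keeping m-r of m genes and adding r fresh ones gives
    Jaccard (m-r)/(m+r) >= overlap_min for r <= m(1-o)/(1+o)."""
    m = len(seed_set)
    r = int(math.floor(m * (1 - overlap_min) / (1 + overlap_min)))
    genes = sorted(seed_set)
    for _ in range(_MAX_RESAMPLES):
        kept = frozenset(genes[i] for i in rng.choice(m, size=m - r, replace=False))
        fresh_pool = [g for g in pool if g not in seed_set]
        fresh = frozenset(
            fresh_pool[i] for i in rng.choice(len(fresh_pool), size=r, replace=False)
        )
        candidate = kept | fresh
        if _jaccard(candidate, seed_set) < overlap_min:
            continue
        if all(_jaccard(candidate, other) <= ceiling for other in accepted_others):
            return candidate
    raise InfeasibleParametersError(
        "could not build a planted partner satisfying both overlap bounds"
    )


def _variant_for_gene(rng: np.random.Generator, gene: str) -> Variant:
    ref = _BASES[rng.integers(4)]
    alt = _BASES[(rng.integers(1, 4) + _BASES.index(ref)) % 4]
    protein = None
    if rng.random() < 0.7:
        protein = f"p.{_AA[rng.integers(20)]}{int(rng.integers(1, 900))}{_AA[rng.integers(20)]}"
    return Variant(
        gene=gene,
        chrom=str(int(rng.integers(1, 23))),
        pos=int(rng.integers(1, 50_000_000)),
        ref=ref,
        alt=alt,
        variant_type=VariantType.SNV,
        protein_change=protein,
        pathogenicity=round(float(rng.random()), 3),
        gene_role=GeneRole(["oncogene", "TSG", "unknown"][int(rng.integers(3))]),
    )


def _case_from_genes(
    rng: np.random.Generator, case_id: str, genes: frozenset[str], created: datetime
) -> Case:
    variants = tuple(_variant_for_gene(rng, g) for g in sorted(genes))
    n_hist = int(rng.integers(0, 3))
    history = tuple(
        HistoryEvent(
            date=created.date() - timedelta(days=int(rng.integers(30, 720))),
            description=f"prior finding {int(rng.integers(100, 999))}",
        )
        for _ in range(n_hist)
    )
    n_prior = int(rng.integers(0, 4))
    prior = {
        f"DRUG-{int(rng.integers(1, 40)):03d}": bool(rng.random() < 0.5)
        for _ in range(n_prior)
    }
    flags = tuple(
        sorted(f for f in _LAB_FLAGS if rng.random() < 0.2)
    )
    return Case(
        case_id=case_id,
        age_years=int(rng.integers(25, 86)),
        sex=Sex(["female", "male"][int(rng.integers(2))]),
        diagnosis_code=_ICD_CODES[int(rng.integers(len(_ICD_CODES)))],
        diagnosis_text="synthetic tumor case",
        clinical_history=history,
        prior_therapies=prior,
        lab_flags=flags,
        variants=variants,
        state=WorkflowState.BACKLOG,
        transitions=(
            Transition(
                from_state=None,
                to_state=WorkflowState.BACKLOG,
                timestamp=created,
                actor="synth",
            ),
        ),
        group_id="GRP-SYNTH",
        panel_size_mb=1.5,
    )


def generate_cohort(params: SynthParams) -> tuple[list[Case], list[tuple[str, str]]]:
    """Generate a cohort with planted near-duplicate pairs.

    Returns the cases plus a manifest of (case_id, partner_case_id) planted
    pairs. Deterministic for a fixed seed: same params, same cohort. The
    first ``n_planted_pairs`` cases serve as pair seeds; their partners are
    appended after the background cases.
    """
    rng = np.random.default_rng(params.seed)
    n_base = params.n_cases - params.n_planted_pairs
    # The background ceiling exists to keep planted pairs unambiguous at
    # retrieval time; without planted pairs it is not enforced (large
    # cohorts over the default gene pool could not satisfy it anyway).
    ceiling = params.background_overlap_max if params.n_planted_pairs > 0 else 1.0
    gene_sets: list[frozenset[str]] = []
    for _ in range(n_base):
        gene_sets.append(
            _background_set(
                rng,
                params.gene_pool,
                params.variants_per_case_mean,
                gene_sets,
                ceiling,
            )
        )
    partner_sets: list[frozenset[str]] = []
    for i in range(params.n_planted_pairs):
        others = [s for j, s in enumerate(gene_sets) if j != i] + partner_sets
        partner_sets.append(
            _partner_set(
                rng,
                gene_sets[i],
                params.gene_pool,
                others,
                params.planted_gene_overlap_min,
                params.background_overlap_max,
            )
        )
    all_sets = gene_sets + partner_sets
    base_time = datetime(2023, 1, 1, 9, 0, tzinfo=timezone.utc)
    cases = [
        _case_from_genes(rng, f"CASE-{i:04d}", genes, base_time + timedelta(days=i))
        for i, genes in enumerate(all_sets)
    ]
    manifest = [
        (cases[i].case_id, cases[n_base + i].case_id)
        for i in range(params.n_planted_pairs)
    ]
    return cases, manifest


def generate_snapshot(
    genes,
    params: SynthParams | None = None,
    scale: EvidenceScale = DEFAULT_EVIDENCE_SCALE,
) -> KnowledgeSnapshot:
    """Per gene and source, a Poisson number of synthetic evidence entries
    with valid levels and synthetic citations. Deterministic given seed."""
    params = params or SynthParams()
    if not genes:
        raise ValueError("genes must be non-empty")
    rng = np.random.default_rng(params.seed + 1)
    entries: list[EvidenceEntry] = []
    for gene in genes:
        for source in sorted(params.entries_per_gene_by_source):
            mean = params.entries_per_gene_by_source[source]
            for _ in range(int(rng.poisson(mean))):
                protein = None
                if rng.random() < 0.3:
                    protein = f"p.{_AA[rng.integers(20)]}{int(rng.integers(1, 900))}{_AA[rng.integers(20)]}"
                entries.append(
                    EvidenceEntry(
                        source_id=source,
                        gene=gene,
                        protein_change=protein,
                        drug=f"DRUG-{int(rng.integers(1, 200)):03d}",
                        evidence_level=scale.levels[int(rng.integers(len(scale.levels)))],
                        citation=f"PMID:{int(rng.integers(10_000_000, 40_000_000))}",
                        summary=f"synthetic evidence record {int(rng.integers(1000, 9999))}",
                    )
                )
    return KnowledgeSnapshot(entries=tuple(entries))
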