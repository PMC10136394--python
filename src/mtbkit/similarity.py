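"""Similar-case retrieval at three levels of depth.

Level 1 compares demographics (age within a tolerance, sex, ICD-10 disease
category). Level 2 compares the molecular profile: Jaccard overlap of gene
sets and of exact SNV/INDEL loci, averaged. Level 3 is a deterministic
weighted combination of levels 1 and 2 plus a cosine similarity over the
binary treatment-history/lab-flag feature vector — deliberately a
transparent linear rule rather than a trained model, so every retrieved
case can be explained to the board feature by feature.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .model import Case, Sex, Variant, VariantType, variant_key


class SimilarityLevel(IntEnum):
    DEMOGRAPHIC = 1
    MOLECULAR = 2
    COMBINED = 3


class SimilarityParams(BaseModel):
    """Tunables of the similarity levels.

    ``age_tolerance_years``: two ages count as matching when they differ by
    at most this many years. ``icd_prefix_len``: number of leading ICD-10
    characters compared (3 = disease category, e.g. "C25"). Level-3 weights
    (alpha: demographic, beta: molecular, gamma: treatment/lab features)
    must sum to 1 so combined scores stay in [0, 1].
    """

    model_config = ConfigDict(extra="forbid")

    age_tolerance_years: int = 10
    icd_prefix_len: int = 3
    level1_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    level3_weights: tuple[float, float, float] = (0.25, 0.5, 0.25)

    @model_validator(mode="after")
    def _check(self) -> "SimilarityParams":
        if self.age_tolerance_years < 1 or self.icd_prefix_len < 1:
            raise ValueError("age_tolerance_years and icd_prefix_len must be positive")
        if any(w < 0 for w in self.level1_weights + self.level3_weights):
            raise ValueError("similarity weights must be non-negative")
        if abs(sum(self.level3_weights) - 1.0) > 1e-9:
            raise ValueError("level3_weights must sum to 1")
        if sum(self.level1_weights) <= 0:
            raise ValueError("level1_weights must not all be zero")
        return self


class SimilarityResult(BaseModel):
    model_config = ConfigDict(extra="forbid")

    other_case_id: str
    level: SimilarityLevel
    score: float
    matched_features: tuple[str, ...] = ()


def _jaccard(a: set, b: set) -> float:
    # empty-vs-empty is 0 by design: a profile with no variants is similar
    # to nothing, which blocks vacuous 1.0 matches
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def _gene_set(c: Case) -> set[str]:
    return {v.gene for v in c.variants}


def _locus_set(c: Case) -> set[str]:
    return {
        variant_key(v)
        for v in c.variants
        if v.variant_type in (VariantType.SNV, VariantType.INDEL)
    }


def sim_demographic(a: Case, b: Case, params: SimilarityParams | None = None) -> float:
    """Weighted indicator average over age, sex and ICD-10 category."""
    params = params or SimilarityParams()
    w_age, w_sex, w_dx = params.level1_weights
    age_ok = abs(a.age_years - b.age_years) <= params.age_tolerance_years
    sex_ok = a.sex == b.sex and a.sex != Sex.UNKNOWN
    n = params.icd_prefix_len
    dx_ok = (
        bool(a.diagnosis_code)
        and bool(b.diagnosis_code)
        and a.diagnosis_code[:n] == b.diagnosis_code[:n]
    )
    total = w_age + w_sex + w_dx
    return (w_age * age_ok + w_sex * sex_ok + w_dx * dx_ok) / total


def sim_molecular(a: Case, b: Case) -> float:
    """Mean of gene-set Jaccard and SNV/INDEL locus-set Jaccard."""
    return (_jaccard(_gene_set(a), _gene_set(b)) + _jaccard(_locus_set(a), _locus_set(b))) / 2.0


def _feature_cosine(a: Case, b: Case) -> float:
    feats = sorted(set(a.prior_therapies) | set(a.lab_flags) | set(b.prior_therapies) | set(b.lab_flags))
    if not feats:
        return 0.0
    fa = np.array([1.0 if f in a.prior_therapies or f in a.lab_flags else 0.0 for f in feats])
    fb = np.array([1.0 if f in b.prior_therapies or f in b.lab_flags else 0.0 for f in feats])
    na, nb = np.linalg.norm(fa), np.linalg.norm(fb)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(fa, fb) / (na * nb))


def sim_combined(a: Case, b: Case, params: SimilarityParams | None = None) -> float:
    """alpha*demographic + beta*molecular + gamma*cosine(history/lab features)."""
    params = params or SimilarityParams()
    alpha, beta, gamma = params.level3_weights
    return (
        alpha * sim_demographic(a, b, params)
        + beta * sim_molecular(a, b)
        + gamma * _feature_cosine(a, b)
    )


def _matched_features(a: Case, b: Case, params: SimilarityParams) -> tuple[str, ...]:
    out = []
    if abs(a.age_years - b.age_years) <= params.age_tolerance_years:
        out.append("age")
    if a.sex == b.sex and a.sex != Sex.UNKNOWN:
        out.append("sex")
    n = params.icd_prefix_len
    if a.diagnosis_code and a.diagnosis_code[:n] == b.diagnosis_code[:n]:
        out.append("diagnosis")
    shared = sorted(_gene_set(a) & _gene_set(b))
    out.extend(f"gene:{g}" for g in shared)
    return tuple(out)


def retrieve_similar(
    case: Case,
    cohort: list[Case],
    level: int | SimilarityLevel = SimilarityLevel.MOLECULAR,
    k: int = 5,
    params: SimilarityParams | None = None,
) -> list[SimilarityResult]:
    """Top-k most similar cohort members, the query case excluded.

    Deterministic: descending score, ties broken by case id ascending.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    params = params or SimilarityParams()
    level = SimilarityLevel(level)
    scorer = {
        SimilarityLevel.DEMOGRAPHIC: lambda a, b: sim_demographic(a, b, params),
        SimilarityLevel.MOLECULAR: sim_molecular,
        SimilarityLevel.COMBINED: lambda a, b: sim_combined(a, b, params),
    }[level]
    results = [
        SimilarityResult(
            other_case_id=other.case_id,
            level=level,
            score=scorer(case, other),
            matched_features=_matched_features(case, other, params),
        )
        for other in cohort
        if other.case_id != case.case_id
    ]
    results.sort(key=lambda r: (-r.score, r.other_case_id))
    return results[:k]
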