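"""Engine configuration.

Defaults reflect how the boards this engine supports actually run: roughly
ten cases per 60-90 minute session (meeting capacity 10) and a reassessment
of every discussed patient after three to six months (follow-up window
90-180 days). Source weights encode editorial trust in each knowledge
source: a hospital's own historical cases rank highest, expert-curated
CIViC entries above generic databases, raw literature hits lowest.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, model_validator

from .errors import InvalidConfigError
from .model import DEFAULT_PSEUDONYM_PATTERN, EvidenceScale
from .similarity import SimilarityParams

DEFAULT_SOURCE_WEIGHTS: dict[str, float] = {
    "historical_cases": 3.0,
    "civic": 2.0,
    "cosmic": 1.0,
    "cbioportal": 1.0,
    "mastermind": 1.0,
    "pubmed": 0.5,
    "ascopubs": 0.5,
}


class Config(BaseModel):
    model_config = ConfigDict(extra="forbid")

    source_weights: dict[str, float] = dict(DEFAULT_SOURCE_WEIGHTS)
    pathogenicity_weight: float = 1.0
    evidence_scale: EvidenceScale = EvidenceScale()
    meeting_capacity: int = 10
    follow_up_min_days: int = 90
    follow_up_max_days: int = 180
    similarity_params: SimilarityParams = SimilarityParams()
    pseudonym_pattern: str = DEFAULT_PSEUDONYM_PATTERN
    pii_blacklist: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "Config":
        if self.meeting_capacity < 1:
            raise InvalidConfigError(
                f"meeting_capacity: must be >= 1 (got {self.meeting_capacity})"
            )
        if self.follow_up_min_days > self.follow_up_max_days:
            raise InvalidConfigError(
                "follow_up_min_days: must not exceed follow_up_max_days "
                f"({self.follow_up_min_days} > {self.follow_up_max_days})"
            )
        for src, w in self.source_weights.items():
            if w < 0:
                raise InvalidConfigError(f"source_weights.{src}: must be >= 0 (got {w})")
        if self.pathogenicity_weight < 0:
            raise InvalidConfigError(
                f"pathogenicity_weight: must be >= 0 (got {self.pathogenicity_weight})"
            )
        return self


DEFAULT_CONFIG = Config()
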