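"""Group-based access control and pseudonymization validation.

Access is deny-by-default: a user may act on a case only when they belong
to the case's owning group (typically one hospital). Pseudonymization is
enforced structurally — the case schema is a whitelist, the pseudonym must
match a configurable pattern, and every free-text field is scanned for a
site-configured blacklist of identifying tokens (names, record numbers).
The blacklist ships empty because identifying vocabulary is inherently
site-specific.
"""

from __future__ import annotations

import re
from enum import Enum
from typing import Iterator

from pydantic import BaseModel, ConfigDict

from .model import Case, DEFAULT_PSEUDONYM_PATTERN


class Action(str, Enum):
    READ = "read"
    ANNOTATE = "annotate"
    SCHEDULE = "schedule"
    DOCUMENT = "document"


class AccessPolicy(BaseModel):
    """Maps group ids to their member user ids."""

    model_config = ConfigDict(extra="forbid")

    groups: dict[str, set[str]] = {}


class PiiPolicy(BaseModel):
    model_config = ConfigDict(extra="forbid")

    allowed_fields: set[str] = set(Case.model_fields)
    pii_blacklist: tuple[str, ...] = ()
    pseudonym_pattern: str = DEFAULT_PSEUDONYM_PATTERN


def check_access(user: str, case: Case, action: Action | str, policy: AccessPolicy) -> bool:
    """True (allow) iff the user belongs to the case's group. Never raises:
    unknown groups, users or actions simply deny."""
    try:
        Action(action)
    except ValueError:
        return False
    members = policy.groups.get(case.group_id, set())
    return user in members


def iter_free_text_fields(case: Case) -> Iterator[tuple[str, str]]:
    """Yield (field path, text) for every free-text field of a case —
    the surfaces where identifying information could leak."""
    yield "diagnosis_text", case.diagnosis_text
    for i, ev in enumerate(case.clinical_history):
        yield f"clinical_history[{i}].description", ev.description
    for i, ann in enumerate(case.annotations):
        yield f"annotations[{i}].reasoning", ann.reasoning
    for i, t in enumerate(case.transitions):
        if t.note:
            yield f"transitions[{i}].note", t.note
    for i, p in enumerate(case.postponements):
        yield f"postponements[{i}].reason", p.reason
        for j, q in enumerate(p.open_questions):
            yield f"postponements[{i}].open_questions[{j}]", q
    if case.documentation is not None:
        yield "documentation.remarks", case.documentation.remarks


def validate_pseudonymization(case: Case, policy: PiiPolicy | None = None) -> list[str]:
    """Report every pseudonymization breach: bad pseudonym, fields outside
    the schema whitelist, blacklisted tokens in free text (case-insensitive
    substring match). One violation per (field, token) hit."""
    policy = policy or PiiPolicy()
    violations: list[str] = []
    if not re.match(policy.pseudonym_pattern, case.case_id):
        violations.append(
            f"case_id: {case.case_id!r} does not match pseudonym pattern"
        )
    for field in case.model_dump():
        if field not in policy.allowed_fields:
            violations.append(f"{field}: field not in the allowed schema")
    tokens = [t.lower() for t in policy.pii_blacklist if t]
    if tokens:
        for path, text in iter_free_text_fields(case):
            low = text.lower()
            for token in tokens:
                if token in low:
                    violations.append(f"{path}: contains blacklisted token {token!r}")
    return violations
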