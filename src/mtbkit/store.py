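"""File-backed case store: one JSON file per case plus a meetings index.

All writes go through write-temp-then-rename, so a crash mid-write leaves
the previous version intact and readers never see a torn file.
"""

from __future__ import annotations

import json
from pathlib import Path

from .errors import DuplicateCaseError
from .io import _atomic_write_text, read_case, write_case
from .model import Case
from .workflow import Meeting


class CaseStore:
    """Directory layout: ``<root>/cases/<case_id>.json`` and
    ``<root>/meetings.json``."""

    def __init__(self, root: str | Path):
        self.root = Path(root)

    @property
    def cases_dir(self) -> Path:
        return self.root / "cases"

    @property
    def meetings_path(self) -> Path:
        return self.root / "meetings.json"

    def init(self) -> None:
        self.cases_dir.mkdir(parents=True, exist_ok=True)
        if not self.meetings_path.exists():
            _atomic_write_text(self.meetings_path, "{}\n")

    def case_path(self, case_id: str) -> Path:
        return self.cases_dir / f"{case_id}.json"

    def exists(self, case_id: str) -> bool:
        return self.case_path(case_id).exists()

    def case_ids(self) -> list[str]:
        return sorted(p.stem for p in self.cases_dir.glob("*.json"))

    def load(self, case_id: str) -> Case:
        return read_case(self.case_path(case_id))

    def load_all(self) -> list[Case]:
        return [self.load(cid) for cid in self.case_ids()]

    def save(self, case: Case, *, expect_new: bool = False) -> None:
        if expect_new and self.exists(case.case_id):
            raise DuplicateCaseError(f"case id {case.case_id!r} already exists in store")
        write_case(case, self.case_path(case.case_id))

    def load_meetings(self) -> dict[str, Meeting]:
        if not self.meetings_path.exists():
            return {}
        with open(self.meetings_path, encoding="utf-8") as fh:
            data = json.load(fh)
        return {mid: Meeting.model_validate(m) for mid, m in data.items()}

    def save_meetings(self, meetings: dict[str, Meeting]) -> None:
        data = {mid: m.model_dump(mode="json") for mid, m in sorted(meetings.items())}
        _atomic_write_text(self.meetings_path, json.dumps(data, indent=2, sort_keys=True) + "\n")
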