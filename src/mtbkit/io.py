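"""File formats: variant tables, minimal VCF, case files, knowledge
snapshots and configuration.

Variant lists arrive as UTF-8 tab-separated tables with a header row
(columns ``gene chrom pos ref alt variant_type`` plus optional
``protein_change pathogenicity gene_role``) — the portable concretization
of the spreadsheets sequencing labs hand to the board. A minimal VCF import
covers the pipeline-direct path. Cases are single-document JSON with a
whitelisted schema; snapshots are JSON-lines, one evidence entry per line,
so they stream and diff cleanly. Configuration is YAML (JSON is a subset).
"""

from __future__ import annotations

import json
import math
import os
import tempfile
from pathlib import Path

import pandas as pd
import pydantic
import pysam
import yaml

from .config import Config
from .errors import (
    InvalidConfigError,
    MissingColumnError,
    SchemaViolationError,
    SnapshotParseError,
    TableParseError,
    VcfParseError,
)
from .model import Case, GeneRole, Variant, VariantType, validate_case
from .scoring import EvidenceEntry, KnowledgeSnapshot

REQUIRED_TABLE_COLUMNS = ("gene", "chrom", "pos", "ref", "alt", "variant_type")
OPTIONAL_TABLE_COLUMNS = ("protein_change", "pathogenicity", "gene_role")

_ALLELES = set("ACGT")


def _atomic_write_text(path: str | Path, text: str) -> None:
    """Write-temp-then-rename so readers never observe a half-written file."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def read_variant_table(path: str | Path) -> list[Variant]:
    """Parse a TSV variant list, preserving row order.

    Errors carry 1-based file line numbers (the header is line 1). Rows are
    never silently dropped: each either yields a variant or raises.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    for col in REQUIRED_TABLE_COLUMNS:
        if col not in df.columns:
            raise MissingColumnError(col)
    variants: list[Variant] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        rec = dict(zip(df.columns, row))
        try:
            vtype = VariantType(str(rec["variant_type"]).strip())
        except ValueError:
            raise TableParseError(
                line, f"variant_type {rec['variant_type']!r} not one of SNV/INDEL/CNV/FUSION"
            ) from None
        try:
            pos = int(str(rec["pos"]).strip())
        except (TypeError, ValueError):
            raise TableParseError(line, f"pos {rec['pos']!r} is not an integer") from None
        if pos < 1:
            raise TableParseError(line, f"pos must be >= 1 (got {pos})")
        ref = _opt_str(rec["ref"]) or ""
        alt = _opt_str(rec["alt"]) or ""
        if vtype in (VariantType.SNV, VariantType.INDEL):
            for name, allele in (("ref", ref), ("alt", alt)):
                if not allele or not set(allele) <= _ALLELES:
                    raise TableParseError(
                        line, f"{name} {allele!r} must be a non-empty string over ACGT"
                    )
        pathogenicity = None
        if "pathogenicity" in df.columns:
            raw = _opt_str(rec["pathogenicity"])
            if raw is not None:
                try:
                    pathogenicity = float(raw)
                except ValueError:
                    raise TableParseError(
                        line, f"pathogenicity {raw!r} is not a number"
                    ) from None
                if not (0.0 <= pathogenicity <= 1.0):
                    raise TableParseError(
                        line, f"pathogenicity {pathogenicity} outside [0, 1]"
                    )
        gene_role = None
        if "gene_role" in df.columns:
            raw = _opt_str(rec["gene_role"])
            if raw is not None:
                try:
                    gene_role = GeneRole(raw)
                except ValueError:
                    raise TableParseError(line, f"gene_role {raw!r} unknown") from None
        variants.append(
            Variant(
                gene=str(rec["gene"]).strip(),
                chrom=str(rec["chrom"]).strip(),
                pos=pos,
                ref=ref,
                alt=alt,
                variant_type=vtype,
                protein_change=_opt_str(rec["protein_change"])
                if "protein_change" in df.columns
                else None,
                pathogenicity=pathogenicity,
                gene_role=gene_role,
            )
        )
    return variants


def write_variant_table(variants: list[Variant], path: str | Path) -> None:
    rows = [
        {
            "gene": v.gene,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "variant_type": v.variant_type.value,
            "protein_change": v.protein_change or "",
            "pathogenicity": "" if v.pathogenicity is None else v.pathogenicity,
            "gene_role": v.gene_role.value if v.gene_role else "",
        }
        for v in variants
    ]
    cols = list(REQUIRED_TABLE_COLUMNS) + list(OPTIONAL_TABLE_COLUMNS)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_vcf_minimal(
    path: str | Path, gene_map: dict[str, str] | None = None
) -> list[Variant]:
    """Import CHROM/POS/REF/ALT (+ optional INFO GENE) from a VCF.

    Multi-allelic records are split into one variant per ALT. The gene
    symbol comes from INFO key GENE when present, else from ``gene_map``
    keyed on ``chrom:pos``, else "UNKNOWN". Single-base ref and alt means
    SNV; anything else is an INDEL.
    """
    gene_map = gene_map or {}
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    variants: list[Variant] = []
    try:
        for rec in vf:
            info_gene = rec.info.get("GENE") if "GENE" in rec.info else None
            if isinstance(info_gene, tuple):
                info_gene = info_gene[0]
            for alt in rec.alts or ():
                gene = (
                    str(info_gene)
                    if info_gene
                    else gene_map.get(f"{rec.chrom}:{rec.pos}", "UNKNOWN")
                )
                vtype = (
                    VariantType.SNV
                    if len(rec.ref) == 1 and len(alt) == 1
                    else VariantType.INDEL
                )
                variants.append(
                    Variant(
                        gene=gene,
                        chrom=str(rec.chrom),
                        pos=int(rec.pos),
                        ref=str(rec.ref),
                        alt=str(alt),
                        variant_type=vtype,
                    )
                )
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"malformed VCF record in {path}: {exc}") from exc
    finally:
        vf.close()
    return variants


def read_case(path: str | Path) -> Case:
    """Load a case file; unknown fields are a schema violation, never
    silently accepted."""
    with open(path, encoding="utf-8") as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaViolationError([f"not valid JSON: {exc}"]) from exc
    try:
        return Case.model_validate(data)
    except pydantic.ValidationError as exc:
        raise SchemaViolationError(
            [f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()]
        ) from exc


def write_case(case: Case, path: str | Path) -> None:
    """Persist a case atomically; invalid cases are refused with the full
    violation list."""
    violations = validate_case(case)
    if violations:
        raise SchemaViolationError(violations)
    _atomic_write_text(
        path, json.dumps(case.model_dump(mode="json"), indent=2, sort_keys=True) + "\n"
    )


def read_snapshot(path: str | Path) -> KnowledgeSnapshot:
    """Read a JSON-lines snapshot; parse errors carry line numbers."""
    entries: list[EvidenceEntry] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.strip()
            if not raw:
                continue
            try:
                data = json.loads(raw)
            except json.JSONDecodeError as exc:
                raise SnapshotParseError(lineno, f"not valid JSON: {exc}") from exc
            try:
                entries.append(EvidenceEntry.model_validate(_entry_from_wire(data)))
            except (pydantic.ValidationError, ValueError, KeyError) as exc:
                raise SnapshotParseError(lineno, str(exc)) from exc
    return KnowledgeSnapshot(entries=tuple(entries))


def _entry_from_wire(data: dict) -> dict:
    # wire field is "source"; the in-memory model says source_id
    if "source" not in data:
        raise KeyError("missing required field 'source'")
    out = dict(data)
    out["source_id"] = out.pop("source")
    for field in ("gene", "drug", "evidence_level", "citation"):
        if field not in out:
            raise KeyError(f"missing required field {field!r}")
    return out


def write_snapshot(snapshot: KnowledgeSnapshot, path: str | Path) -> None:
    lines = []
    for e in snapshot.entries:
        data = {"source": e.source_id, "gene": e.gene, "drug": e.drug,
                "evidence_level": e.evidence_level, "citation": e.citation}
        if e.protein_change is not None:
            data["protein_change"] = e.protein_change
        if e.summary is not None:
            data["summary"] = e.summary
        lines.append(json.dumps(data, sort_keys=True))
    _atomic_write_text(path, "\n".join(lines) + ("\n" if lines else ""))


def load_config(path: str | Path) -> Config:
    """Load YAML/JSON configuration; unset keys take their defaults."""
    with open(path, encoding="utf-8") as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise InvalidConfigError(f"cannot parse config {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise InvalidConfigError("config root must be a mapping")
    try:
        return Config.model_validate(data)
    except InvalidConfigError:
        raise
    except pydantic.ValidationError as exc:
        first = exc.errors()[0]
        key = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise InvalidConfigError(f"{key}: {first['msg']}") from exc
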