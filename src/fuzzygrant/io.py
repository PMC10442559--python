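"""Readers and writers for the interchange formats.

Formats (all UTF-8, comma-separated CSV with a mandatory header row and
decimal points):

* **Evaluation config** (YAML or JSON, one document): keys ``score_range``,
  ``groups`` (each with ``id``, ``label``, ``criteria``), ``wishes``,
  ``group_weights``, ``sigma``, ``regional_criterion_weights``, ``kr``.
  Wishes and weights may be lists (schema order) or mappings keyed by
  group id.
* **Score sheets** (CSV): long form with columns
  ``project_id,region_id,criterion_id,score`` or wide form with one row per
  project, columns ``project_id,region_id,<criterion ids...>``.  The dialect
  is sniffed from the header.
* **Region table** (CSV): criteria as rows, first column ``criterion_id``,
  one column per region; plus a YAML/JSON sidecar declaring per-criterion
  ``direction``, ``weight`` and optional ``reference``.
* **Results**: flat CSV (one row per project) and nested JSON with run
  metadata.  Files are written atomically (temp file + rename).

Every loader collects *all* validation problems into a single
:class:`~fuzzygrant.errors.ValidationError` rather than stopping at the
first.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError, ValidationReport
from .fuzzy_core import CharacteristicValues
from .project_eval import (
    Criterion,
    CriteriaSchema,
    CriterionGroup,
    InvestorProfile,
    ScoreSheet,
)
from .ranking import EvaluationResult
from .region_eval import RegionCriterion, RegionTable

__all__ = [
    "load_config",
    "dump_config",
    "load_score_sheets",
    "write_score_sheets",
    "load_region_table",
    "write_region_table",
    "write_result_csv",
    "write_result_json",
]


def _atomic_write_text(text: str, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _load_document(path: str | Path) -> dict:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        if path.suffix.lower() == ".json":
            doc = json.load(fh)
        else:  # YAML is a superset of JSON, so .yaml/.yml and friends go here
            doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: expected a mapping at the top level")
    return doc


def _per_group(values, group_ids: tuple[str, ...], what: str, report: ValidationReport):
    """Accept a list in schema order or a mapping keyed by group id."""
    if values is None:
        return None
    if isinstance(values, dict):
        missing = [g for g in group_ids if g not in values]
        extra = [g for g in values if g not in group_ids]
        if missing:
            report.add(f"{what}: missing entries for groups {missing}")
        if extra:
            report.add(f"{what}: unknown group ids {extra}")
        if missing or extra:
            return None
        return tuple(float(values[g]) for g in group_ids)
    seq = tuple(float(v) for v in values)
    if len(seq) != len(group_ids):
        report.add(f"{what}: {len(seq)} entries for {len(group_ids)} groups")
        return None
    return seq


def load_config(path: str | Path) -> tuple[CriteriaSchema, InvestorProfile]:
    """Load the combined criteria-schema + investor-profile document."""
    doc = _load_document(path)
    report = ValidationReport()

    raw_groups = doc.get("groups")
    if not raw_groups:
        report.add(f"{path}: 'groups' key is missing or empty")
        report.raise_if_any()
    groups = []
    for g in raw_groups:
        criteria = tuple(
            Criterion(id=str(c["id"]), label=str(c.get("label", "")))
            if isinstance(c, dict)
            else Criterion(id=str(c))
            for c in g.get("criteria", ())
        )
        try:
            groups.append(
                CriterionGroup(id=str(g["id"]), label=str(g.get("label", "")), criteria=criteria)
            )
        except (KeyError, ValidationError, ValueError) as exc:
            report.add(f"{path}: bad group definition {g.get('id', '?')!r}: {exc}")
    report.raise_if_any()

    score_range = tuple(doc.get("score_range", (1, 10)))
    try:
        schema = CriteriaSchema(groups=tuple(groups), score_range=score_range)
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from exc

    gids = schema.group_ids()
    wishes = _per_group(doc.get("wishes"), gids, "wishes", report)
    if wishes is None and not report:
        report.add(f"{path}: 'wishes' key is required")
    weights = _per_group(doc.get("group_weights"), gids, "group_weights", report)
    report.raise_if_any()

    sigma = doc.get("sigma")
    rc_weights = doc.get("regional_criterion_weights")
    try:
        profile = InvestorProfile(
            wishes=wishes,
            group_weights=weights,
            sigma=CharacteristicValues(tuple(sigma)) if sigma else CharacteristicValues(),
            regional_criterion_weights=tuple(rc_weights) if rc_weights else None,
            kr=float(doc.get("kr", 0.5)),
        )
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    report.extend(f"{path}: {issue}" for issue in profile.validate_for(schema))
    report.raise_if_any()
    return schema, profile


def dump_config(schema: CriteriaSchema, profile: InvestorProfile, path: str | Path) -> None:
    """Serialize schema + profile back to a YAML (or JSON) document."""
    doc = {
        "score_range": list(schema.score_range),
        "groups": [
            {
                "id": g.id,
                "label": g.label,
                "criteria": [{"id": c.id, "label": c.label} for c in g.criteria],
            }
            for g in schema.groups
        ],
        "wishes": list(profile.wishes),
        "group_weights": list(profile.group_weights) if profile.group_weights else None,
        "sigma": list(profile.sigma.sigma),
        "regional_criterion_weights": (
            list(profile.regional_criterion_weights)
            if profile.regional_criterion_weights
            else None
        ),
        "kr": profile.kr,
    }
    path = Path(path)
    if path.suffix.lower() == ".json":
        _atomic_write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", path)
    else:
        _atomic_write_text(yaml.safe_dump(doc, sort_keys=False), path)


def load_score_sheets(
    path: str | Path, schema: CriteriaSchema, *, allow_noninteger: bool = False
) -> list[ScoreSheet]:
    """Read score sheets from CSV, sniffing long vs wide form from the header.

    Scores are integer point grades by default; ``allow_noninteger`` admits
    fractional expert scores (nothing downstream requires integrality).
    """
    df = pd.read_csv(path)
    report = ValidationReport()
    if df.empty:
        raise ValidationError(f"{path}: no projects (empty score-sheet file)")
    cols = list(df.columns)
    sheets: list[ScoreSheet] = []
    if {"project_id", "region_id", "criterion_id", "score"} <= set(cols):
        for (pid, region), sub in df.groupby(["project_id", "region_id"], sort=False):
            dup = sub["criterion_id"][sub["criterion_id"].duplicated()].tolist()
            for cid in dup:
                report.add(f"{path}: project {pid!r}: duplicate criterion {cid!r}")
            sheets.append(
                ScoreSheet(
                    project_id=str(pid),
                    region_id=str(region),
                    scores=dict(zip(sub["criterion_id"].astype(str), sub["score"])),
                )
            )
    elif {"project_id", "region_id"} <= set(cols):
        crit_cols = [c for c in cols if c not in ("project_id", "region_id")]
        for _, row in df.iterrows():
            sheets.append(
                ScoreSheet(
                    project_id=str(row["project_id"]),
                    region_id=str(row["region_id"]),
                    scores={cid: row[cid] for cid in crit_cols},
                )
            )
    else:
        raise ValidationError(
            f"{path}: unrecognized score-sheet header {cols}; expected long form "
            "(project_id,region_id,criterion_id,score) or wide form "
            "(project_id,region_id,<criterion ids...>)"
        )
    seen: set[str] = set()
    for sheet in sheets:
        if sheet.project_id in seen:
            report.add(f"{path}: duplicate project id {sheet.project_id!r}")
        seen.add(sheet.project_id)
        report.extend(
            f"{path}: {i}"
            for i in sheet.validate(schema, allow_noninteger=allow_noninteger)
        )
    report.raise_if_any()
    return sheets


def write_score_sheets(
    sheets: list[ScoreSheet], path: str | Path, *, wide: bool = True
) -> None:
    if wide:
        crit_ids = sorted({cid for s in sheets for cid in s.scores})
        rows = [
            {"project_id": s.project_id, "region_id": s.region_id, **{c: s.scores[c] for c in crit_ids}}
            for s in sheets
        ]
        df = pd.DataFrame(rows)
    else:
        records = [
            {
                "project_id": s.project_id,
                "region_id": s.region_id,
                "criterion_id": cid,
                "score": score,
            }
            for s in sheets
            for cid, score in s.scores.items()
        ]
        df = pd.DataFrame(records)
    _atomic_write_text(df.to_csv(index=False), path)


def load_region_table(csv_path: str | Path, sidecar_path: str | Path) -> RegionTable:
    """Read the raw indicator matrix plus its direction/weight sidecar."""
    df = pd.read_csv(csv_path)
    if "criterion_id" not in df.columns:
        raise ValidationError(f"{csv_path}: first column must be 'criterion_id'")
    meta = _load_document(sidecar_path)
    report = ValidationReport()
    declared = {str(c["id"]): c for c in meta.get("criteria", ())}
    criteria: list[RegionCriterion] = []
    for cid in df["criterion_id"].astype(str):
        spec = declared.get(cid)
        if spec is None:
            report.add(f"{sidecar_path}: no declaration for criterion {cid!r}")
            continue
        try:
            criteria.append(
                RegionCriterion(
                    id=cid,
                    label=str(spec.get("label", "")),
                    direction=str(spec.get("direction", "")),
                    weight=float(spec.get("weight", 1.0)),
                    reference=(
                        float(spec["reference"]) if spec.get("reference") is not None else None
                    ),
                )
            )
        except ValueError as exc:
            report.add(f"{sidecar_path}: criterion {cid!r}: {exc}")
    extra = set(declared) - set(df["criterion_id"].astype(str))
    for cid in sorted(extra):
        report.add(f"{sidecar_path}: declared criterion {cid!r} absent from {csv_path}")
    report.raise_if_any()
    regions = tuple(c for c in df.columns if c != "criterion_id")
    values = df[list(regions)].to_numpy(dtype=float)
    try:
        return RegionTable(criteria=tuple(criteria), regions=regions, values=values)
    except ValueError as exc:
        issues = getattr(exc, "issues", [str(exc)])
        raise ValidationError([f"{csv_path}: {i}" for i in issues]) from exc


def write_region_table(
    table: RegionTable, csv_path: str | Path, sidecar_path: str | Path
) -> None:
    df = pd.DataFrame(table.values, columns=list(table.regions))
    df.insert(0, "criterion_id", [c.id for c in table.criteria])
    _atomic_write_text(df.to_csv(index=False), csv_path)
    meta = {
        "criteria": [
            {
                "id": c.id,
                "label": c.label,
                "direction": c.direction,
                "weight": c.weight,
                "reference": c.reference,
            }
            for c in table.criteria
        ]
    }
    sidecar_path = Path(sidecar_path)
    if sidecar_path.suffix.lower() == ".json":
        _atomic_write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n", sidecar_path)
    else:
        _atomic_write_text(yaml.safe_dump(meta, sort_keys=False), sidecar_path)


def write_result_csv(result: EvaluationResult, path: str | Path) -> None:
    """One row per project, in rank order, with all intermediate quantities."""
    _atomic_write_text(result.to_dataframe().to_csv(index=False), path)


def write_result_json(result: EvaluationResult, path: str | Path) -> None:
    """Full nested result with metadata; key order is stable across runs."""
    _atomic_write_text(result.to_json(indent=2) + "\n", path)
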