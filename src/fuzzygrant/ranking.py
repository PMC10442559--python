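"""Stage 3 and orchestration: regional proximity, output scores, ranking.

The investor's desire-for-a-regional-coefficient KR in [0, 1] is compared
with each region's development level Delta; the proximity coefficient

    chi(R_h) = 1 - |KR - Delta(R_h)| / D,
    D = max(KR - min_h Delta, max_h Delta - KR)

rewards regions whose development level is closest to KR (KR near 0 biases
the selection toward the least developed regions, KR near 1 toward the most
developed).  Each project's output score is Y = mu(P) * chi(region), and
projects are ranked by Y descending.
"""

from __future__ import annotations

import json
import logging
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

from .errors import ConfigurationError, ValidationError, ValidationReport
from .project_eval import (
    CriteriaSchema,
    InvestorProfile,
    ProjectEvaluation,
    ScoreSheet,
    evaluate_project,
)
from .region_eval import RegionTable, development_levels

__all__ = [
    "ProjectResult",
    "EvaluationResult",
    "regional_proximity",
    "final_scores",
    "evaluate_competition",
]

logger = logging.getLogger(__name__)


def regional_proximity(levels: Mapping[str, float], kr: float) -> dict[str, float]:
    """Proximity coefficient chi per region for a given KR.

    The common denominator D is the larger of the distances from KR to the
    extremes of the Delta set, so chi spans [0, 1]: the region closest to KR
    gets the largest chi and the farthest extreme gets 0.  When all Delta
    are equal (in particular a single region) the *relative* distance notion
    degenerates — the formula would zero every region, or divide by zero if
    Delta = KR — so all regions get chi = 1 by convention: with no spread
    there is nothing to discriminate, and proximity must not veto projects.
    """
    if not levels:
        raise ValidationError("no regions: cannot compute proximity coefficients")
    if not 0.0 <= kr <= 1.0:
        raise ConfigurationError(f"regional coefficient kr must be in [0, 1], got {kr}")
    deltas = list(levels.values())
    if any(not (math.isfinite(d) and d > 0.0) for d in deltas):
        raise ValidationError(f"development levels must be positive, got {deltas}")
    if any(d > 1.0 + 1e-9 for d in deltas):
        # possible only when a region beat an external reference upstream
        logger.warning("development levels above 1 encountered: %s", deltas)
    if max(deltas) - min(deltas) <= 0.0:
        logger.warning(
            "all development levels equal (%s); chi set to 1 for all regions",
            deltas[0],
        )
        return {region: 1.0 for region in levels}
    d = max(kr - min(deltas), max(deltas) - kr)
    return {
        region: max(0.0, 1.0 - abs(kr - delta) / d) for region, delta in levels.items()
    }


@dataclass(frozen=True)
class ProjectResult:
    """Per-project evaluation record with all intermediate quantities."""

    project_id: str
    region_id: str
    project_score: float
    development_level: float
    proximity: float
    output_score: float
    rank: int
    group_satisfaction: dict[str, float] | None = None

    def to_dict(self) -> dict:
        return {
            "project_id": self.project_id,
            "region_id": self.region_id,
            "project_score": self.project_score,
            "development_level": self.development_level,
            "proximity": self.proximity,
            "output_score": self.output_score,
            "rank": self.rank,
            "group_satisfaction": self.group_satisfaction,
        }


@dataclass(frozen=True)
class EvaluationResult:
    """Ranked projects plus run metadata (KR, mode flags, seed if synthetic)."""

    projects: tuple[ProjectResult, ...]
    metadata: dict = field(default_factory=dict)

    def ranked(self) -> tuple[ProjectResult, ...]:
        return tuple(sorted(self.projects, key=lambda p: p.rank))

    def ranking(self) -> tuple[str, ...]:
        return tuple(p.project_id for p in self.ranked())

    def to_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "projects": [p.to_dict() for p in self.ranked()],
        }

    def to_json(self, *, indent: int | None = None) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_dataframe(self):
        """Flat per-project table (pandas), one row per project in rank order."""
        import pandas as pd

        rows = []
        for p in self.ranked():
            row = {
                "rank": p.rank,
                "project_id": p.project_id,
                "region_id": p.region_id,
                "project_score": p.project_score,
                "development_level": p.development_level,
                "proximity": p.proximity,
                "output_score": p.output_score,
            }
            if p.group_satisfaction:
                for gid, mu in p.group_satisfaction.items():
                    row[f"muO_{gid}"] = mu
            rows.append(row)
        return pd.DataFrame(rows)


def final_scores(
    project_scores: Mapping[str, float],
    assignment: Mapping[str, str],
    chi: Mapping[str, float],
    *,
    levels: Mapping[str, float] | None = None,
    group_satisfaction: Mapping[str, Mapping[str, float]] | None = None,
    metadata: Mapping | None = None,
) -> EvaluationResult:
    """Combine project scores with regional proximity and rank.

    ``Y_j = mu(P_j) * chi(region_j)``; ranking sorts Y descending with ties
    broken by higher mu(P) and then by stable input order.
    """
    report = ValidationReport()
    for pid in project_scores:
        region = assignment.get(pid)
        if region is None:
            report.add(f"project {pid!r} has no region assignment")
        elif region not in chi:
            report.add(f"project {pid!r} assigned to unknown region {region!r}")
    report.raise_if_any()

    order = list(project_scores)
    output = {pid: project_scores[pid] * chi[assignment[pid]] for pid in order}
    by_rank = sorted(
        order,
        key=lambda pid: (-output[pid], -project_scores[pid], order.index(pid)),
    )
    ranks = {pid: i + 1 for i, pid in enumerate(by_rank)}
    projects = tuple(
        ProjectResult(
            project_id=pid,
            region_id=assignment[pid],
            project_score=float(project_scores[pid]),
            development_level=float(levels[assignment[pid]]) if levels else float("nan"),
            proximity=float(chi[assignment[pid]]),
            output_score=float(output[pid]),
            rank=ranks[pid],
            group_satisfaction=(
                dict(group_satisfaction[pid])
                if group_satisfaction and pid in group_satisfaction
                else None
            ),
        )
        for pid in order
    )
    return EvaluationResult(projects=projects, metadata=dict(metadata or {}))


def evaluate_competition(
    sheets: Sequence[ScoreSheet],
    schema: CriteriaSchema,
    profile: InvestorProfile,
    table: RegionTable,
    *,
    given_scores: Mapping[str, float] | None = None,
    given_regions: Mapping[str, str] | None = None,
    kr: float | None = None,
    printed_rounding: bool = False,
    clamp_normalized: bool = False,
    metadata: Mapping | None = None,
) -> EvaluationResult:
    """Run all three stages for a whole competition.

    ``given_scores``/``given_regions`` admit projects whose project score
    mu(P) was established outside this run (e.g. published results of a
    previous evaluation round) alongside projects with full score sheets.
    ``kr`` overrides the profile's regional coefficient.  The run is
    deterministic given inputs and mode flags; re-invoking with a revised
    profile or extended indicator set implements the investor's
    re-evaluation loop.
    """
    given_scores = dict(given_scores or {})
    given_regions = dict(given_regions or {})

    report = ValidationReport()
    report.extend(profile.validate_for(schema))
    seen: set[str] = set()
    for sheet in sheets:
        if sheet.project_id in seen:
            report.add(f"duplicate project id {sheet.project_id!r}")
        seen.add(sheet.project_id)
        if sheet.project_id in given_scores:
            report.add(
                f"project {sheet.project_id!r} has both a score sheet and a given score"
            )
        if sheet.region_id not in table.regions:
            report.add(
                f"project {sheet.project_id!r} references region {sheet.region_id!r} "
                "absent from the region table"
            )
        report.extend(sheet.validate(schema, allow_noninteger=True))
    for pid, region in given_regions.items():
        if region not in table.regions:
            report.add(
                f"given-score project {pid!r} references region {region!r} "
                "absent from the region table"
            )
    for pid in given_scores:
        if pid not in given_regions:
            report.add(f"given-score project {pid!r} has no region assignment")
    if not sheets and not given_scores:
        report.add("no projects: provide at least one score sheet or given score")
    report.raise_if_any()

    evaluations: dict[str, ProjectEvaluation] = {
        sheet.project_id: evaluate_project(
            sheet, schema, profile, printed_rounding=printed_rounding
        )
        for sheet in sheets
    }
    project_scores: dict[str, float] = {
        pid: ev.project_score for pid, ev in evaluations.items()
    }
    assignment: dict[str, str] = {pid: ev.region_id for pid, ev in evaluations.items()}
    project_scores.update({pid: float(s) for pid, s in given_scores.items()})
    assignment.update(given_regions)

    levels = development_levels(
        table,
        weights=profile.regional_criterion_weights,
        clamp=clamp_normalized,
        printed_rounding=printed_rounding,
    )
    effective_kr = profile.kr if kr is None else kr
    chi = regional_proximity(levels, effective_kr)

    meta = {
        "kr": effective_kr,
        "printed_rounding": printed_rounding,
        "clamp_normalized": clamp_normalized,
        **dict(metadata or {}),
    }
    return final_scores(
        project_scores,
        assignment,
        chi,
        levels=levels,
        group_satisfaction={
            pid: ev.group_satisfaction for pid, ev in evaluations.items()
        },
        metadata=meta,
    )
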