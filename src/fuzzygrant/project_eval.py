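"""Stage 1: evaluate one project application against the investor's wishes.

A project is scored by experts on a schema of criterion groups; per group the
scores are convolved (summed), fuzzified, projected onto the five-term
linguistic variable anchored at the fuzzified wish, and aggregated to a group
satisfaction.  A weighted average of the group satisfactions yields the
project score mu(P).
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

from .errors import ConfigurationError, ValidationError, ValidationReport
from .fuzzy_core import (
    CharacteristicValues,
    FuzzificationBounds,
    TermAssessment,
    aggregate_terms,
    project_to_terms,
    sshape_membership,
)

__all__ = [
    "Criterion",
    "CriterionGroup",
    "CriteriaSchema",
    "ScoreSheet",
    "InvestorProfile",
    "ProjectEvaluation",
    "group_convolution",
    "normalize_weights",
    "evaluate_project",
]


@dataclass(frozen=True)
class Criterion:
    id: str
    label: str = ""


@dataclass(frozen=True)
class CriterionGroup:
    id: str
    label: str = ""
    criteria: tuple[Criterion, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "criteria", tuple(self.criteria))
        if not self.criteria:
            raise ConfigurationError(f"criterion group {self.id!r} has no criteria")

    def bounds(self, score_range: tuple[float, float]) -> FuzzificationBounds:
        """Attainable sum bounds: (n*low, n*high) for n sub-criteria."""
        n = len(self.criteria)
        low, high = score_range
        return FuzzificationBounds(n * low, n * high)


@dataclass(frozen=True)
class CriteriaSchema:
    """Ordered criterion groups plus the per-criterion score range."""

    groups: tuple[CriterionGroup, ...]
    score_range: tuple[int, int] = (1, 10)

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "score_range", tuple(self.score_range))
        if not self.groups:
            raise ConfigurationError("schema needs at least one criterion group")
        low, high = self.score_range
        if not low < high:
            raise ConfigurationError(f"score range requires low < high, got ({low}, {high})")
        seen: set[str] = set()
        for group in self.groups:
            if group.id in seen:
                raise ConfigurationError(f"duplicate group id {group.id!r}")
            seen.add(group.id)
        crit_seen: set[str] = set()
        for cid in self.criterion_ids():
            if cid in crit_seen:
                raise ConfigurationError(f"duplicate criterion id {cid!r}")
            crit_seen.add(cid)

    def group_ids(self) -> tuple[str, ...]:
        return tuple(g.id for g in self.groups)

    def criterion_ids(self) -> tuple[str, ...]:
        return tuple(c.id for g in self.groups for c in g.criteria)

    def group_bounds(self) -> dict[str, FuzzificationBounds]:
        return {g.id: g.bounds(self.score_range) for g in self.groups}


@dataclass(frozen=True)
class ScoreSheet:
    """One consolidated expert score sheet: criterion_id -> points."""

    project_id: str
    region_id: str
    scores: Mapping[str, float]

    def __post_init__(self) -> None:
        coerced: dict[str, float] = {}
        for cid, value in dict(self.scores).items():
            try:  # numpy scalars and numeric strings become plain numbers
                value = float(value)
            except (TypeError, ValueError):
                pass
            coerced[str(cid)] = value
        object.__setattr__(self, "scores", coerced)

    def validate(self, schema: CriteriaSchema, *, allow_noninteger: bool = False) -> list[str]:
        """Return all validation issues against ``schema`` (empty if valid)."""
        issues: list[str] = []
        expected = set(schema.criterion_ids())
        got = set(self.scores)
        for cid in sorted(expected - got):
            issues.append(f"project {self.project_id!r}: missing score for criterion {cid!r}")
        for cid in sorted(got - expected):
            issues.append(f"project {self.project_id!r}: unknown criterion {cid!r}")
        low, high = schema.score_range
        for cid in sorted(expected & got):
            score = self.scores[cid]
            if not (isinstance(score, (int, float)) and math.isfinite(score)):
                issues.append(
                    f"project {self.project_id!r}: non-numeric score for {cid!r}: {score!r}"
                )
                continue
            if not low <= score <= high:
                issues.append(
                    f"project {self.project_id!r}: score {score} for criterion {cid!r} "
                    f"outside [{low}, {high}]"
                )
            elif not allow_noninteger and float(score) != int(score):
                issues.append(
                    f"project {self.project_id!r}: non-integer score {score} for "
                    f"criterion {cid!r} (set allow_noninteger to accept)"
                )
        return issues


@dataclass(frozen=True)
class InvestorProfile:
    """Investor-side configuration of an evaluation run.

    wishes
        Target point sum per criterion group (vector T); each wish must lie
        strictly between the group's minimum and maximum attainable sums so
        that its fuzzified value is positive and exceeding it is possible.
    group_weights
        Raw importance weights per group, each >= 1; ``None`` means balanced
        (uniform) weights.
    sigma
        Characteristic values converting linguistic confidences to scores.
    regional_criterion_weights
        Optional raw weights for the regional indicators, overriding the
        weights declared in the region table.
    kr
        Desire-for-a-regional-coefficient in [0, 1]; 1 favours the most
        developed regions, 0 the least developed.
    """

    wishes: tuple[float, ...]
    group_weights: tuple[float, ...] | None = None
    sigma: CharacteristicValues = field(default_factory=CharacteristicValues)
    regional_criterion_weights: tuple[float, ...] | None = None
    kr: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "wishes", tuple(float(t) for t in self.wishes))
        if self.group_weights is not None:
            object.__setattr__(
                self, "group_weights", tuple(float(p) for p in self.group_weights)
            )
        if self.regional_criterion_weights is not None:
            object.__setattr__(
                self,
                "regional_criterion_weights",
                tuple(float(v) for v in self.regional_criterion_weights),
            )
        if not isinstance(self.sigma, CharacteristicValues):
            object.__setattr__(self, "sigma", CharacteristicValues(tuple(self.sigma)))
        if not 0.0 <= self.kr <= 1.0:
            raise ConfigurationError(f"regional coefficient kr must be in [0, 1], got {self.kr}")

    def validate_for(self, schema: CriteriaSchema) -> list[str]:
        """All consistency issues of this profile against ``schema``."""
        issues: list[str] = []
        k = len(schema.groups)
        if len(self.wishes) != k:
            issues.append(f"profile has {len(self.wishes)} wishes for {k} criterion groups")
            return issues
        if self.group_weights is not None and len(self.group_weights) != k:
            issues.append(
                f"profile has {len(self.group_weights)} group weights for {k} groups"
            )
        for group, wish in zip(schema.groups, self.wishes):
            b = group.bounds(schema.score_range)
            if not b.min_sum < wish < b.max_sum:
                issues.append(
                    f"wish {wish} for group {group.id!r} must lie strictly inside "
                    f"({b.min_sum}, {b.max_sum}): at the minimum the wish fuzzifies to 0, "
                    "at the maximum no score can exceed it"
                )
        if self.group_weights is not None:
            for gid, p in zip(schema.group_ids(), self.group_weights):
                if p <= 0:
                    issues.append(f"group weight for {gid!r} must be positive, got {p}")
        return issues


def group_convolution(sheet: ScoreSheet, schema: CriteriaSchema) -> dict[str, float]:
    """Per-group score sums g_i (the convolution of expert points).

    Raises :class:`ValidationError` naming every offending criterion if the
    sheet does not validate against the schema.
    """
    issues = sheet.validate(schema, allow_noninteger=True)
    if issues:
        raise ValidationError(issues)
    return {
        group.id: float(sum(sheet.scores[c.id] for c in group.criteria))
        for group in schema.groups
    }


def normalize_weights(raw: Sequence[float]) -> tuple[float, ...]:
    """Normalize raw importance weights to sum to one: w_i = p_i / sum(p)."""
    raw = tuple(float(p) for p in raw)
    if not raw:
        raise ValidationError("weight vector is empty")
    bad = [p for p in raw if not (math.isfinite(p) and p > 0)]
    if bad:
        raise ValidationError(f"weights must be positive and finite, got {bad}")
    total = sum(raw)
    return tuple(p / total for p in raw)


@dataclass(frozen=True)
class ProjectEvaluation:
    """Full stage-1 trace for one project."""

    project_id: str
    region_id: str
    group_sums: dict[str, float]
    gamma: dict[str, float]
    alpha: dict[str, float]
    assessments: dict[str, TermAssessment]
    group_satisfaction: dict[str, float]
    project_score: float


def _round_assessment(assessment: TermAssessment) -> TermAssessment:
    """Round confidences to 2 decimals, keeping the partition of unity.

    The lower-index confidence is rounded and its partner takes the exact
    complement — the convention used in hand-worked evaluation protocols.
    """
    if len(assessment.terms) == 1:
        return assessment
    (f1, c1), (f2, _) = assessment.terms
    r1 = round(c1, 2)
    return TermAssessment(((f1, r1), (f2, 1.0 - r1)))


def evaluate_project(
    sheet: ScoreSheet,
    schema: CriteriaSchema,
    profile: InvestorProfile,
    *,
    printed_rounding: bool = False,
) -> ProjectEvaluation:
    """Run the stage-1 pipeline for one project.

    Per group: sum the scores, fuzzify the sum (gamma) and the wish (alpha)
    with the group's attainable bounds, project gamma onto the five-term
    linguistic variable anchored at alpha, and aggregate the term
    confidences against the characteristic values.  The project score is the
    weighted average of the group satisfactions.

    With ``printed_rounding=True`` intermediate quantities are rounded to the
    precision used in desk calculations: gamma and alpha to 2 decimals before
    term projection, confidences to 2 decimals before aggregation, and
    normalized weights to 2 decimals before the final convolution.
    """
    report = ValidationReport()
    report.extend(profile.validate_for(schema))
    report.raise_if_any()
    sums = group_convolution(sheet, schema)

    bounds = schema.group_bounds()
    gamma: dict[str, float] = {}
    alpha: dict[str, float] = {}
    assessments: dict[str, TermAssessment] = {}
    satisfaction: dict[str, float] = {}
    for group, wish in zip(schema.groups, profile.wishes):
        g = sums[group.id]
        gam = sshape_membership(g, bounds[group.id])
        alp = sshape_membership(wish, bounds[group.id])
        if printed_rounding:
            gam, alp = round(gam, 2), round(alp, 2)
        gamma[group.id] = gam
        alpha[group.id] = alp
        try:
            assessment = project_to_terms(gam, alp)
        except ConfigurationError as exc:
            raise ConfigurationError(f"group {group.id!r}: {exc}") from exc
        if printed_rounding:
            assessment = _round_assessment(assessment)
        assessments[group.id] = assessment
        satisfaction[group.id] = aggregate_terms(assessment, profile.sigma)

    raw_weights = profile.group_weights or tuple(1.0 for _ in schema.groups)
    weights = normalize_weights(raw_weights)
    if printed_rounding:
        weights = tuple(round(w, 2) for w in weights)
    score = sum(w * satisfaction[g.id] for w, g in zip(weights, schema.groups))
    return ProjectEvaluation(
        project_id=sheet.project_id,
        region_id=sheet.region_id,
        group_sums=sums,
        gamma=gamma,
        alpha=alpha,
        assessments=assessments,
        group_satisfaction=satisfaction,
        project_score=score,
    )
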