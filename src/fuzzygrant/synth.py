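"""Seeded generator of synthetic competition instances.

Emulates the study conditions of the bundled case at configurable size:
integer expert scores drawn uniformly over the score range, investor wishes
placed at a fixed fraction of each group's attainable span, and positive
regional indicator values with random benefit/cost directions.  Instances
always pass load-time validation, and identical seeds yield identical
instances, so the generator doubles as a property-test harness.

What it does *not* emulate: correlated expert scores (real experts agree
more within strong projects), region-indicator correlations, or external
national reference values (synthetic tables normalize against the
over-region extremum, so normalized values never exceed 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .fuzzy_core import CharacteristicValues
from .project_eval import (
    Criterion,
    CriteriaSchema,
    CriterionGroup,
    InvestorProfile,
    ScoreSheet,
)
from .region_eval import RegionCriterion, RegionTable

__all__ = ["SyntheticSpec", "generate_synthetic"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Size and placement parameters of a synthetic instance.

    ``criteria_per_group`` is either a fixed count or an inclusive
    ``(low, high)`` range sampled per group.  ``wish_fraction`` places each
    group wish at that fraction of the span between the group's minimum and
    maximum attainable sums; it must lie strictly inside (0, 1) because a
    wish at the minimum fuzzifies to zero and a wish at the maximum can
    never be exceeded.  ``kr`` defaults to a seeded uniform draw.
    """

    n_projects: int = 10
    n_regions: int = 4
    n_groups: int = 4
    criteria_per_group: int | tuple[int, int] = (2, 5)
    score_range: tuple[int, int] = (1, 10)
    wish_fraction: float = 0.8
    kr: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_projects", "n_regions", "n_groups"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        cpg = self.criteria_per_group
        if isinstance(cpg, int):
            if cpg < 1:
                raise ConfigurationError(f"criteria_per_group must be >= 1, got {cpg}")
        else:
            lo, hi = cpg
            if not 1 <= lo <= hi:
                raise ConfigurationError(f"bad criteria_per_group range {cpg}")
        if not 0.0 < self.wish_fraction < 1.0:
            raise ConfigurationError(
                f"wish_fraction must lie strictly in (0, 1), got {self.wish_fraction}: "
                "0 puts the wish at the group minimum (degenerate), 1 at the maximum "
                "(unexceedable)"
            )
        low, high = self.score_range
        if not low < high:
            raise ConfigurationError(f"score range requires low < high, got {self.score_range}")
        if self.kr is not None and not 0.0 <= self.kr <= 1.0:
            raise ConfigurationError(f"kr must be in [0, 1], got {self.kr}")


def generate_synthetic(
    spec: SyntheticSpec,
) -> tuple[list[ScoreSheet], CriteriaSchema, InvestorProfile, RegionTable]:
    """Draw a full competition instance deterministically from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    low, high = spec.score_range

    cpg = spec.criteria_per_group
    if isinstance(cpg, int):
        counts = [cpg] * spec.n_groups
    else:
        counts = [int(rng.integers(cpg[0], cpg[1] + 1)) for _ in range(spec.n_groups)]

    groups = tuple(
        CriterionGroup(
            id=f"G{i + 1}",
            label=f"Synthetic group {i + 1}",
            criteria=tuple(
                Criterion(f"K{i + 1}_{j + 1}", f"Synthetic criterion {i + 1}.{j + 1}")
                for j in range(counts[i])
            ),
        )
        for i in range(spec.n_groups)
    )
    schema = CriteriaSchema(groups=groups, score_range=(low, high))

    # wish at the configured fraction of each group's attainable span
    wishes = tuple(
        n * low + spec.wish_fraction * (n * high - n * low) for n in counts
    )
    profile = InvestorProfile(
        wishes=wishes,
        group_weights=tuple(float(rng.integers(1, 11)) for _ in range(spec.n_groups)),
        sigma=CharacteristicValues(),
        regional_criterion_weights=None,
        kr=float(rng.uniform(0.0, 1.0)) if spec.kr is None else spec.kr,
    )

    regions = tuple(f"R{h + 1}" for h in range(spec.n_regions))
    criterion_ids = schema.criterion_ids()
    sheets = [
        ScoreSheet(
            project_id=f"P{j + 1}",
            region_id=regions[int(rng.integers(0, spec.n_regions))],
            scores={
                cid: int(rng.integers(low, high + 1)) for cid in criterion_ids
            },
        )
        for j in range(spec.n_projects)
    ]

    n_rc = 5
    scales = rng.uniform(5.0, 500.0, size=n_rc)
    values = scales[:, None] * rng.uniform(0.5, 1.5, size=(n_rc, spec.n_regions))
    table = RegionTable(
        criteria=tuple(
            RegionCriterion(
                id=f"RC{g + 1}",
                label=f"Synthetic indicator {g + 1}",
                direction="benefit" if rng.random() < 0.5 else "cost",
                weight=float(rng.integers(1, 11)),
                reference=None,
            )
            for g in range(n_rc)
        ),
        regions=regions,
        values=values,
    )
    return sheets, schema, profile, table
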