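"""Stage 2: development level of each candidate region.

Raw quantitative health indicators (e.g. total mortality per 1,000, life
expectancy at birth, live births per 1,000, outpatient-clinic capacity per
10,000, new tuberculosis cases per 100,000) are normalized by direction-aware
ratios and contracted with normalized indicator weights into a scalar
development level Delta in (0, 1] per region.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ValidationError
from .project_eval import normalize_weights

__all__ = [
    "RegionCriterion",
    "RegionTable",
    "normalize_region_values",
    "region_development_level",
    "development_levels",
]

logger = logging.getLogger(__name__)

_DIRECTIONS = ("benefit", "cost")


@dataclass(frozen=True)
class RegionCriterion:
    """One quantitative regional indicator.

    direction
        ``"benefit"`` if larger raw values are better (life expectancy),
        ``"cost"`` if smaller raw values are better (mortality, TB
        incidence).
    reference
        Optional external benchmark (e.g. the national value).  When given
        it is the normalizing constant; otherwise the extremum over the
        table's regions is used.
    """

    id: str
    label: str = ""
    direction: str = "benefit"
    weight: float = 1.0
    reference: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTIONS:
            raise ConfigurationError(
                f"criterion {self.id!r}: direction must be one of {_DIRECTIONS}, "
                f"got {self.direction!r}"
            )
        if not (math.isfinite(self.weight) and self.weight > 0):
            raise ConfigurationError(
                f"criterion {self.id!r}: weight must be positive, got {self.weight}"
            )
        if self.reference is not None and not (
            math.isfinite(self.reference) and self.reference > 0
        ):
            raise ConfigurationError(
                f"criterion {self.id!r}: reference must be positive, got {self.reference}"
            )


@dataclass(frozen=True)
class RegionTable:
    """Raw indicator values, criteria as rows and regions as columns.

    Only strictly positive quantitative values are accepted — the ratio
    normalization is undefined at zero, and qualitative indicators need an
    upstream quantification step that is out of scope here.
    """

    criteria: tuple[RegionCriterion, ...]
    regions: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "criteria", tuple(self.criteria))
        object.__setattr__(self, "regions", tuple(str(r) for r in self.regions))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if not self.criteria:
            raise ConfigurationError("region table needs at least one criterion")
        if not self.regions:
            raise ConfigurationError("region table needs at least one region")
        if len(set(c.id for c in self.criteria)) != len(self.criteria):
            raise ConfigurationError("duplicate criterion ids in region table")
        if len(set(self.regions)) != len(self.regions):
            raise ConfigurationError("duplicate region ids in region table")
        if values.shape != (len(self.criteria), len(self.regions)):
            raise ConfigurationError(
                f"region table values have shape {values.shape}, expected "
                f"({len(self.criteria)}, {len(self.regions)})"
            )
        issues = []
        for i, criterion in enumerate(self.criteria):
            for j, region in enumerate(self.regions):
                v = values[i, j]
                if not (math.isfinite(v) and v > 0):
                    issues.append(
                        f"criterion {criterion.id!r}, region {region!r}: value must be "
                        f"a positive number, got {v}"
                    )
        if issues:
            raise ValidationError(issues)

    def raw_weights(self) -> tuple[float, ...]:
        return tuple(c.weight for c in self.criteria)


def normalize_region_values(table: RegionTable, *, clamp: bool = False) -> np.ndarray:
    """Direction-aware ratio normalization of the raw indicator matrix.

    Benefit criteria are normalized as ``value / ref`` with ``ref`` the
    criterion's reference (or the max over regions when absent); cost
    criteria as ``ref / value`` with ``ref`` the reference (or the min over
    regions).  Outputs lie in (0, 1] unless a region beats an external
    reference, in which case the value exceeds 1 and a warning is logged
    (or the value is clamped to 1 when ``clamp`` is set).
    """
    out = np.empty_like(table.values)
    for i, criterion in enumerate(table.criteria):
        row = table.values[i]
        if criterion.direction == "benefit":
            ref = criterion.reference if criterion.reference is not None else row.max()
            out[i] = row / ref
        else:
            ref = criterion.reference if criterion.reference is not None else row.min()
            out[i] = ref / row
        over = out[i] > 1.0
        if over.any():
            beaters = [r for r, o in zip(table.regions, over) if o]
            if clamp:
                out[i] = np.minimum(out[i], 1.0)
                logger.warning(
                    "criterion %r: regions %s beat the reference %s; clamped to 1",
                    criterion.id, beaters, ref,
                )
            else:
                logger.warning(
                    "criterion %r: regions %s beat the reference %s (normalized value > 1)",
                    criterion.id, beaters, ref,
                )
    return out


def region_development_level(
    normalized: np.ndarray,
    weights: Sequence[float],
    regions: Sequence[str],
    *,
    weight_sum_tol: float = 1e-6,
) -> dict[str, float]:
    """Weighted contraction of the normalized indicator matrix per region.

    ``Delta(R_h) = sum_g eps_g * O[g, h]`` with normalized weights eps
    summing to 1; a convex combination, so Delta lies between the region's
    smallest and largest normalized indicator values.  ``weight_sum_tol``
    loosens the sum-to-one check for weights that were decimal-rounded
    after normalization.
    """
    normalized = np.asarray(normalized, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if normalized.shape[0] != weights.shape[0]:
        raise ValidationError(
            f"{weights.shape[0]} weights for {normalized.shape[0]} criteria"
        )
    if normalized.shape[1] != len(regions):
        raise ValidationError(
            f"{len(regions)} region ids for {normalized.shape[1]} value columns"
        )
    if abs(weights.sum() - 1.0) > weight_sum_tol:
        raise ValidationError(f"criterion weights must sum to 1, got {weights.sum()}")
    # explicit accumulation: bit-identical across array layouts, unlike BLAS
    levels: dict[str, float] = {}
    for h, region in enumerate(regions):
        levels[region] = float(sum(w * o for w, o in zip(weights, normalized[:, h])))
    return levels


def development_levels(
    table: RegionTable,
    *,
    weights: Sequence[float] | None = None,
    clamp: bool = False,
    printed_rounding: bool = False,
) -> dict[str, float]:
    """Full stage-2 pipeline: normalize, weight, contract.

    ``weights`` are raw (unnormalized) criterion weights overriding the
    table's own; with ``printed_rounding`` the normalized matrix is rounded
    to 3 decimals and the normalized weights to 2, matching desk arithmetic.
    """
    normalized = normalize_region_values(table, clamp=clamp)
    eps = normalize_weights(weights if weights is not None else table.raw_weights())
    tol = 1e-6
    if printed_rounding:
        normalized = np.round(normalized, 3)
        eps = tuple(round(e, 2) for e in eps)
        tol = 0.05  # rounded weights need not sum to 1 exactly
    return region_development_level(normalized, eps, table.regions, weight_sum_tol=tol)
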