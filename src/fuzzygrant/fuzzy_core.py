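"""Fuzzy primitives for scoring a criterion group against an investor wish.

The first evaluation stage turns a crisp group score (a sum of expert points)
into a satisfaction value on a 0-100 scale in three steps:

1. **Fuzzification** — an s-shaped, "value x is greater" membership function
   maps the group sum ``g`` onto a degree in [0, 1] relative to the group's
   minimum and maximum attainable sums (:func:`sshape_membership`).
2. **Linguistic projection** — the fuzzified score ``gamma`` is compared with
   the fuzzified investor wish ``alpha`` through a five-term linguistic
   variable (*significantly lower*, *lower*, *close to*, *a little better*,
   *much better* than the wishes).  Each term carries a triangular membership
   function whose breakpoints are ``alpha/2, 3*alpha/4, alpha, 5*alpha/4,
   3*alpha/2``; at most two adjacent terms are active for any ``gamma``
   (:func:`project_to_terms`).
3. **Aggregation** — the active terms' confidences are contracted against a
   characteristic value per term (default ``(50, 75, 100, 75, 50)``, peaked at
   the *close to the wishes* term) to give the group satisfaction score
   (:func:`aggregate_terms`).

All functions here are pure and operate in full floating-point precision;
any decimal rounding policy is applied by the calling stage.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass, field

from .errors import ConfigurationError, DegenerateWishError

__all__ = [
    "DEFAULT_SIGMA",
    "FuzzificationBounds",
    "TermAssessment",
    "CharacteristicValues",
    "sshape_membership",
    "project_to_terms",
    "aggregate_terms",
]

#: Default characteristic values sigma_1..sigma_5 on the [1, 100] output scale.
DEFAULT_SIGMA: tuple[float, ...] = (50.0, 75.0, 100.0, 75.0, 50.0)

_CONF_TOL = 1e-9


@dataclass(frozen=True)
class FuzzificationBounds:
    """Minimum and maximum attainable point sums for one criterion group.

    For a group of ``n`` criteria each scored on ``[low, high]`` the bounds
    are ``(n * low, n * high)``.
    """

    min_sum: float
    max_sum: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.min_sum) and math.isfinite(self.max_sum)):
            raise ConfigurationError(
                f"fuzzification bounds must be finite, got ({self.min_sum}, {self.max_sum})"
            )
        if self.min_sum >= self.max_sum:
            raise ConfigurationError(
                f"fuzzification bounds require min_sum < max_sum, got "
                f"({self.min_sum}, {self.max_sum})"
            )

    @property
    def midpoint(self) -> float:
        return (self.min_sum + self.max_sum) / 2.0

    @property
    def span(self) -> float:
        return self.max_sum - self.min_sum


def sshape_membership(g: float, bounds: FuzzificationBounds) -> float:
    """S-shaped "value x is greater" membership of a group sum ``g``.

    Four-branch quadratic spline rising from 0 at ``min_sum`` to 1 at
    ``max_sum``::

        0                                   g <= min
        2*((g - min)/(max - min))**2        min < g <= (min+max)/2
        1 - 2*((max - g)/(max - min))**2    (min+max)/2 < g < max
        1                                   g >= max

    Nondecreasing in ``g``; values outside ``[min_sum, max_sum]`` saturate.
    """
    if not math.isfinite(g):
        raise ConfigurationError(f"score sum must be finite, got {g!r}")
    if g <= bounds.min_sum:
        return 0.0
    if g >= bounds.max_sum:
        return 1.0
    if g <= bounds.midpoint:
        return 2.0 * ((g - bounds.min_sum) / bounds.span) ** 2
    return 1.0 - 2.0 * ((bounds.max_sum - g) / bounds.span) ** 2


@dataclass(frozen=True)
class TermAssessment:
    """One or two adjacent linguistic terms with their confidences.

    ``terms`` is an ordered tuple of ``(term_index, confidence)`` pairs with
    term indices in 1..5 (1 = *significantly lower* ... 5 = *much better*
    than the investors' wishes).  Confidences sum to 1; when two terms are
    active they are adjacent.  A zero-confidence member is permitted: at a
    breakpoint the projection reports the vanishing neighbour explicitly
    (e.g. term 2 with confidence 0 next to term 3 with confidence 1).
    """

    terms: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.terms) <= 2:
            raise ConfigurationError(
                f"a term assessment holds 1 or 2 terms, got {len(self.terms)}"
            )
        for index, confidence in self.terms:
            if index not in (1, 2, 3, 4, 5):
                raise ConfigurationError(f"term index out of range 1..5: {index}")
            if not (-_CONF_TOL <= confidence <= 1.0 + _CONF_TOL):
                raise ConfigurationError(
                    f"confidence for term {index} outside [0, 1]: {confidence}"
                )
        if len(self.terms) == 2:
            (f1, _), (f2, _) = self.terms
            if abs(f1 - f2) != 1:
                raise ConfigurationError(
                    f"two-term assessments must use adjacent terms, got {f1} and {f2}"
                )
        total = sum(c for _, c in self.terms)
        if abs(total - 1.0) > 1e-6:
            raise ConfigurationError(f"term confidences must sum to 1, got {total}")

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(f for f, _ in self.terms)

    def confidence(self, index: int) -> float:
        """Confidence of term ``index``; 0.0 if the term is not present."""
        for f, c in self.terms:
            if f == index:
                return c
        return 0.0


@dataclass(frozen=True)
class CharacteristicValues:
    """Per-term output values sigma_1..sigma_5 on the final score scale.

    The default peaks at the middle term (*close to the wishes*) and decays
    symmetrically, but any five finite values are accepted — an investor may
    e.g. reward overshooting the wish with an asymmetric vector.
    """

    sigma: tuple[float, ...] = field(default=DEFAULT_SIGMA)

    def __post_init__(self) -> None:
        sigma = tuple(float(s) for s in self.sigma)
        object.__setattr__(self, "sigma", sigma)
        if len(sigma) != 5:
            raise ConfigurationError(
                f"characteristic values need exactly 5 entries, got {len(sigma)}"
            )
        if not all(math.isfinite(s) for s in sigma):
            raise ConfigurationError(f"characteristic values must be finite: {sigma}")


def project_to_terms(gamma: float, alpha: float) -> TermAssessment:
    """Project a fuzzified score onto the five-term linguistic variable.

    The triangular term memberships are parameterized by the fuzzified wish
    ``alpha``; on each breakpoint interval exactly two adjacent terms are
    active and their memberships sum to 1 (partition of unity).  Intervals
    are left-open/right-closed, so at a breakpoint the vanishing neighbour
    is reported with confidence 0.  Outside ``[alpha/2, 3*alpha/2]`` the
    projection saturates to the extreme term with confidence 1.

    Parameters
    ----------
    gamma : membership degree of the group score, ``>= 0``.
    alpha : membership degree of the investor wish; must be ``> 0`` since
        every term formula divides by it.
    """
    if not math.isfinite(gamma) or gamma < 0:
        raise ConfigurationError(f"gamma must be finite and >= 0, got {gamma!r}")
    if not math.isfinite(alpha) or alpha <= 0.0:
        raise DegenerateWishError(
            f"investor wish fuzzifies to alpha={alpha!r}; term projection needs alpha > 0 "
            "(raise the wish above the group's minimum attainable sum)"
        )
    a = alpha
    if gamma <= 0.5 * a:
        return TermAssessment(((1, 1.0),))
    if gamma > 1.5 * a:
        return TermAssessment(((5, 1.0),))
    if gamma <= 0.75 * a:
        pair = ((1, (3.0 * a - 4.0 * gamma) / a), (2, (4.0 * gamma - 2.0 * a) / a))
    elif gamma <= a:
        pair = ((2, (4.0 * a - 4.0 * gamma) / a), (3, (4.0 * gamma - 3.0 * a) / a))
    elif gamma <= 1.25 * a:
        pair = ((3, (5.0 * a - 4.0 * gamma) / a), (4, (4.0 * gamma - 4.0 * a) / a))
    else:
        pair = ((4, (6.0 * a - 4.0 * gamma) / a), (5, (4.0 * gamma - 5.0 * a) / a))
    # clamp fp residue at the interval edges
    pair = tuple((f, min(1.0, max(0.0, c))) for f, c in pair)
    return TermAssessment(pair)


def aggregate_terms(
    assessment: TermAssessment,
    sigma: CharacteristicValues | Sequence[float] | None = None,
) -> float:
    """Contract term confidences against the characteristic values.

    Returns ``sum_f confidence_f * sigma_f`` over the present terms — the
    group satisfaction score.  With the default sigma the result lies in
    [50, 100] and equals ``sigma_f`` exactly when a single term has
    confidence 1.
    """
    if sigma is None:
        cv = CharacteristicValues()
    elif isinstance(sigma, CharacteristicValues):
        cv = sigma
    else:
        cv = CharacteristicValues(tuple(sigma))
    return sum(c * cv.sigma[f - 1] for f, c in assessment.terms)
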