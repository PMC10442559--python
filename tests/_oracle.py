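"""Independent step-by-step oracle used to cross-check the implementation.

Every function here re-derives its quantity directly from the published
formulas, symbol by symbol, with explicit piecewise branches and plain
loops — deliberately sharing no code with the package.
"""

from __future__ import annotations


def oracle_sshape(g: float, lo: float, hi: float) -> float:
    if g <= lo:
        return 0.0
    if g >= hi:
        return 1.0
    mid = (lo + hi) / 2
    if g <= mid:
        return 2 * ((g - lo) / (hi - lo)) ** 2
    return 1 - 2 * ((hi - g) / (hi - lo)) ** 2


def oracle_term_memberships(gamma: float, alpha: float) -> list[float]:
    """Memberships of the five linguistic terms, each from its own formula."""
    a = alpha
    g = gamma

    def u1():
        if g <= a - a / 2:
            return 1.0
        if a - a / 2 < g <= a - a / 4:
            return (3 * a - 4 * g) / a
        return 0.0

    def u2():
        if a - a / 2 < g <= a - a / 4:
            return (4 * g - 2 * a) / a
        if a - a / 4 < g <= a:
            return (4 * a - 4 * g) / a
        return 0.0

    def u3():
        if a - a / 4 < g <= a:
            return (4 * g - 3 * a) / a
        if a < g <= a + a / 4:
            return (5 * a - 4 * g) / a
        return 0.0

    def u4():
        if a < g <= a + a / 4:
            return (4 * g - 4 * a) / a
        if a + a / 4 < g <= a + a / 2:
            return (6 * a - 4 * g) / a
        return 0.0

    def u5():
        if a + a / 4 < g <= a + a / 2:
            return (4 * g - 5 * a) / a
        if g > a + a / 2:
            return 1.0
        return 0.0

    return [u1(), u2(), u3(), u4(), u5()]


def oracle_aggregate(memberships: list[float], sigma: list[float]) -> float:
    """Contraction of all five term memberships against the characteristic values."""
    total = 0.0
    for mu, s in zip(memberships, sigma):
        total += mu * s
    return total


def oracle_project_score(
    scores_by_group: list[list[float]],
    wishes: list[float],
    raw_weights: list[float],
    score_range: tuple[float, float],
    sigma: list[float],
) -> tuple[list[float], float]:
    """Full stage-1 composition for one project; returns (mu_O list, mu_P)."""
    low, high = score_range
    mu_o = []
    for scores, wish in zip(scores_by_group, wishes):
        n = len(scores)
        g = sum(scores)
        gamma = oracle_sshape(g, n * low, n * high)
        alpha = oracle_sshape(wish, n * low, n * high)
        memberships = oracle_term_memberships(gamma, alpha)
        mu_o.append(oracle_aggregate(memberships, sigma))
    wsum = sum(raw_weights)
    mu_p = sum(p / wsum * o for p, o in zip(raw_weights, mu_o))
    return mu_o, mu_p


def oracle_normalize_region(
    values: list[list[float]],
    directions: list[str],
    references: list[float | None],
) -> list[list[float]]:
    out = []
    for row, direction, ref in zip(values, directions, references):
        if direction == "benefit":
            r = ref if ref is not None else max(row)
            out.append([v / r for v in row])
        else:
            r = ref if ref is not None else min(row)
            out.append([r / v for v in row])
    return out


def oracle_development(
    normalized: list[list[float]], raw_weights: list[float]
) -> list[float]:
    wsum = sum(raw_weights)
    eps = [w / wsum for w in raw_weights]
    n_regions = len(normalized[0])
    return [
        sum(eps[g] * normalized[g][h] for g in range(len(normalized)))
        for h in range(n_regions)
    ]


def oracle_chi(deltas: list[float], kr: float) -> list[float]:
    if max(deltas) == min(deltas):  # degenerate spread: nothing to discriminate
        return [1.0 for _ in deltas]
    d = max(kr - min(deltas), max(deltas) - kr)
    return [1 - abs(kr - delta) / d for delta in deltas]


def oracle_competition(
    scores_by_group_by_project: dict[str, list[list[float]]],
    project_regions: dict[str, str],
    wishes: list[float],
    group_weights: list[float],
    score_range: tuple[float, float],
    sigma: list[float],
    region_ids: list[str],
    region_values: list[list[float]],
    directions: list[str],
    references: list[float | None],
    region_weights: list[float],
    kr: float,
) -> dict[str, dict]:
    """End-to-end composition of all three stages; returns per-project records."""
    normalized = oracle_normalize_region(region_values, directions, references)
    deltas = oracle_development(normalized, region_weights)
    delta_by_region = dict(zip(region_ids, deltas))
    chis = oracle_chi(deltas, kr)
    chi_by_region = dict(zip(region_ids, chis))
    out = {}
    for pid, groups in scores_by_group_by_project.items():
        mu_o, mu_p = oracle_project_score(
            groups, wishes, group_weights, score_range, sigma
        )
        region = project_regions[pid]
        out[pid] = {
            "mu_o": mu_o,
            "mu_p": mu_p,
            "delta": delta_by_region[region],
            "chi": chi_by_region[region],
            "y": mu_p * chi_by_region[region],
        }
    return out
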