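# Methods

## Model overview

`fuzzygrant` ranks project applications by composing three stages:

**Stage 1 — project scores.** For each criterion group *i* with *n_i*
sub-criteria scored on `[low, high]` (default `[1, 10]`), the expert point
sum `g_i` ranges over `[n_i·low, n_i·high]`. Both `g_i` and the investor's
wish `t_i` are fuzzified by the s-shaped, nondecreasing "value x is greater"
spline over that range, giving γ_i = μ(g_i) and α_i = μ(t_i). γ_i is then
projected onto a five-term linguistic variable whose triangular memberships
are anchored at α_i/2, 3α_i/4, α_i, 5α_i/4, 3α_i/2; on each anchor interval
exactly two adjacent terms are active and their memberships sum to one
(partition of unity — property-tested). Outside `[α/2, 3α/2]` the projection
saturates to the extreme term with confidence 1. The active confidences are
contracted against the characteristic values σ, and the group satisfactions
are averaged with normalized group weights into μ(P).

The model assumes a single consolidated score sheet per project (multi-expert
panels and consensus procedures are out of scope), that within-group point
sums are a meaningful convolution (the sum is fixed here, though the
operation is the natural extension point for other convolutions), and that
wishes are stated per group on the same point scale as the scores.

**Stage 2 — region development levels.** Quantitative indicators with
declared direction (benefit: larger is better; cost: smaller is better) are
normalized by ratios — `value/ref` for benefit, `ref/value` for cost — and
contracted with normalized indicator weights into Δ(R), a convex combination
of the normalized column, hence bounded by its extremes. Only strictly
positive values are accepted: the ratios are undefined at zero, and
qualitative indicators would need an upstream quantification step this
package deliberately does not provide.

**Stage 3 — proximity and ranking.** With D = max(KR − min Δ, max Δ − KR),
each region gets χ(R) = 1 − |KR − Δ(R)|/D ∈ [0, 1]; χ orders regions by
closeness of Δ to KR, the farthest extreme always getting 0. Output scores
Y = μ(P)·χ rank the projects. Re-running with a revised profile (different
wishes, weights, σ, KR, or added indicators) implements the investor's
re-evaluation loop; a KR sweep is available as a subcommand.

## Parameters

| Parameter | Units / range | Default | Why |
| --- | --- | --- | --- |
| `score_range` | points per criterion | (1, 10) | common expert grading scale |
| `wishes` t_i | points, strictly inside (n_i·low, n_i·high) | required | at the minimum the wish fuzzifies to α = 0 (the term formulas divide by α); at the maximum no score could exceed it, making the upper terms unreachable — both are rejected as configuration errors |
| `group_weights` p_i | raw, > 0 | uniform | missing weights are treated as balanced |
| `sigma` σ | output scale, 5 values | (50, 75, 100, 75, 50) | peaked at *close to the wishes*; a 100-point final scale is customary for grant scoring; investor-configurable (e.g. asymmetric vectors that reward overshooting) |
| indicator `direction` | benefit / cost | required | determines the ratio orientation |
| indicator `reference` | raw units, > 0 | none (over-region extremum) | a national benchmark when available; the extremum otherwise |
| `kr` | dimensionless [0, 1] | 0.5 | neutral midpoint; the bundled case uses 0.8 |
| `printed_rounding` | flag | off | see below |
| `clamp_normalized` | flag | off | see below |

## Numerical and design choices

- **Interval endpoints.** The term-projection intervals are left-open,
  right-closed; a γ exactly at a breakpoint resolves to the right-closed
  branch and the vanishing neighbour is reported explicitly with confidence
  0 (e.g. terms (2: 0, 3: 1) when the score sum equals the wish). This keeps
  the assessment's shape stable across the breakpoint and makes the
  partition of unity hold with equality everywhere.
- **Printed-rounding mode.** Desk protocols for this model round
  intermediates to fixed decimals; the flag reproduces that arithmetic:
  γ and α to 2 decimals before term projection; the lower-index confidence
  to 2 decimals with its partner taking the exact complement; normalized
  group weights to 2 decimals before the final convolution (they may then
  sum to 1 ± 0.01 — the weight-sum check is relaxed accordingly); normalized
  indicator values to 3 decimals and indicator weights to 2 before Δ.
  Default is full floating-point precision end to end.
- **Regions beating an external reference.** When a region outperforms the
  national benchmark the normalized value exceeds 1; this is allowed and
  logged as a warning rather than silently clamped (clamping is available by
  flag), since clamping would hide a real difference between regions.
- **Degenerate proximity.** When all Δ are equal — in particular with a
  single region — the relative distance normalization has nothing to
  discriminate: the formula would either divide by zero (Δ = KR) or zero
  out every region. All regions then get χ = 1 by convention, logged as a
  warning; proximity must not veto projects when it carries no information.
- **Tie-breaking.** Ranking sorts by Y descending, then μ(P) descending,
  then stable input order — a deterministic total order even when a χ = 0
  region zeroes several projects at once.
- **Bit-level determinism.** Δ is accumulated with an explicit loop rather
  than a BLAS matrix product; BLAS results can differ in the last bit with
  array alignment, which would break byte-identical reports across input
  paths (in-memory fixture vs files on disk).
- **Validation.** Loaders and the competition entry point collect *every*
  issue (missing/duplicate/out-of-range criteria, dangling region
  references, invalid wishes) into one report instead of failing at the
  first, naming file and key.

## The bundled case and its recorded desk values

The demonstration fixture (five Ukrainian healthcare research projects, four
oblasts, national benchmarks, KR = 0.8) stores, next to the raw inputs, the
hand-worked reference intermediates of the original desk evaluation. A few
of those recorded figures contain small arithmetic slips — a fuzzified group
score recorded as 0.97 where the spline gives 0.9644, one confidence pair
recorded as 0.78/0.22 where the formulas give ≈0.74/0.26 (rounded), a
project score recorded as 96.4 where the recorded operands give 96.335, and
two development levels recorded one unit low in the third decimal. The
regression tests therefore pin recorded and recomputed values separately,
each at its own tolerance, and the final rank order — which is robust under
every precision mode — is the primary regression surface. Projects P2–P5
enter with externally published project scores (`given_scores`) rather than
score sheets; cross-project comparability of those scores is an input
assumption, not something the model derives.

## Synthetic data

The seeded generator emulates the study conditions at configurable size:
integer scores uniform over the score range; wishes at a fixed fraction
(default 0.8) of each group's attainable span, mirroring the bundled case
where wishes sit at 78–93% of the group maxima; integer weights uniform on
1–10; five regional indicators with random direction and positive values
spread ±50% around a per-indicator scale; KR drawn uniformly unless fixed.
Identical seeds give identical instances, and generated instances always
pass load-time validation.

It does **not** emulate: correlation between experts or between a project's
groups (real sheets are strongly correlated), correlated regional indicators,
or external national references (synthetic tables normalize against the
over-region extremum, so synthetic Δ never exceeds 1). Passing property
tests on synthetic instances therefore demonstrates the pipeline's
invariants (ranges, partition of unity, ordering, determinism, oracle
equivalence), not calibration against real competition data.

Default problem sizes in the test suite (3–10 projects, 3–4 regions, 2–4
groups, up to 6 criteria per group) keep each property batch at desk scale;
the model itself is size-independent.

## Known limitations

- Group convolution is the plain sum; weighted or nonlinear within-group
  convolutions are not implemented.
- One score sheet per project: no inter-rater aggregation or reliability
  statistics.
- Qualitative regional indicators are rejected, not quantified.
- χ is relative to the candidate set: adding or removing a region can change
  every χ (the denominator D depends on the Δ extremes). This is inherent to
  the relative-proximity definition.
- The output score Y conflates quality and regional fit multiplicatively; a
  project in a χ = 0 region is eliminated regardless of quality. That is the
  intended policy semantics, but users should inspect μ(P) alongside Y.
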