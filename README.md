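# fuzzygrant

Fuzzy multi-criteria ranking of healthcare project applications that lets an
investor bias selection toward less- (or more-) developed regions with a
single knob.

## The problem

Grant-style competitions score project applications with expert point sheets,
but structural and investment funds often also pursue a policy goal: closing
the development gap between regions. In practice the better-resourced regions
submit the stronger applications, so a pure quality ranking concentrates
funding where it is least needed. `fuzzygrant` implements a three-stage fuzzy
decision-support model that keeps the expert quality assessment and folds the
regional policy in explicitly:

1. **Project evaluation.** Experts score each application on a configurable
   schema of criterion groups (default: idea & quality, societal
   significance, plan quality & realism, implementing team). Per group the
   point sum *g* is fuzzified with an s-shaped "value x is greater"
   membership function over the group's attainable range,

   μ(g) = 0 for g ≤ min; 2·((g−min)/(max−min))² up to the midpoint;
   1 − 2·((max−g)/(max−min))² above it; 1 for g ≥ max,

   and compared with the investor's fuzzified per-group **wish** α = μ(t)
   through a five-term linguistic variable (*significantly lower … much
   better than the wishes*) with triangular memberships anchored at
   α/2, 3α/4, α, 5α/4, 3α/2. The one or two active terms are contracted
   against characteristic values σ = (50, 75, 100, 75, 50) — peaked at
   *close to the wishes* — giving a group satisfaction μ(O) ∈ [50, 100], and
   the weighted average over groups gives the project score μ(P).
2. **Region evaluation.** Quantitative regional health indicators (mortality,
   life expectancy, birth rate, outpatient capacity, TB incidence, …) are
   normalized by direction-aware ratios against a reference (a national
   benchmark, or the over-region extremum) and contracted with normalized
   weights into a development level Δ(R) ∈ (0, 1].
3. **Ranking.** The investor picks the desire-for-a-regional-coefficient
   KR ∈ [0, 1] (0 favours the least developed regions, 1 the most). Each
   region receives a proximity coefficient
   χ(R) = 1 − |KR − Δ(R)| / max(KR − min Δ, max Δ − KR),
   and projects are ranked by the output score Y = μ(P) · χ(region).

## Worked example

The package bundles a demonstration case: five Ukrainian state-funded
healthcare research projects across four oblasts, with the national values of
Ukraine as normalization benchmarks and KR = 0.8. The `--printed-rounding`
flag rounds intermediates to the 2-/3-decimal precision of a hand-worked
evaluation protocol.

```text
$ fuzzygrant evaluate --fixture demo --printed-rounding
KR = 0.8
rank  project  region          mu(P)    Delta    chi      Y
   1  P5       Lviv            92.8     0.7884   0.9154   84.9461
   2  P3       Kharkiv         94.4     0.7756   0.8214   77.5367
   3  P1       Zakarpattia     97.3175  0.8614   0.5505   53.5713
   4  P2       Kyiv            96.1     0.9366   0        0
   5  P4       Kyiv            93.4     0.9366   0        0
ranking: P5, P3, P1, P2, P4
```

Reading the output: P2 has the second-best expert score μ(P) = 96.1, but its
region (Kyiv) is the most developed (Δ = 0.937) and hence the farthest
extreme from the investor's KR = 0.8, so χ = 0 wipes its output score; the
Lviv project P5 wins despite the lowest μ(P) because its region's development
level best matches the investor's regional wish. Sweeping KR shows the knob
at work — at KR = 1 the Kyiv projects jump to the top:

```text
$ fuzzygrant sweep-kr --fixture demo --grid 0,0.5,1
KR=0      ranking: P3 > P5 > P1 > P2 > P4
KR=0.5    ranking: P3 > P5 > P1 > P2 > P4
KR=1      ranking: P2 > P4 > P1 > P5 > P3
```

The same pipeline is available as a library (`evaluate_competition`,
`evaluate_project`, `development_levels`, `regional_proximity`), on your own
CSV/YAML inputs (`fuzzygrant evaluate --sheets … --config … --region-table …
--sidecar …`; see the docstrings in `fuzzygrant.io` for the exact columns),
and on seeded synthetic instances (`fuzzygrant synth`).

## Documentation

`docs/methods.md` describes the model, its assumptions, every tunable
parameter, the rounding modes, the synthetic-data generator and the known
limitations.
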