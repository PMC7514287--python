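# sigentropy

Sample-entropy analysis of online-signature dynamics for early-stage
Alzheimer's screening.

## The problem

A handwritten signature is one of the most automated movements an adult
produces. A digitizing tablet records it as five raw temporal functions at
125 Hz — pen position *x(t)*, *y(t)*, pressure *p(t)* (0 while the pen is
in the air), and the two pen inclination angles, azimuth *Az(t)* and
altitude *Alt(t)*. Early neurodegeneration subtly disturbs this automated
motor program, and the disturbance shows up as a loss of *information
content* in those signals: patients' channels become more regular, more
predictable, than those of healthy writers of the same age.

`sigentropy` quantifies that information content with **sample entropy**
(SampEn) and carries it through a complete screening-style analysis:
metadata correlations, signature-style clustering, nonparametric group
testing, and linear classification — all exercised end-to-end on a seeded
synthetic cohort generator that emulates the structure of a 31-patient /
39-control clinical sample (two signatures per person), so every stage is
reproducible without any private data. It is a library first (the modules
below), with an `examples/` directory of narrative scripts and a thin
`sigentropy` command-line wrapper.

## The measure

For a series *u(1), …, u(N)*, embed the *N − m + 1* overlapping templates
*X<sub>m</sub>(i) = (u(i), …, u(i+m−1))* and use the Chebyshev distance
*d(X<sub>m</sub>(i), X<sub>m</sub>(j)) = max<sub>k</sub> |u(i+k) − u(j+k)|*.
With *B* the number of template pairs within tolerance *r* in dimension
*m*, and *A* the same count in dimension *m + 1*,

> SampEn(m, r) = −ln (A / B),   with A ≤ B, hence SampEn ≥ 0.

Lower values mean a more regular, less information-rich signal. The
tolerance is taken relative to the standard deviation of the series
(*r*/std convention), which makes SampEn invariant under affine rescaling
of a channel — device units never matter. The engine sweeps the full
hyper-parameter grid *m = 1…9*, *r = 0.1…0.9*, counts pairs with the
Richman–Moorman restricted convention by default (both *A* and *B* over
the *N − m* extendable templates, which guarantees A ≤ B), and exposes the
literal template convention, the distance inequality, and the std
estimator as options. A deliberately naive O(N²) brute-force oracle ships
in the package and the tests hold the optimized path to exact count
agreement with it.

## Modules

| module | what it does |
| --- | --- |
| `sigentropy.records` | domain types (signature, subject, cohort) and SVC-style text + CSV I/O |
| `sigentropy.sampen` | SampEn engine: embedding, match counting, grid sweep, brute-force oracle |
| `sigentropy.simulate` | seeded synthetic cohort generator (stroke-based signature synthesis) |
| `sigentropy.stats` | person-level aggregation, correlations, k-means style clustering, Mann–Whitney, group summaries |
| `sigentropy.classify` | entropy feature matrices, linear SVM / LDA under two-fold CV, prior-relative improvements |
| `sigentropy.pipeline` | one-call orchestration with config hashing and cached grids |

## Worked example

```python
from sigentropy import SimulationConfig, generate_cohort
from sigentropy.stats import (Selector, build_cohort_table, compute_grid_map,
                              mann_whitney_test, relative_increase)

cohort = generate_cohort(SimulationConfig(seed=7))    # 31 AD + 39 HC subjects
grids = compute_grid_map(cohort)                      # SampEn over the full (m, r) grid
table = build_cohort_table(cohort, grids, Selector("fixed", 3, 0.1))
for ch in ("x", "y", "p", "Alt"):
    t = mann_whitney_test(table, ch)
    print(ch, round(relative_increase(table, ch), 1), t.p_value)
```

prints (channel, relative entropy increase of controls over patients in
percent, two-sided Mann–Whitney p-value at m = 3, r/std = 0.1):

```
x 1.8 0.29
y -0.3 0.91
p 59.5 1.2e-09
Alt 29.3 1.1e-06
```

The synthetic patients' entropy deficit is concentrated on pen pressure
and altitude — position channels barely separate the groups, pressure
does so decisively. `examples/04_classification.py` continues this run:
a linear SVM on the pressure features detects ~88% of patients against a
44% base rate.

Each example in `examples/` is a self-contained script for one
capability: the measure itself, cohort simulation, cohort statistics,
classification, and the one-call pipeline (also available as
`sigentropy run --seed 21 --out demo_out`).

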