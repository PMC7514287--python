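"""Cohort-level statistics: metadata correlations, style clustering, and the
AD vs HC group comparison.

Computes person-average SampEn per channel, correlates it with MMSE and
age, clusters subjects in the (SE(x), SE(y)) plane, and tests the group
difference at the discriminative cell (m=3, r/std=0.1).
"""

from sigentropy import SimulationConfig, generate_cohort
from sigentropy.stats import (
    Selector,
    build_cohort_table,
    compute_grid_map,
    correlate_metadata,
    mann_whitney_test,
    relative_increase,
    style_cluster,
)

cohort = generate_cohort(SimulationConfig(seed=7))
grids = compute_grid_map(cohort)  # full (m, r) grid, channels x, y, p, Alt

# Correlations use grid-averaged entropy (one coefficient per channel);
# tests use the fixed discriminative cell.
avg_table = build_cohort_table(cohort, grids, Selector("grid_average", None, None))
cell_table = build_cohort_table(cohort, grids, Selector("fixed", 3, 0.1))

print("correlation of person-average SampEn with metadata (n = 70):")
for cov in ("mmse", "age"):
    row = "  ".join(
        f"{ch}: {correlate_metadata(avg_table, ch, cov):+.2f}" for ch in ("x", "y", "p", "Alt")
    )
    print(f"  {cov:>5}: {row}")
print("  -> more irregular signatures go with higher MMSE and younger age")

clusters = style_cluster(cell_table, k=3, seed=0)
print("\nstyle clustering on (SE(x), SE(y)):")
print(clusters.crosstab.to_string())
share = 100 * clusters.crosstab.sum(axis=1).max() / clusters.crosstab.to_numpy().sum()
print(f"  dominant cluster holds {share:.1f}% of subjects: "
      "entropy is largely style-independent")

print("\nAD vs HC at (m=3, r/std=0.1):")
for ch in ("x", "y", "p", "Alt"):
    t = mann_whitney_test(cell_table, ch)
    ri = relative_increase(cell_table, ch)
    print(f"  {ch:>4}: HC mean exceeds AD by {ri:5.1f}%   Mann-Whitney p = {t.p_value:.2g}")
print("  -> the entropy deficit of the AD group is strongest on pen pressure")
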