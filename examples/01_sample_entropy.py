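"""Sample entropy of a time series: the core measure.

Builds a perfectly periodic series and a noisy one, computes SampEn at a
few (m, r) cells, and sweeps the full hyper-parameter grid on one synthetic
signature channel.
"""

import numpy as np

from sigentropy import SEParams, entropy_grid, sample_entropy
from sigentropy.simulate import SimulationConfig, generate_cohort

# A periodic series is perfectly predictable: every length-m template match
# extends to m+1, so SampEn is exactly 0.
periodic = np.array([1.0, 2.0, 3.0] * 4)
ev = sample_entropy(periodic, SEParams(m=2, r_rel=0.1), tolerance=0.1)
print(f"periodic series: SampEn = {ev.value:.3f}  (A={ev.counts.A}, B={ev.counts.B})")

# White noise is maximally unpredictable at fine tolerance.
rng = np.random.default_rng(0)
noisy = rng.standard_normal(300)
ev = sample_entropy(noisy, SEParams(m=2, r_rel=0.2))
print(f"white noise:     SampEn = {ev.value:.3f}  (A={ev.counts.A}, B={ev.counts.B})")

# Full grid sweep on a synthetic signature's pressure channel: SampEn falls
# as the tolerance r grows, and barely moves with the template length m.
cohort = generate_cohort(SimulationConfig(n_ad=1, n_hc=1, seed=1))
sig = cohort.subjects[0].signature(1)
grid = entropy_grid(sig, channels=("p",))
print(f"\npressure channel of one synthetic signature (N={grid.n_samples}):")
print("  r:   " + "  ".join(f"{r:.1f}" for r in grid.r_range))
for m in (1, 3, 9):
    row = [grid.value("p", m, r) for r in grid.r_range]
    txt = "  ".join(f"{e.value:.2f}" if e.defined else " -- " for e in row)
    print(f"  m={m}: {txt}")
print("rows are nearly identical (m barely matters); values fall along each row")
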