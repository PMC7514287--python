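# Methods

## Sample entropy

SampEn(m, r) of a series u(1..N) is −ln(A/B): B counts unordered pairs of
length-m templates whose Chebyshev distance is below the tolerance, A the
same for length-(m+1) templates, self-pairs excluded. Unordered counting
halves both A and B relative to ordered counting and leaves the ratio
unchanged (asserted in the tests). Two conventions differ between
published implementations, and both are exposed:

* **Template convention.** Default `restricted` (Richman–Moorman): A and B
  both range over the N−m templates that admit an (m+1)-point extension.
  Every (m+1)-dimensional pair then has a corresponding m-dimensional
  pair, so A ≤ B and SampEn ≥ 0 structurally. The `literal` option lets B
  range over all N−m+1 length-m templates for sensitivity analysis.
* **Inequality.** Default strict (d < r); non-strict available.

The natural logarithm is used, and the tolerance is r_rel × std(series)
with the N−1 sample std by default (population std available). The std is
computed on the whole raw channel, pen-up samples included, because the
analysis treats the complete signing gesture — in-air movement carries
signal too.

**Undefined values are first class.** A constant series (std = 0) or a
zero count (A = 0 or B = 0) yields an undefined result carrying its
counts, never an exception or a silent drop. Downstream policy differs by
stage: statistics exclude undefined values pairwise (with counts logged);
classification, by default, replaces an undefined (A = 0) value with the
maximum resolvable entropy ln((N−m)(N−m−1)/2) — A = 0 means not even one
template pair survived extension, i.e. maximal irregularity, so a small or
mean-imputed value would invert the signal. A `drop` policy removes the
subject instead.

**Tolerance = 0.** The match-counting precondition admits a zero
tolerance (returning zero counts under the strict inequality); only
negative tolerances are rejected. A defined entropy still requires a
positive tolerance.

**Implementation.** The optimized counter builds the N×N pairwise sample
distance matrix once per channel and propagates template matches along
diagonals (S_{L+1}[i,j] = S_L[i,j] ∧ close[i+L, j+L]), so one O(N²)
structure serves the whole 9×9 (m, r) sweep. It is held to exact count
agreement with a deliberately naive double-loop oracle that ships in the
package, and with an independent embedding + Chebyshev-distance-matrix
oracle in the test suite. A full default grid (4 channels × 81 cells) on a
1500-sample signature takes well under a second.

## Synthetic cohort generator

The generator exists so that every pipeline stage is testable and
reproducible without clinical data. It emulates the *statistical
structure* the analysis relies on, not the visual appearance of real
signatures.

**Structure.** 31 AD / 39 HC subjects by default, two signatures each,
five channels at 125 Hz, durations uniform on 1.5–4.0 s. Demographics
follow the emulated sample's per-group/per-sex cells: sex splits 14/17
(AD) and 7/32 (HC); ages normal with the cell means and stds; MMSE drawn
from a truncated normal whose location is solved (Brent's method) so the
*truncated* mean hits the cell target, then rounded to an integer —
truncation alone would bias the AD mean upward by more than a point. AD
MMSE is confined to 21–30 (the early-stage inclusion criterion), HC to
26–30 (a floor consistent with a 28.8 ± 1 marginal; the exact floor is a
free choice). Style labels are drawn from per-group probabilities over
{stylized, mixed}; text-based signatures have probability zero. All but
roughly one subject in seventy are right-handed.

**Signal synthesis.** Each signature is a sequence of K pen-down strokes
(Poisson counts, means 5 for AD and 7 for HC, minimum 2) separated by
pen-up gaps (pressure exactly 0; realized pen-up fraction ≈ 10–24% of
samples). Per stroke, speed follows a lognormal-in-time bump whose
direction rotates at a per-stroke angular velocity; x and y integrate
that velocity, plus a 4 Hz oscillatory "writing rhythm" (amplitude 0.3 of
the positional std) that keeps the trajectory wavy rather than
trend-dominated — without it the SampEn-vs-r profile of the position
channels develops small non-monotonic bumps at large tolerance. Pressure
is a per-stroke flat-top envelope with raised-cosine attack and release
(a Tukey window): grip pressure plateaus mid-stroke, which is where
template matches concentrate, so the noise modulation acts exactly where
SampEn looks. A pure 0-to-peak raised cosine turned out to pin SampEn(p)
at an envelope-geometry constant insensitive to the irregularity
parameter. Altitude is a per-subject baseline plus κ times the normalized
vertical velocity (default κ = 10 degrees per unit; strong vertical
movement tilts the pen) plus noise. Azimuth is a per-subject baseline
with small between-subject spread (8 units), a tiny linear drift, and a
small fixed-amplitude noise — a nearly constant channel, as expected of
an almost entirely right-handed population.

**The group difference** is a single irregularity parameter θ per subject
(lognormal around group geometric means 0.06 AD / 0.12 HC, log-sd 0.22,
within-subject jitter 0.12). θ scales the stochastic component of every
channel: multiplicative pressure modulation (1 + θ·noise), additive
altitude noise, and broadband positional noise. "Smooth noise" is white
Gaussian noise low-pass filtered at a group-dependent cutoff — 5.8 Hz for
AD, 7.7 Hz for HC — and bandwidth, not amplitude, is the dominant lever:
smooth noise rarely breaks the extension of a matched template, so SampEn
responds mostly to how fast the noise decorrelates. Position and altitude
additionally carry a θ-independent tremor floor (0.20 and 0.12 of the
respective noise scales, fixed 8 Hz bandwidth) so the healthy-vs-patient
contrast concentrates on pressure and altitude rather than on x/y, which
is the phenomenology the analysis expects. These defaults were fixed once
by offline calibration so that the pressure-channel relative increase of
the HC group mean over AD at (m = 3, r/std = 0.1) lands centrally in a
30–70% bracket (measured: 36–69% across seeds, mean ≈ 51%); that bracket
is a generator design target, not a claim about real data.

**Metadata coupling.** A Gaussian copula with coefficient β = 0.6 ties
the standardized θ to MMSE (positively) and age (negatively) while
leaving the marginals on their targets. Setting β = 0 *and* equalizing
the group irregularity knobs removes the MMSE–entropy association
entirely; with the group gap in place, a positive association persists at
β = 0 simply because patients have both lower MMSE and lower θ.

**Determinism.** One master seed; each subject draws from a
counter-derived substream (SeedSequence spawn keys), so subject i is
bit-identical across runs and unchanged when the cohort grows.

**What passing tests do not show.** The generator makes no claim of
kinematic realism: stroke shapes, pressure magnitudes, durations and
stroke counts are plausible but uncalibrated against any real corpus
(real per-signature durations and stroke counts are not publicly
reported). Effect recovery on this cohort demonstrates that the pipeline
detects the structure it was designed to detect — it is evidence about
the code, not about patients.

## Statistics

* **Person averages.** The unit of analysis is the subject: the SampEn of
  the two signatures is averaged when both are defined, the single
  defined value is used when one is, and the subject is NaN when neither
  is. A pooled per-signature mode is not provided; person-level n = 70 is
  the default throughout.
* **Selectors.** Correlations with MMSE and age default to the
  grid-average of SampEn over all 81 (m, r) cells (one coefficient per
  channel summarizing the whole sweep); group tests, clustering and
  classification default to the fixed cell (m = 3, r/std = 0.1), the most
  discriminative region of the grid. Both selectors are available
  everywhere and the choice is recorded in every output.
* **Correlation.** Pearson by default, Spearman available.
* **Clustering.** k-means (k = 3) on the 2-D person-average
  (SE(x), SE(y)) points: squared Euclidean, k-means++ with 10 restarts,
  300-iteration cap, tolerance 1e−6, seeded. Clusters are relabeled by
  decreasing SE(x) centroid so cluster 0 is always the highest-entropy
  group, and a cluster × style cross-tabulation is returned.
* **Group test.** Two-sided Mann–Whitney U on person averages; normal
  approximation with tie correction by default, exact enumeration
  optional for small groups. No multiple-testing correction is applied
  across the four channels — raw p-values are reported as such, and
  consumers should bear this in mind.
* **Relative increase.** 100 × (mean_HC − mean_AD)/mean_AD at the
  selector's cell.

## Classification

Features are the per-signature SampEn values at the fixed cell (two
columns per channel); channel sets {p}, {Alt}, {p, Alt}, {x, y, p, Alt}
by default. Evaluation is stratified two-fold cross-validation: a seeded
random 50/50 split within each group, train on one half, predict the
other, swap, and pool the held-out predictions into one confusion matrix
(pooling is stated in every report). Features are standardized with
training-fold statistics only; zero-variance training features are
dropped with a warning. The SVM uses a linear kernel with C = 1 and the
LDA pooled covariance with empirical priors (both exposed). A single
2-fold split of 70 subjects is high-variance, so a `repeats` option
redraws the split and reports mean ± sd alongside the first split's
counts. Sensitivity (patients detected) and specificity (controls
detected) are judged by their relative improvement over the a-priori
group probabilities 31/70 and 39/70.

## Numerical choices and edge cases

* Match counts are integers and compared exactly against oracles; SampEn
  values agree with the oracle to 1e−12.
* −ln(A/B) is normalized to +0.0 when A = B.
* The SVC-style writer emits floats via `repr`, so read-after-write is
  bit-exact; the time column is carried (8 ms steps at 125 Hz) but never
  used in analysis — uniform sampling is assumed, not checked.
* Pressure is authoritative for pen-up (p = 0); the button column in the
  file dialect is validated for consistency but not trusted.
* Grid cells with A = 0 at small r are retained as undefined with their
  counts; on the synthetic cohort defaults they essentially never occur
  (0 of 45 360 cells in a typical run), but the policy machinery is
  exercised by tests regardless.

## Known limitations

* Entropy is the only feature family; kinematic descriptors (speed,
  acceleration, jerk) are out of scope.
* The two-fold protocol and the undefined-value cap follow common
  practice but are choices; both are isolated behind options.
* The azimuth channel is generated and analyzable on request but excluded
  from default analyses — with a nearly uniformly right-handed population
  it carries almost no between-subject variance.
* Figure rendering (entropy surfaces, boxplots) is not implemented; the
  `group_summary` table holds the numbers such plots would show.
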