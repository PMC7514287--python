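"""Sample entropy (SampEn) of raw signature channels.

SampEn(m, r) of a series u(1..N) is -ln(A/B), where B counts pairs of
length-m template vectors whose Chebyshev distance is below the tolerance,
and A counts the same for length-(m+1) templates.  It estimates the negative
log conditional probability that two subsequences that match for m points
also match for m+1 points: lower values mean a more regular, less
information-rich signal.

The tolerance is expressed relative to the standard deviation of the series
(the r/std convention), which makes the measure invariant under affine
rescaling of a channel.  Two conventions commonly differ between
implementations and are both supported:

* ``template_convention``: under ``restricted`` (Richman–Moorman, the
  default) both A and B are counted over the N-m templates that admit an
  (m+1)-point extension, which structurally guarantees A <= B and hence
  SampEn >= 0; under ``literal`` B ranges over all N-m+1 length-m templates.
* ``inequality``: ``strict`` (d < r, the default) or ``non-strict`` (d <= r).

Self-pairs are excluded and each unordered pair {i, j} is counted once; the
A/B ratio is identical to ordered counting.

The optimized counting routine builds the pairwise sample-distance matrix
once and propagates template matches along diagonals, so a full
(m, r) hyper-parameter sweep reuses one O(N^2) structure.  A deliberately
naive brute-force oracle (:func:`count_matches_bruteforce`) is kept in the
package for verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .records import SignatureRecord

DEFAULT_M_RANGE: tuple[int, ...] = tuple(range(1, 10))
DEFAULT_R_RANGE: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(1, 10))
#: Azimuth is excluded by default: with an almost entirely right-handed
#: population it carries little between-subject variance.
DEFAULT_CHANNELS: tuple[str, ...] = ("x", "y", "p", "Alt")


class SampEnError(ValueError):
    """Raised on invalid sample-entropy inputs."""


@dataclass(frozen=True)
class SEParams:
    """Hyper-parameters of one SampEn evaluation.

    ``r_rel`` is the tolerance as a multiple of the series' standard
    deviation; ``std_ddof=1`` selects the sample (N-1) estimator.
    """

    m: int
    r_rel: float
    inequality: str = "strict"
    template_convention: str = "restricted"
    std_ddof: int = 1

    def __post_init__(self) -> None:
        if self.m < 1:
            raise SampEnError("m must be >= 1")
        if self.r_rel <= 0:
            raise SampEnError("r_rel must be > 0")
        if self.inequality not in ("strict", "non-strict"):
            raise SampEnError(f"unknown inequality {self.inequality!r}")
        if self.template_convention not in ("restricted", "literal"):
            raise SampEnError(
                f"unknown template_convention {self.template_convention!r}"
            )

    def tolerance(self, series: np.ndarray) -> float:
        return float(self.r_rel * np.std(series, ddof=self.std_ddof))


@dataclass(frozen=True)
class MatchCounts:
    """Pair counts in dimensions m+1 (A) and m (B)."""

    A: int
    B: int

    def __post_init__(self) -> None:
        if self.A < 0 or self.B < 0:
            raise SampEnError("negative match count")


@dataclass(frozen=True)
class EntropyValue:
    """A SampEn result; undefined when A = 0, B = 0 or std = 0."""

    value: float | None
    defined: bool
    counts: MatchCounts

    def __post_init__(self) -> None:
        if self.defined and (self.value is None or self.value < 0):
            raise SampEnError("defined SampEn must be a nonnegative real")


@dataclass
class EntropyGrid:
    """SampEn over a (channel, m, r_rel) grid for one signature."""

    subject_id: str
    instance: int
    m_range: tuple[int, ...]
    r_range: tuple[float, ...]
    channels: tuple[str, ...]
    entries: dict[tuple[str, int, float], EntropyValue]
    n_samples: int

    def value(self, channel: str, m: int, r_rel: float) -> EntropyValue:
        return self.entries[(channel, m, round(float(r_rel), 6))]

    def validate_complete(self) -> None:
        for ch in self.channels:
            for m in self.m_range:
                for r in self.r_range:
                    if (ch, m, round(float(r), 6)) not in self.entries:
                        raise SampEnError(f"grid incomplete: missing {(ch, m, r)}")

    def to_jsonable(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "instance": self.instance,
            "m_range": list(self.m_range),
            "r_range": list(self.r_range),
            "channels": list(self.channels),
            "n_samples": self.n_samples,
            "entries": [
                {
                    "channel": ch,
                    "m": m,
                    "r": r,
                    "value": ev.value if ev.defined else None,
                    "A": ev.counts.A,
                    "B": ev.counts.B,
                }
                for (ch, m, r), ev in sorted(self.entries.items())
            ],
        }

    @classmethod
    def from_jsonable(cls, obj: Mapping) -> "EntropyGrid":
        entries = {}
        for e in obj["entries"]:
            counts = MatchCounts(int(e["A"]), int(e["B"]))
            defined = e["value"] is not None
            entries[(e["channel"], int(e["m"]), round(float(e["r"]), 6))] = EntropyValue(
                e["value"], defined, counts
            )
        return cls(
            subject_id=obj["subject_id"],
            instance=int(obj["instance"]),
            m_range=tuple(obj["m_range"]),
            r_range=tuple(round(float(r), 6) for r in obj["r_range"]),
            channels=tuple(obj["channels"]),
            entries=entries,
            n_samples=int(obj["n_samples"]),
        )


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def embed(series: Sequence[float] | np.ndarray, m: int) -> np.ndarray:
    """Return the N-m+1 overlapping template vectors X_m(i) of length m."""
    u = np.asarray(series, dtype=float)
    if m < 1:
        raise SampEnError("m must be >= 1")
    if m > u.size:
        raise SampEnError(f"m = {m} exceeds series length {u.size}")
    return np.lib.stride_tricks.sliding_window_view(u, m).copy()


def chebyshev_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Maximum absolute componentwise difference between two vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise SampEnError("length mismatch")
    return float(np.max(np.abs(a - b)))


def _pair_count(match: np.ndarray, t: int) -> int:
    """Unordered within-tolerance pairs among the first ``t`` templates of a
    symmetric boolean match matrix (diagonal assumed True-or-irrelevant)."""
    sub = match[:t, :t]
    total = int(np.count_nonzero(sub))
    diag = int(np.count_nonzero(np.diagonal(sub)))
    return (total - diag) // 2


def count_matches(
    series: Sequence[float] | np.ndarray,
    m: int,
    tolerance: float,
    inequality: str = "strict",
    template_convention: str = "restricted",
) -> MatchCounts:
    """Count template-vector pairs within tolerance in dimensions m and m+1.

    Self-pairs (i = j) are excluded and each unordered pair counted once.
    Under the ``restricted`` convention both counts range over the N-m
    templates i = 1..N-m; under ``literal`` B uses all N-m+1 templates.
    """
    u = np.asarray(series, dtype=float)
    n = u.size
    if n < m + 2:
        raise SampEnError(f"series too short: N = {n} < m + 2 = {m + 2}")
    if tolerance < 0:
        raise SampEnError("tolerance must be >= 0")
    counts = _sweep_counts(u, (m,), (tolerance,), inequality, template_convention)
    a, b = counts[(m, tolerance)]
    return MatchCounts(A=a, B=b)


def _sweep_counts(
    u: np.ndarray,
    m_values: Sequence[int],
    tolerances: Sequence[float],
    inequality: str,
    template_convention: str,
) -> dict[tuple[int, float], tuple[int, int]]:
    """(A, B) for every (m, tolerance) over one series, sharing the pairwise
    distance matrix.  Match propagation: S_{L+1}[i, j] = S_L[i, j] and
    close[i+L, j+L]."""
    if inequality not in ("strict", "non-strict"):
        raise SampEnError(f"unknown inequality {inequality!r}")
    if template_convention not in ("restricted", "literal"):
        raise SampEnError(f"unknown template_convention {template_convention!r}")
    n = u.size
    max_m = max(m_values)
    if n < max_m + 2:
        raise SampEnError(f"series too short: N = {n} < m + 2 = {max_m + 2}")
    m_set = set(m_values)
    d = np.abs(u[:, None] - u[None, :])
    out: dict[tuple[int, float], tuple[int, int]] = {}
    for tol in tolerances:
        close = d < tol if inequality == "strict" else d <= tol
        s = close  # S_1: length-1 template matches
        length = 1
        full: dict[int, int] = {}
        dropped: dict[int, int] = {}
        while length <= max_m + 1:
            t_full = n - length + 1
            if length in m_set or (length - 1) in m_set:
                full[length] = _pair_count(s, t_full)
            if length in m_set:
                dropped[length] = _pair_count(s, t_full - 1)
            if length == max_m + 1:
                break
            s = s[:-1, :-1] & close[length:, length:]
            length += 1
        for m in m_values:
            a = full[m + 1]
            b = dropped[m] if template_convention == "restricted" else full[m]
            out[(m, tol)] = (a, b)
    return out


def sample_entropy(
    series: Sequence[float] | np.ndarray,
    params: SEParams,
    tolerance: float | None = None,
) -> EntropyValue:
    """SampEn of one series under ``params``.

    ``tolerance`` overrides the r_rel * std tolerance with an absolute value
    (useful for controlled comparisons).  Undefined results (zero counts or
    a constant series) are returned as first-class values, never raised.
    """
    u = np.asarray(series, dtype=float)
    if u.size < params.m + 2:
        raise SampEnError(
            f"series too short: N = {u.size} < m + 2 = {params.m + 2}"
        )
    if tolerance is None:
        std = float(np.std(u, ddof=params.std_ddof))
        if std == 0.0:
            return EntropyValue(None, False, MatchCounts(0, 0))
        tolerance = params.r_rel * std
    if tolerance <= 0:
        return EntropyValue(None, False, MatchCounts(0, 0))
    counts = count_matches(
        u, params.m, tolerance, params.inequality, params.template_convention
    )
    if counts.A == 0 or counts.B == 0:
        return EntropyValue(None, False, counts)
    return EntropyValue(float(-np.log(counts.A / counts.B)) + 0.0, True, counts)


def max_resolvable_entropy(n: int, m: int) -> float:
    """ln((N-m)(N-m-1)/2): the largest SampEn resolvable from a length-N
    series, reached when a single template pair matches at dimension m+1.
    Used as the cap for undefined (A = 0) values downstream."""
    pairs = (n - m) * (n - m - 1) / 2
    if pairs <= 0:
        raise SampEnError("series too short for the entropy cap")
    return float(np.log(pairs))


# ---------------------------------------------------------------------------
# Grid sweep over a signature
# ---------------------------------------------------------------------------

def entropy_grid(
    signature: SignatureRecord,
    channels: Sequence[str] = DEFAULT_CHANNELS,
    m_range: Sequence[int] = DEFAULT_M_RANGE,
    r_range: Sequence[float] = DEFAULT_R_RANGE,
    inequality: str = "strict",
    template_convention: str = "restricted",
    std_ddof: int = 1,
) -> EntropyGrid:
    """SampEn of whole raw channels (pen-up samples included) over the full
    (m, r_rel) grid.  The std that scales each tolerance is computed on the
    whole series of that channel."""
    channels = tuple(channels)
    m_range = tuple(int(m) for m in m_range)
    r_range = tuple(round(float(r), 6) for r in r_range)
    if not channels or not m_range or not r_range:
        raise SampEnError("channels, m_range and r_range must be non-empty")
    for ch in channels:
        if ch not in signature.channels:
            raise SampEnError(f"channel {ch!r} absent from signature")
    if any(r <= 0 for r in r_range):
        raise SampEnError("r_rel values must be > 0")
    n = signature.n_samples
    if n < max(m_range) + 2:
        raise SampEnError("signature too short for the requested m_range")

    entries: dict[tuple[str, int, float], EntropyValue] = {}
    for ch in channels:
        u = signature.channel(ch)
        std = float(np.std(u, ddof=std_ddof))
        if std == 0.0:
            for m in m_range:
                for r in r_range:
                    entries[(ch, m, r)] = EntropyValue(None, False, MatchCounts(0, 0))
            continue
        tolerances = [r * std for r in r_range]
        counts = _sweep_counts(u, m_range, tolerances, inequality, template_convention)
        for m in m_range:
            for r, tol in zip(r_range, tolerances):
                a, b = counts[(m, tol)]
                mc = MatchCounts(a, b)
                if a == 0 or b == 0:
                    entries[(ch, m, r)] = EntropyValue(None, False, mc)
                else:
                    entries[(ch, m, r)] = EntropyValue(
                        float(-np.log(a / b)) + 0.0, True, mc
                    )
    grid = EntropyGrid(
        subject_id=signature.subject_id,
        instance=signature.instance,
        m_range=m_range,
        r_range=r_range,
        channels=channels,
        entries=entries,
        n_samples=n,
    )
    grid.validate_complete()
    return grid


# ---------------------------------------------------------------------------
# Brute-force reference oracle
# ---------------------------------------------------------------------------

def count_matches_bruteforce(
    series: Sequence[float] | np.ndarray,
    m: int,
    tolerance: float,
    inequality: str = "strict",
    template_convention: str = "restricted",
) -> MatchCounts:
    """O(N^2) double-loop reference for :func:`count_matches`.

    Deliberately naive: explicit embedding, explicit pairwise Chebyshev
    distances, explicit pair loops.  Kept for verification; do not use on
    long series.
    """
    u = np.asarray(series, dtype=float)
    n = u.size
    if n < m + 2:
        raise SampEnError("series too short")
    if tolerance < 0:
        raise SampEnError("tolerance must be >= 0")

    def pairs(vectors: np.ndarray) -> int:
        count = 0
        for i in range(len(vectors)):
            for j in range(i + 1, len(vectors)):
                dist = chebyshev_distance(vectors[i], vectors[j])
                hit = dist < tolerance if inequality == "strict" else dist <= tolerance
                if hit:
                    count += 1
        return count

    templates_m = embed(u, m)
    templates_m1 = embed(u, m + 1)
    if template_convention == "restricted":
        b = pairs(templates_m[: n - m])
    else:
        b = pairs(templates_m)
    a = pairs(templates_m1)
    return MatchCounts(A=a, B=b)


def sample_entropy_bruteforce(
    series: Sequence[float] | np.ndarray,
    params: SEParams,
    tolerance: float | None = None,
) -> EntropyValue:
    """Brute-force counterpart of :func:`sample_entropy`."""
    u = np.asarray(series, dtype=float)
    if tolerance is None:
        std = float(np.std(u, ddof=params.std_ddof))
        if std == 0.0:
            return EntropyValue(None, False, MatchCounts(0, 0))
        tolerance = params.r_rel * std
    if tolerance <= 0:
        return EntropyValue(None, False, MatchCounts(0, 0))
    counts = count_matches_bruteforce(
        u, params.m, tolerance, params.inequality, params.template_convention
    )
    if counts.A == 0 or counts.B == 0:
        return EntropyValue(None, False, counts)
    return EntropyValue(float(-np.log(counts.A / counts.B)) + 0.0, True, counts)
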