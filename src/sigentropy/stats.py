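"""Person-level entropy aggregation and cohort statistics.

Builds the per-subject table (SampEn of both signatures plus their average,
per channel, joined with metadata), then runs the analyses that sit on top
of it: correlations of entropy with MMSE and age, k-means clustering of
subjects in the (SE(x), SE(y)) plane to probe signature-style effects,
per-cell group summaries over the (m, r) grid, the between-group relative
entropy increase, and the Mann-Whitney rank test of AD vs HC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans

from .records import Cohort
from .sampen import EntropyGrid

logger = logging.getLogger(__name__)

GridMap = Mapping[tuple[str, int], EntropyGrid]


@dataclass(frozen=True)
class Selector:
    """How to reduce an entropy grid to one number per (signature, channel).

    ``fixed``: the single cell (m, r_rel).  ``grid_average``: the mean of all
    defined cells over the declared ranges (one coefficient per channel even
    though SampEn was swept over the whole hyper-parameter grid).
    """

    mode: str = "fixed"
    m: int | None = 3
    r_rel: float | None = 0.1
    m_range: tuple[int, ...] | None = None
    r_range: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "grid_average"):
            raise ValueError(f"unknown selector mode {self.mode!r}")
        if self.mode == "fixed" and (self.m is None or self.r_rel is None):
            raise ValueError("fixed selector needs m and r_rel")

    def reduce(self, grid: EntropyGrid, channel: str) -> float:
        """Value for one signature-channel; NaN when undefined."""
        if self.mode == "fixed":
            if self.m not in grid.m_range or round(float(self.r_rel), 6) not in [
                round(r, 6) for r in grid.r_range
            ]:
                raise ValueError(
                    f"selector cell ({self.m}, {self.r_rel}) outside computed ranges"
                )
            ev = grid.value(channel, self.m, self.r_rel)
            return ev.value if ev.defined else float("nan")
        m_range = self.m_range or grid.m_range
        r_range = self.r_range or grid.r_range
        vals = []
        for m in m_range:
            for r in r_range:
                ev = grid.value(channel, m, r)
                if ev.defined:
                    vals.append(ev.value)
        return float(np.mean(vals)) if vals else float("nan")

    def label(self) -> str:
        if self.mode == "fixed":
            return f"fixed(m={self.m}, r={self.r_rel})"
        return "grid_average"


@dataclass(frozen=True)
class TestResult:
    """Mann-Whitney comparison of per-person SampEn between groups."""

    channel: str
    statistic: float
    p_value: float
    alternative: str
    n_ad: int
    n_hc: int

    def __post_init__(self) -> None:
        if not 0 <= self.statistic <= self.n_ad * self.n_hc:
            raise ValueError("U outside [0, n_ad * n_hc]")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class StyleClusterResult:
    assignments: pd.Series  # subject_id -> cluster label (0 = highest SE(x))
    centroids: np.ndarray  # (k, 2), ordered by decreasing SE of first channel
    crosstab: pd.DataFrame  # cluster x style counts
    inertia: float


def build_cohort_table(
    cohort: Cohort,
    grids: GridMap,
    selector: Selector = Selector(),
    channels: Sequence[str] = ("x", "y", "p", "Alt"),
) -> pd.DataFrame:
    """One row per subject: metadata plus per-channel SampEn of each
    signature and their person-average.

    The person-average is the mean of the two defined values, the single
    defined value if only one is defined, and NaN if neither is.  Undefined
    entries are logged, never imputed.
    """
    rows = []
    n_undefined = 0
    for subj in cohort.subjects:
        row: dict = {
            "subject_id": subj.subject_id,
            "group": subj.group,
            "age": subj.age,
            "sex": subj.sex,
            "mmse": subj.mmse,
            "style": subj.style,
        }
        for inst in (1, 2):
            key = (subj.subject_id, inst)
            if key not in grids:
                raise KeyError(f"missing entropy grid for {key}")
            row[f"n_samples_{inst}"] = grids[key].n_samples
        for ch in channels:
            se = {}
            for inst in (1, 2):
                val = selector.reduce(grids[(subj.subject_id, inst)], ch)
                se[inst] = val
                if np.isnan(val):
                    n_undefined += 1
                    logger.warning(
                        "undefined SampEn: subject %s instance %d channel %s",
                        subj.subject_id,
                        inst,
                        ch,
                    )
            row[f"SE1_{ch}"] = se[1]
            row[f"SE2_{ch}"] = se[2]
            defined = [v for v in (se[1], se[2]) if not np.isnan(v)]
            row[f"SE_{ch}"] = float(np.mean(defined)) if defined else float("nan")
        rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["selector"] = selector.label()
    table.attrs["undefined_policy"] = "NaN, excluded pairwise downstream"
    table.attrs["n_undefined"] = n_undefined
    return table


def correlate_metadata(
    table: pd.DataFrame,
    channel: str,
    covariate: str,
    method: str = "pearson",
) -> float:
    """Correlation between person-average SampEn of ``channel`` and a
    metadata covariate, across all subjects regardless of group."""
    if covariate not in ("mmse", "age"):
        raise ValueError(f"covariate must be mmse or age, got {covariate!r}")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    se = table[f"SE_{channel}"]
    cov = table[covariate].astype(float)
    mask = se.notna() & cov.notna()
    if mask.sum() < 3:
        raise ValueError("need at least 3 subjects with defined values")
    x, y = se[mask].to_numpy(), cov[mask].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    if method == "pearson":
        return float(sps.pearsonr(x, y).statistic)
    return float(sps.spearmanr(x, y).statistic)


def style_cluster(
    table: pd.DataFrame,
    k: int = 3,
    channel_pair: tuple[str, str] = ("x", "y"),
    seed: int = 0,
) -> StyleClusterResult:
    """k-means in the 2-D (SE(x), SE(y)) person-average plane.

    Clusters are relabeled in decreasing order of the first channel's
    centroid, so cluster 0 is the highest-entropy group.  Returns the
    cluster-by-style cross-tabulation used to judge whether signature style
    confounds the entropy measure.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    cols = [f"SE_{channel_pair[0]}", f"SE_{channel_pair[1]}"]
    data = table[["subject_id", "style"] + cols].dropna(subset=cols)
    points = data[cols].to_numpy()
    if len(np.unique(points, axis=0)) < k:
        raise ValueError("fewer distinct points than clusters")
    km = KMeans(
        n_clusters=k,
        n_init=10,
        init="k-means++",
        max_iter=300,
        tol=1e-6,
        random_state=seed,
    ).fit(points)
    order = np.argsort(-km.cluster_centers_[:, 0])  # decreasing SE(x)
    relabel = {int(old): int(new) for new, old in enumerate(order)}
    labels = np.array([relabel[int(l)] for l in km.labels_])
    centroids = km.cluster_centers_[order]
    assignments = pd.Series(labels, index=data["subject_id"].to_numpy(), name="cluster")
    crosstab = pd.crosstab(
        pd.Series(labels, name="cluster"), data["style"].reset_index(drop=True)
    )
    return StyleClusterResult(
        assignments=assignments,
        centroids=centroids,
        crosstab=crosstab,
        inertia=float(km.inertia_),
    )


def mann_whitney_test(
    table: pd.DataFrame, channel: str, method: str = "asymptotic"
) -> TestResult:
    """Two-sided Mann-Whitney U test of person-average SampEn, AD vs HC.

    ``asymptotic`` uses the normal approximation with tie correction;
    ``exact`` enumerates (feasible for small groups, no ties).
    """
    se = table[f"SE_{channel}"]
    ad = se[(table["group"] == "AD") & se.notna()].to_numpy()
    hc = se[(table["group"] == "HC") & se.notna()].to_numpy()
    if ad.size == 0 or hc.size == 0:
        raise ValueError(f"a group has no defined values for channel {channel}")
    res = sps.mannwhitneyu(ad, hc, alternative="two-sided", method=method)
    return TestResult(
        channel=channel,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alternative="two-sided",
        n_ad=int(ad.size),
        n_hc=int(hc.size),
    )


def relative_increase(table: pd.DataFrame, channel: str) -> float:
    """Relative increase (percent) of the HC group-mean SampEn over AD:
    100 * (mean_HC - mean_AD) / mean_AD."""
    se = table[f"SE_{channel}"]
    mean_ad = se[table["group"] == "AD"].mean(skipna=True)
    mean_hc = se[table["group"] == "HC"].mean(skipna=True)
    if np.isnan(mean_ad) or np.isnan(mean_hc):
        raise ValueError("a group mean is undefined")
    if mean_ad <= 0:
        raise ValueError("AD group mean must be > 0")
    return float(100.0 * (mean_hc - mean_ad) / mean_ad)


def group_summary(
    grids: GridMap,
    cohort: Cohort,
    channels: Sequence[str] = ("x", "y", "p", "Alt"),
    m_range: Sequence[int] | None = None,
    r_range: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Per (channel, m, r_rel) group statistics of per-person average SampEn:
    mean, median, quartiles, and the count of subjects with no defined value
    (the numbers behind entropy surfaces and boxplots)."""
    any_grid = next(iter(grids.values()))
    m_range = tuple(m_range or any_grid.m_range)
    r_range = tuple(round(float(r), 6) for r in (r_range or any_grid.r_range))
    rows = []
    for ch in channels:
        for m in m_range:
            for r in r_range:
                per_group: dict[str, list[float]] = {"AD": [], "HC": []}
                undef = {"AD": 0, "HC": 0}
                for subj in cohort.subjects:
                    vals = []
                    for inst in (1, 2):
                        ev = grids[(subj.subject_id, inst)].value(ch, m, r)
                        if ev.defined:
                            vals.append(ev.value)
                    if vals:
                        per_group[subj.group].append(float(np.mean(vals)))
                    else:
                        undef[subj.group] += 1
                for grp in ("AD", "HC"):
                    v = np.asarray(per_group[grp])
                    rows.append(
                        {
                            "channel": ch,
                            "m": m,
                            "r": r,
                            "group": grp,
                            "n": v.size,
                            "n_undefined": undef[grp],
                            "mean": float(np.mean(v)) if v.size else float("nan"),
                            "median": float(np.median(v)) if v.size else float("nan"),
                            "q1": float(np.percentile(v, 25)) if v.size else float("nan"),
                            "q3": float(np.percentile(v, 75)) if v.size else float("nan"),
                        }
                    )
    return pd.DataFrame(rows)


def compute_grid_map(
    cohort: Cohort,
    channels: Sequence[str] = ("x", "y", "p", "Alt"),
    m_range: Sequence[int] | None = None,
    r_range: Sequence[float] | None = None,
) -> dict[tuple[str, int], EntropyGrid]:
    """Entropy grids for every signature of a cohort, keyed by
    (subject_id, instance)."""
    from .sampen import DEFAULT_M_RANGE, DEFAULT_R_RANGE, entropy_grid

    m_range = tuple(m_range or DEFAULT_M_RANGE)
    r_range = tuple(r_range or DEFAULT_R_RANGE)
    out = {}
    for sig in cohort.signatures:
        out[(sig.subject_id, sig.instance)] = entropy_grid(
            sig, channels=channels, m_range=m_range, r_range=r_range
        )
    return out
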