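"""Trajectory metrics and statistical comparisons.

Implements the per-trajectory quantities used to compare search strategies —
path length, mean horizontal deviation from the start-source axis, track-angle
histograms, turn counts — and the group-level statistics: success-rate
summaries, two-way ANOVA, pairwise Wilcoxon rank-sum comparisons with the
usual star convention, and notched box-plot summaries.

Track angles are movement directions relative to upwind (0 deg = straight
upwind, +/-90 deg = crosswind, 180 deg = downwind).  By default they are
computed on segments resampled to equal arc length (2 cm) so histograms do
not depend on the simulation tick.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "path_length",
    "delta_x",
    "resample_path",
    "track_angles",
    "track_angle_histogram",
    "count_turns",
    "metric_table",
    "success_rate_summary",
    "SuccessRateSummary",
    "compare_groups",
    "GroupComparison",
    "box_summary",
    "BoxSummary",
    "stars",
]

STIMULATED_DOSES = ("minimum", "medium", "maximum")


def _positions(traj) -> np.ndarray:
    """Accept a Trajectory, a DataFrame with x/y columns, or an (n, 2) array."""
    if hasattr(traj, "positions"):
        return traj.positions()
    if isinstance(traj, pd.DataFrame):
        return traj[["x", "y"]].to_numpy(dtype=float)
    return np.asarray(traj, dtype=float).reshape(-1, 2)


def path_length(traj) -> float:
    """Total Euclidean length of the sampled path, m."""
    pos = _positions(traj)
    if len(pos) < 2:
        raise ValueError("path_length needs at least 2 samples")
    return float(np.hypot(*np.diff(pos, axis=0).T).sum())


def delta_x(traj) -> float:
    """Mean absolute horizontal deviation from the x=0 start-source axis, m."""
    pos = _positions(traj)
    if len(pos) < 1:
        raise ValueError("delta_x needs at least 1 sample")
    return float(np.abs(pos[:, 0]).mean())


def resample_path(traj, ds: float = 0.02) -> np.ndarray:
    """Resample a path at equal arc-length intervals ``ds`` (m).

    Points are linearly interpolated along the polyline; duplicate samples
    (zero-length segments, e.g. infotaxis 'stay') are dropped first.
    """
    pos = _positions(traj)
    seg = np.hypot(*np.diff(pos, axis=0).T)
    keep = np.concatenate([[True], seg > 0])
    pos = pos[keep]
    if len(pos) < 2:
        return pos
    seg = np.hypot(*np.diff(pos, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    grid = np.arange(0.0, s[-1] + ds * 1e-9, ds)
    return np.column_stack([np.interp(grid, s, pos[:, 0]),
                            np.interp(grid, s, pos[:, 1])])


def track_angles(traj, ds: float | None = 0.02) -> np.ndarray:
    """Per-segment movement directions in degrees relative to upwind (+y).

    ``ds`` selects equal-arc-length resampling (default 2 cm); ``ds=None``
    uses the raw samples.  Zero-length segments are skipped.
    """
    pos = resample_path(traj, ds) if ds else _positions(traj)
    if len(pos) < 2:
        raise ValueError("track_angles needs at least 2 samples")
    d = np.diff(pos, axis=0)
    length = np.hypot(d[:, 0], d[:, 1])
    d = d[length > 0]
    if len(d) == 0:
        return np.empty(0)
    return np.degrees(np.arctan2(d[:, 0], d[:, 1]))


#: Histogram bin edges: 10-degree bins centered on multiples of 10 so the
#: upwind (0), crosswind (+/-60, +/-90) and downwind (180) directions fall in
#: the middle of a bin.
TRACK_ANGLE_EDGES = np.arange(-175.0, 186.0, 10.0)
TRACK_ANGLE_CENTERS = (TRACK_ANGLE_EDGES[:-1] + TRACK_ANGLE_EDGES[1:]) / 2


def track_angle_histogram(traj, bin_deg: float = 10.0,
                          ds: float | None = 0.02):
    """Track-angle histogram in percent.

    Returns ``(centers, pct)`` where ``pct`` sums to 100.  Bins are
    ``bin_deg`` wide and centered on multiples of ``bin_deg`` over
    (-180, 180], with angles wrapped accordingly.
    """
    a = np.atleast_1d(track_angles(traj, ds))
    if a.size == 0:
        raise ValueError("no non-degenerate segments")
    half = bin_deg / 2
    edges = np.arange(-180.0 + half, 180.0 + half + bin_deg * 1e-9, bin_deg)
    wrapped = ((a - edges[0]) % 360.0) + edges[0]
    counts, _ = np.histogram(wrapped, bins=edges)
    return (edges[:-1] + edges[1:]) / 2, 100.0 * counts / counts.sum()


def count_turns(traj, threshold_deg: float = 55.0, mode: str = "track",
                ds: float | None = 0.02) -> int:
    """Number of turns in a trajectory.

    ``mode='track'`` (default, the literal reading of the assay's counting
    rule) counts segments whose |track angle| exceeds ``threshold_deg``;
    ``mode='event'`` counts heading *changes* between consecutive segments
    exceeding the threshold.  The track mode depends on the segment length,
    hence the equal-arc-length resampling default.
    """
    a = track_angles(traj, ds)
    if mode == "track":
        return int(np.count_nonzero(np.abs(a) > threshold_deg))
    if mode == "event":
        d = np.diff(a)
        d = (d + 180.0) % 360.0 - 180.0
        return int(np.count_nonzero(np.abs(d) > threshold_deg))
    raise ValueError("mode must be 'track' or 'event'")


def metric_table(trajectories) -> pd.DataFrame:
    """Per-trajectory metric rows for a collection of trials."""
    rows = []
    for traj in trajectories:
        rows.append({
            "strategy": traj.strategy,
            "dose": traj.dose,
            "seed": traj.seed,
            "outcome": traj.outcome,
            "path_length": path_length(traj),
            "delta_x": delta_x(traj),
            "n_turns": count_turns(traj),
            "n_detections": traj.n_detections,
        })
    return pd.DataFrame(rows)


@dataclass
class SuccessRateSummary:
    """Success-rate percentages per strategy x dose plus marginal averages.

    Marginals are arithmetic means of the per-dose percentages (not pooled
    counts) — the convention that reproduces the printed aggregate rates from
    the per-cell counts — rounded to the nearest integer for reporting.
    """

    pct: pd.DataFrame                       # dose rows x strategy columns
    dose_means: dict[str, int]              # across strategies, stimulated doses
    strategy_means: dict[str, int]          # across stimulated doses
    strategy_means_all: dict[str, int]      # across all doses incl. 'none'


def success_rate_summary(counts: pd.DataFrame,
                         aggregate: str = "mean_of_percentages") -> SuccessRateSummary:
    """Summarize a tidy table of trial counts.

    ``counts`` needs columns strategy, dose, successes, totals with totals > 0.
    ``aggregate`` may be 'mean_of_percentages' (default) or 'pooled'
    (aggregate = 100 * sum(S) / sum(T)).
    """
    required = {"strategy", "dose", "successes", "totals"}
    if not required <= set(counts.columns):
        raise ValueError(f"counts table needs columns {sorted(required)}")
    if (counts["totals"] <= 0).any():
        raise ValueError("all totals must be positive")
    df = counts.copy()
    df["pct"] = 100.0 * df["successes"] / df["totals"]
    pct = df.pivot(index="dose", columns="strategy", values="pct")

    def agg(sub: pd.DataFrame) -> float:
        if aggregate == "pooled":
            return 100.0 * sub["successes"].sum() / sub["totals"].sum()
        return float(sub["pct"].mean())

    stim = df[df["dose"].isin(STIMULATED_DOSES)]
    dose_means = {
        d: round(agg(df[df["dose"] == d])) for d in STIMULATED_DOSES
        if (df["dose"] == d).any()
    }
    strategy_means = {
        s: round(agg(stim[stim["strategy"] == s]))
        for s in df["strategy"].unique()
    }
    strategy_means_all = {
        s: round(agg(df[df["strategy"] == s])) for s in df["strategy"].unique()
    }
    return SuccessRateSummary(pct, dose_means, strategy_means, strategy_means_all)


def stars(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05, '' otherwise."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class GroupComparison:
    anova: pd.DataFrame
    pairwise: pd.DataFrame
    flagged: list[str] = dataclass_field(default_factory=list)


def _pairwise_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    if len(df):
        from statsmodels.stats.multitest import multipletests

        df["p_holm"] = multipletests(df["p"], method="holm")[1]
        df["stars"] = df["p"].map(stars)
    return df


def compare_groups(table: pd.DataFrame, metric: str = "path_length",
                   min_n: int = 3) -> GroupComparison:
    """Two-way ANOVA (strategy, dose, interaction) on ``metric`` plus pairwise
    Wilcoxon rank-sum tests: all strategy pairs per dose and all dose pairs
    per strategy.

    P-values are reported unadjusted (with the star convention) plus a
    Holm-adjusted column.  Groups with fewer than ``min_n`` observations are
    skipped and flagged.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = table.rename(columns={metric: "value"})[["strategy", "dose", "value"]].copy()
    if df["strategy"].nunique() < 2:
        raise ValueError("need at least two strategy groups")

    formula = "value ~ C(strategy)"
    if df["dose"].nunique() >= 2:
        formula += " * C(dose)"
    model = ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    flagged: list[str] = []

    def group(strategy=None, dose=None):
        sub = df
        if strategy is not None:
            sub = sub[sub["strategy"] == strategy]
        if dose is not None:
            sub = sub[sub["dose"] == dose]
        return sub["value"].to_numpy()

    rows: list[dict] = []
    doses = list(df["dose"].unique())
    strategies = list(df["strategy"].unique())
    for dose in doses:
        for s1, s2 in itertools.combinations(strategies, 2):
            a, b = group(s1, dose), group(s2, dose)
            if len(a) < min_n or len(b) < min_n:
                flagged.append(f"{s1} vs {s2} at dose {dose}: too few observations")
                continue
            p = sps.mannwhitneyu(a, b, alternative="two-sided").pvalue
            rows.append({"kind": "strategy", "fixed": dose,
                         "group1": s1, "group2": s2, "p": float(p)})
    for strategy in strategies:
        for d1, d2 in itertools.combinations(doses, 2):
            a, b = group(strategy, d1), group(strategy, d2)
            if len(a) < min_n or len(b) < min_n:
                flagged.append(
                    f"{d1} vs {d2} for strategy {strategy}: too few observations"
                )
                continue
            p = sps.mannwhitneyu(a, b, alternative="two-sided").pvalue
            rows.append({"kind": "dose", "fixed": strategy,
                         "group1": d1, "group2": d2, "p": float(p)})
    return GroupComparison(anova=anova, pairwise=_pairwise_frame(rows),
                           flagged=flagged)


@dataclass
class BoxSummary:
    """Notched box-plot numbers: median, quartiles, 95% CI of the median
    (median +/- 1.58 IQR / sqrt(n)) and outliers beyond 2.5 IQR from the
    quartiles."""

    median: float
    q1: float
    q3: float
    notch_low: float
    notch_high: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray
    n: int


def box_summary(values) -> BoxSummary:
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("box_summary needs at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    notch = 1.58 * iqr / math.sqrt(v.size)
    lo, hi = q1 - 2.5 * iqr, q3 + 2.5 * iqr
    outliers = v[(v < lo) | (v > hi)]
    inliers = v[(v >= lo) & (v <= hi)]
    return BoxSummary(
        median=float(med), q1=float(q1), q3=float(q3),
        notch_low=float(med - notch), notch_high=float(med + notch),
        whisker_low=float(inliers.min()), whisker_high=float(inliers.max()),
        outliers=outliers, n=int(v.size),
    )
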