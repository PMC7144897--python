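"""Condition-level summaries and response surfaces of a screen.

Raw per-well read counts are first normalized within their PCR index group
(every zone is amplified in one indexed PCR, so yields are only comparable
within a group); quadruplicates are summarized by their median and a
normalized mean absolute difference; medians are arranged on the TSO×RTP
grid per (enzyme, RNA mass) for contour display; and two-objective
condition sets can be reduced to their Pareto-efficient front.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConditionSummary",
    "SurfaceGrid",
    "relative_yields",
    "replicate_summary",
    "summarize_conditions",
    "build_surface",
    "pareto_front",
]


def relative_yields(counts: pd.Series, groups: pd.Series) -> pd.Series:
    """Per-well read counts divided by the mean count of the well's PCR
    index group.  Scale-invariant within each group; group means of the
    result are exactly 1."""
    counts = counts.astype(float)
    if not counts.index.equals(groups.index):
        groups = groups.reindex(counts.index)
    if groups.isna().any():
        raise ValueError("every well must belong to exactly one index group")
    return counts / counts.groupby(groups).transform("mean")


@dataclass
class ConditionSummary:
    median: float
    normalized_mad: float
    n_replicates: int
    n_missing: int = 0


def replicate_summary(values, method: str = "median_dev") -> ConditionSummary:
    """Median and normalized MAD of a replicate set (missing values dropped).

    The normalized mean average difference is mean(|x_i − median|) / mean(x)
    (``method="median_dev"``); ``method="pairwise"`` instead averages all
    pairwise absolute differences before dividing by the mean.
    """
    arr = np.asarray([v for v in values if v is not None and not np.isnan(v)], dtype=float)
    n_missing = len(list(values)) - arr.size
    if arr.size < 2:
        raise ValueError("need at least 2 non-missing replicate values")
    med = float(np.median(arr))
    mean = float(arr.mean())
    if method == "median_dev":
        mad = float(np.mean(np.abs(arr - med)))
    elif method == "pairwise":
        diffs = np.abs(arr[:, None] - arr[None, :])
        mad = float(diffs[np.triu_indices(arr.size, k=1)].mean())
    else:
        raise ValueError(f"unknown method {method!r}")
    return ConditionSummary(
        median=med,
        normalized_mad=mad / mean if mean != 0 else np.nan,
        n_replicates=arr.size,
        n_missing=n_missing,
    )


def summarize_conditions(
    df: pd.DataFrame,
    metric: str,
    by: tuple[str, ...] = ("enzyme", "rna_pg", "tso_uM", "rtp_uM"),
    method: str = "median_dev",
    min_replicates: int = 1,
) -> pd.DataFrame:
    """Replicate summary of ``metric`` for every condition in a tidy
    per-well table (one row per well and replicate).  Conditions observed
    only once keep their value as the median with an undefined MAD."""
    rows = []
    for key, grp in df.groupby(list(by), dropna=False):
        vals = grp[metric].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size < max(1, min_replicates):
            continue
        if vals.size >= 2:
            s = replicate_summary(vals, method=method)
            med, mad, n = s.median, s.normalized_mad, s.n_replicates
        else:
            med, mad, n = float(vals[0]), np.nan, 1
        rows.append(dict(zip(by, key)) | {
            "metric": metric, "median": med, "normalized_mad": mad, "n_replicates": n,
        })
    cols = list(by) + ["metric", "median", "normalized_mad", "n_replicates"]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class SurfaceGrid:
    enzyme: str
    rna_mass: float
    metric: str
    tso_levels: list[float]
    rtp_levels: list[float]
    matrix: np.ndarray  # shape (len(tso_levels), len(rtp_levels)), NaN = missing

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.tso_levels, columns=self.rtp_levels)

    def plot(self, path=None, ax=None, cmap: str = "RdYlBu"):
        """Contour rendering on log-scaled molarity axes (presentation
        layer; values are not interpolated for any numeric output)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        X, Y = np.meshgrid(self.rtp_levels, self.tso_levels)
        m = np.ma.masked_invalid(self.matrix)
        cs = ax.contourf(X, Y, m, levels=12, cmap=cmap)
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("RTP (uM)")
        ax.set_ylabel("TSO (uM)")
        ax.set_title(f"{self.metric} — {self.enzyme}, {self.rna_mass:g} pg")
        ax.figure.colorbar(cs, ax=ax)
        if path is not None:
            ax.figure.savefig(path, bbox_inches="tight")
            plt.close(ax.figure)
        return ax


def build_surface(
    summaries: pd.DataFrame,
    metric: str,
    enzyme: str,
    rna_pg: float,
    tso_levels=None,
    rtp_levels=None,
) -> SurfaceGrid:
    """Median-value matrix over the TSO×RTP grid for one (enzyme, RNA mass).

    ``summaries`` is the output of :func:`summarize_conditions`; cells
    without a summary stay NaN.
    """
    sel = summaries[
        (summaries["enzyme"] == enzyme)
        & (summaries["rna_pg"] == rna_pg)
        & (summaries["metric"] == metric)
    ]
    if tso_levels is None:
        tso_levels = sorted(sel["tso_uM"].dropna().unique())
    if rtp_levels is None:
        rtp_levels = sorted(sel["rtp_uM"].dropna().unique())
    mat = np.full((len(tso_levels), len(rtp_levels)), np.nan)
    t_ix = {v: i for i, v in enumerate(tso_levels)}
    r_ix = {v: i for i, v in enumerate(rtp_levels)}
    for _, row in sel.iterrows():
        t, r = row["tso_uM"], row["rtp_uM"]
        if t in t_ix and r in r_ix:
            mat[t_ix[t], r_ix[r]] = row["median"]
    return SurfaceGrid(enzyme, rna_pg, metric, list(tso_levels), list(rtp_levels), mat)


def pareto_front(
    points,
    minimize: tuple[bool, bool] = (True, False),
) -> list:
    """Non-dominated subset of 2-D scored points.

    ``points`` iterates (score_a, score_b) pairs or objects indexable by 0/1;
    ``minimize`` flags per dimension (False = maximize).  A point is
    dominated when another is at least as good on both scores and strictly
    better on one.  Returned in increasing order of the first score.
    """
    pts = list(points)
    if not pts:
        return []
    sign = np.array([1.0 if m else -1.0 for m in minimize])
    arr = np.array([[p[0], p[1]] for p in pts], dtype=float) * sign  # both minimized

    # sort-and-sweep: ascending in the first score, a group of equal first
    # scores survives iff its best second score beats everything seen at a
    # strictly smaller first score; within a group only the best-second
    # points survive (duplicates are mutually non-dominating and all kept)
    order = sorted(range(len(pts)), key=lambda i: (arr[i, 0], arr[i, 1]))
    keep: list[int] = []
    best_b = np.inf
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and arr[order[j], 0] == arr[order[i], 0]:
            j += 1
        group = order[i:j]
        bmin = min(arr[g, 1] for g in group)
        if bmin < best_b:
            keep.extend(g for g in group if arr[g, 1] == bmin)
            best_b = bmin
        i = j
    keep.sort(key=lambda i: (pts[i][0], pts[i][1]))
    return [pts[i] for i in keep]
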