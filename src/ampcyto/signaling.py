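"""BP-R2 signaling-relationship scoring, network construction and trajectory stats.

BP-R2 (binned pseudo-R2) measures the strength of a pairwise signaling
relationship: events are binned into equal-frequency bins of marker x, a
piecewise-constant predictor (the bin mean of marker y) is fitted, and the
score is the fraction of y's variance it explains, clipped to [0, 1].
Scored per timepoint over a stimulation timecourse and summed (or averaged)
per marker pair, it feeds a thresholded undirected network: the canonical
cutoff is a cumulative score of 6.2 over eight stimulation timepoints,
equivalently a mean of 0.775.

Also here: per-timepoint coefficient-of-variation and min-max-normalized
mean trajectories, and the signed-pseudotime rule that places two
consecutive phase transitions on one axis by negating cells of a
designated phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, permutations

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .events import EventTable

__all__ = [
    "Bpr2Result",
    "SignalingNetwork",
    "Bpr2Network",
    "bp_r2",
    "score_timecourse",
    "build_network",
    "trajectory_stats",
    "sign_pseudotime",
]


def bp_r2(x, y, n_bins: int = 10, min_bin_count: int = 20) -> float:
    """Binned pseudo-R2 of y against x, in [0, 1].

    Events are ranked into ``n_bins`` equal-frequency bins of x (ties
    broken by stable event order, so scores are deterministic); bins with
    fewer than ``min_bin_count`` events are dropped; the piecewise-constant
    predictor is the bin mean of y, and the score is
    ``max(0, 1 - SS_res / SS_tot)`` over the retained events.

    Invariant under strictly monotone transforms of x and affine
    transforms of y.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < n_bins * min_bin_count:
        raise ValueError(
            f"need at least n_bins*min_bin_count = {n_bins * min_bin_count} events, got {x.size}"
        )
    order = np.argsort(x, kind="stable")
    kept_idx = []
    for chunk in np.array_split(order, n_bins):
        if chunk.size >= min_bin_count:
            kept_idx.append(chunk)
    if not kept_idx:
        raise ValueError("all bins below min_bin_count")
    kept = np.concatenate(kept_idx)
    y_kept = y[kept]
    ss_tot = np.sum((y_kept - y_kept.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("y is constant over retained events: score undefined")
    ss_res = 0.0
    for chunk in kept_idx:
        yb = y[chunk]
        ss_res += np.sum((yb - yb.mean()) ** 2)
    return float(max(0.0, 1.0 - ss_res / ss_tot))


@dataclass
class Bpr2Result:
    """Per ordered pair x timepoint BP-R2 scores with pair summaries."""

    scores: pd.DataFrame  # columns: marker_x, marker_y, timepoint_min, score
    summary: pd.DataFrame  # columns: marker_x, marker_y, cumulative_sum, mean
    n_bins: int
    min_bin_count: int
    timepoints: tuple[float, ...]


@dataclass
class SignalingNetwork:
    """Thresholded undirected marker network."""

    graph: nx.Graph
    rule: str
    threshold: float

    @property
    def edges(self) -> list[tuple]:
        return sorted(
            (min(a, b), max(a, b), d["strength"]) for a, b, d in self.graph.edges(data=True)
        )

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def score_timecourse(
    table: EventTable,
    markers: list[str],
    timepoints: list[float] | None = None,
    n_bins: int = 10,
    min_bin_count: int = 20,
    transformed: bool = True,
    cofactor: float = 5.0,
) -> Bpr2Result:
    """BP-R2 per ordered marker pair per timepoint, plus cumulative and mean.

    Scores are computed on transformed values by default.  All requested
    timepoints must be present; a missing one raises a named error.
    """
    tp_meta = table.require_meta("timepoint_min").to_numpy(dtype=float)
    present = np.unique(tp_meta)
    if timepoints is None:
        timepoints = sorted(present)
    missing = [t for t in timepoints if t not in present]
    if missing:
        raise ValueError(f"timepoint(s) {missing} absent from the table")
    values = {m: table.channel(m) for m in markers}
    if transformed:
        values = {m: np.arcsinh(v / cofactor) for m, v in values.items()}
    rows = []
    for t in timepoints:
        sel = tp_meta == t
        for mx, my in permutations(markers, 2):
            rows.append(
                {
                    "marker_x": mx,
                    "marker_y": my,
                    "timepoint_min": float(t),
                    "score": bp_r2(values[mx][sel], values[my][sel], n_bins, min_bin_count),
                }
            )
    scores = pd.DataFrame(rows)
    summary = (
        scores.groupby(["marker_x", "marker_y"], sort=False)["score"]
        .agg(cumulative_sum="sum", mean="mean")
        .reset_index()
    )
    return Bpr2Result(
        scores=scores,
        summary=summary,
        n_bins=n_bins,
        min_bin_count=min_bin_count,
        timepoints=tuple(float(t) for t in timepoints),
    )


def build_network(
    result: Bpr2Result, rule: str = "mean", threshold: float = 0.775
) -> SignalingNetwork:
    """Undirected network of pairs whose score summary meets the threshold.

    For each unordered pair the strength is the maximum of the two ordered
    summaries under the chosen rule (``mean`` or ``sum``); an edge is added
    when strength >= threshold.  With T timepoints, the mean rule at
    threshold s and the sum rule at threshold T*s give identical edge sets.
    """
    if rule not in ("mean", "sum"):
        raise ValueError(f"unknown rule {rule!r}")
    col = "mean" if rule == "mean" else "cumulative_sum"
    summ = result.summary.set_index(["marker_x", "marker_y"])[col]
    markers = sorted(
        set(result.summary.marker_x) | set(result.summary.marker_y)
    )
    g = nx.Graph()
    g.add_nodes_from(markers)
    for a, b in combinations(markers, 2):
        vals = [v for v in (summ.get((a, b)), summ.get((b, a))) if v is not None]
        if not vals:
            continue
        strength = max(vals)
        if np.isfinite(strength) and strength >= threshold:
            g.add_edge(a, b, strength=float(strength))
    return SignalingNetwork(graph=g, rule=rule, threshold=threshold)


def trajectory_stats(
    table: EventTable,
    markers: list[str],
    transformed: bool = False,
    cofactor: float = 5.0,
) -> pd.DataFrame:
    """Per marker x condition x timepoint mean, CV and normalized mean.

    CV uses the population standard deviation (divisor n) over raw counts
    by default, and is NaN (flagged) where the mean is zero.  The
    normalized mean is min-max scaled within each marker x condition
    series, so a non-constant series attains both 0 and 1.
    """
    tp = table.require_meta("timepoint_min").to_numpy(dtype=float)
    cond = table.require_meta("condition_id").to_numpy()
    rows = []
    for m in markers:
        v = table.channel(m)
        if transformed:
            v = np.arcsinh(v / cofactor)
        for c in table.conditions():
            for t in np.unique(tp[cond == c]):
                sel = (cond == c) & (tp == t)
                vals = v[sel]
                mean = float(vals.mean())
                cv = float(vals.std() / mean) if mean > 0 else np.nan
                rows.append(
                    {
                        "marker": m,
                        "condition_id": c,
                        "timepoint_min": float(t),
                        "mean_signal": mean,
                        "cv": cv,
                        "cv_defined": mean > 0,
                        "n_events": int(sel.sum()),
                    }
                )
    df = pd.DataFrame(rows)

    def _minmax(s: pd.Series) -> pd.Series:
        span = s.max() - s.min()
        return (s - s.min()) / span if span > 0 else pd.Series(0.0, index=s.index)

    df["normalized_mean"] = df.groupby(["marker", "condition_id"], sort=False)[
        "mean_signal"
    ].transform(_minmax)
    return df


def sign_pseudotime(pseudotime, phase_labels, negative_phase: str) -> np.ndarray:
    """Negate the pseudotime of cells in the designated phase.

    Used to place two consecutive transitions (e.g. EMT then MET) on one
    signed axis: cells of ``negative_phase`` get -pseudotime, others are
    unchanged; within-phase rank order is preserved.  If no cell carries
    the phase, warns and returns the input unchanged.
    """
    pt = np.asarray(pseudotime, dtype=float)
    labels = np.asarray(phase_labels)
    if pt.shape != labels.shape:
        raise ValueError("pseudotime and phase_labels must have equal length")
    if np.any((pt < 0) | (pt > 1)):
        raise ValueError("pseudotime values must lie in [0, 1]")
    mask = labels == negative_phase
    if not mask.any():
        warnings.warn(
            f"no cells labeled {negative_phase!r}; pseudotime returned unsigned",
            stacklevel=2,
        )
        return pt.copy()
    out = pt.copy()
    out[mask] = -out[mask]
    return out


class Bpr2Network(BaseEstimator):
    """BP-R2 scoring and network construction as an sklearn-style estimator.

    ``fit(table)`` scores every ordered marker pair at every timepoint and
    thresholds the pair summaries into an undirected network.

    Attributes
    ----------
    result_ : Bpr2Result
        Per-pair, per-timepoint scores with cumulative/mean summaries.
    network_ : SignalingNetwork
        The thresholded graph; ``edges_`` lists (a, b, strength).
    """

    def __init__(
        self,
        markers: list[str] | None = None,
        n_bins: int = 10,
        min_bin_count: int = 20,
        rule: str = "mean",
        threshold: float = 0.775,
        transformed: bool = True,
        cofactor: float = 5.0,
    ):
        self.markers = markers
        self.n_bins = n_bins
        self.min_bin_count = min_bin_count
        self.rule = rule
        self.threshold = threshold
        self.transformed = transformed
        self.cofactor = cofactor

    def fit(self, X: EventTable, y=None):
        markers = self.markers if self.markers is not None else list(X.channel_names)
        self.result_ = score_timecourse(
            X,
            markers,
            n_bins=self.n_bins,
            min_bin_count=self.min_bin_count,
            transformed=self.transformed,
            cofactor=self.cofactor,
        )
        self.network_ = build_network(self.result_, rule=self.rule, threshold=self.threshold)
        self.edges_ = self.network_.edges
        self.summary_ = self.result_.summary
        return self
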