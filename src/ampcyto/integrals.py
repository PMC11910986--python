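"""Trajectory integral statistics: half-maximal point, AUC above HMP, peak time.

A marker's mean-signal trajectory is computed per treatment condition over
a stimulation timecourse.  The half-maximal point (HMP) is half the
highest mean over ALL conditions and timepoints — shared across
conditions so the integrals are comparable between treatments.  The total
signaling response is the trapezoid area between the piecewise-linear
trajectory and the HMP, counting only segments where the trajectory
exceeds it (threshold crossings are linearly interpolated); the peak time
is the observed timepoint of maximal mean, earliest timepoint on ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .events import EventTable
from .signaling import trajectory_stats

__all__ = [
    "IntegralResult",
    "SignalingIntegrator",
    "compute_hmp",
    "integral_above_hmp",
    "peak_time",
]


@dataclass
class IntegralResult:
    """Per-marker HMP plus per (marker, condition) AUC-above-HMP and peak time."""

    hmp: dict  # marker -> half-maximal point (signal units)
    table: pd.DataFrame  # marker, condition_id, auc_over_hmp, peak_time_min
    degenerate_markers: tuple = ()  # markers whose trajectories are all zero


def compute_hmp(trajectories: pd.DataFrame, marker: str) -> float:
    """Half of the maximum mean signal over all conditions and timepoints.

    ``trajectories`` is the output of :func:`ampcyto.signaling.trajectory_stats`
    (needs columns marker, condition_id, timepoint_min, mean_signal).
    A zero HMP (all-zero trajectory) is returned as 0.0 and should be
    treated as degenerate by callers.
    """
    sub = trajectories[trajectories.marker == marker]
    if sub.empty:
        raise ValueError(f"marker {marker!r} absent from trajectory table")
    if sub.timepoint_min.nunique() < 2:
        raise ValueError("need at least 2 timepoints to define a trajectory")
    return float(sub.mean_signal.max() / 2.0)


def integral_above_hmp(timepoints_min, means, hmp: float) -> float:
    """Trapezoid area between a piecewise-linear trajectory and the HMP level.

    Only the region where the trajectory exceeds ``hmp`` contributes;
    segments crossing the level are split at the linearly interpolated
    crossing point; segments entirely below contribute 0.  Units:
    signal x minutes.
    """
    t = np.asarray(timepoints_min, dtype=float)
    y = np.asarray(means, dtype=float)
    if t.size != y.size:
        raise ValueError("timepoints and means must have equal length")
    if t.size < 2:
        raise ValueError("need at least 2 timepoints")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    excess = y - hmp
    area = 0.0
    for k in range(t.size - 1):
        t0, t1 = t[k], t[k + 1]
        e0, e1 = excess[k], excess[k + 1]
        if e0 <= 0 and e1 <= 0:
            continue
        if e0 >= 0 and e1 >= 0:
            area += 0.5 * (e0 + e1) * (t1 - t0)
        else:
            # one crossing inside the segment
            tc = t0 + (t1 - t0) * e0 / (e0 - e1)
            if e0 > 0:
                area += 0.5 * e0 * (tc - t0)
            else:
                area += 0.5 * e1 * (t1 - tc)
    return float(area)


def peak_time(timepoints_min, means) -> float:
    """Observed timepoint of the maximal mean; earliest timepoint on ties."""
    t = np.asarray(timepoints_min, dtype=float)
    y = np.asarray(means, dtype=float)
    if t.size == 0:
        raise ValueError("empty trajectory")
    return float(t[int(np.argmax(y))])  # argmax returns the first maximum


class SignalingIntegrator(BaseEstimator):
    """HMP / AUC-above-HMP / peak-time analysis as an sklearn-style estimator.

    ``fit(table)`` computes per-marker mean trajectories per condition
    (raw counts by default, matching mean-ion-count reporting), the shared
    HMP per marker, and the per-condition integral and peak time.

    Attributes
    ----------
    trajectories_ : DataFrame
        Mean-signal trajectories (from :func:`trajectory_stats`).
    hmp_ : dict
        marker -> half-maximal point.
    result_ : IntegralResult
        ``result_.table`` has one row per (marker, condition).
    clipped_fraction_ : dict
        (marker, condition) -> fraction of the unsigned area |trajectory -
        HMP| that fell below the HMP and was clipped to zero.
    """

    def __init__(
        self,
        markers: list[str] | None = None,
        transformed: bool = False,
        cofactor: float = 5.0,
    ):
        self.markers = markers
        self.transformed = transformed
        self.cofactor = cofactor

    def fit(self, X: EventTable, y=None):
        markers = self.markers if self.markers is not None else list(X.channel_names)
        traj = trajectory_stats(
            X, markers, transformed=self.transformed, cofactor=self.cofactor
        )
        hmp = {m: compute_hmp(traj, m) for m in markers}
        degenerate = tuple(m for m in markers if hmp[m] == 0.0)
        rows = []
        clipped = {}
        for m in markers:
            for c, grp in traj[traj.marker == m].groupby("condition_id", sort=False):
                grp = grp.sort_values("timepoint_min")
                t = grp.timepoint_min.to_numpy()
                mu = grp.mean_signal.to_numpy()
                auc = integral_above_hmp(t, mu, hmp[m])
                below = integral_above_hmp(t, 2 * hmp[m] - mu, hmp[m])  # mirrored deficit
                total = auc + below
                clipped[(m, c)] = below / total if total > 0 else 0.0
                rows.append(
                    {
                        "marker": m,
                        "condition_id": c,
                        "hmp": hmp[m],
                        "auc_over_hmp": auc,
                        "peak_time_min": peak_time(t, mu),
                    }
                )
        self.trajectories_ = traj
        self.hmp_ = hmp
        self.clipped_fraction_ = clipped
        self.result_ = IntegralResult(
            hmp=hmp, table=pd.DataFrame(rows), degenerate_markers=degenerate
        )
        return self
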