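"""Equal-width-bin amplification and linearity analysis.

The amplification gradient experiment measures the same cells on a
reference channel (conventional secondary antibody, cycle-independent) and
an amplified target channel across thermal-cycle conditions.  Cells are
divided into equal-width bins of reference expression pooled over all
conditions (default 10; bins 1-3 capture the negative/untransfected
population, bin 10 the highest expressors).  From per-(condition, bin)
medians of the target channel the analysis derives:

* linearity ratios — each bin median over the reference-bin (bin 10)
  median; under unbiased amplification the ratio profile is the same in
  every cycle condition;
* fold amplification — reference-bin median relative to a baseline
  condition, on raw counts;
* signal-to-noise — reference-bin median over the pooled negative-bin
  median, and its enhancement relative to baseline;
* concordance — Pearson correlation between the amplified and reference
  channels on transformed values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .events import EventTable, arcsinh_transform

__all__ = [
    "BinningSpec",
    "BinAssignment",
    "BinSummary",
    "AmplificationQuantifier",
    "define_bins",
    "summarize_bins",
    "linearity_ratios",
    "fold_and_snr",
    "concordance",
]


@dataclass(frozen=True)
class BinningSpec:
    """Equal-width binning on a reference channel, pooled across conditions."""

    n_bins: int = 10
    bin_channel: str = "reference"
    negative_bins: tuple[int, ...] = (1, 2, 3)
    reference_bin: int | None = None  # None -> n_bins
    min_bin_count: int = 10
    transformed_bins: bool = True  # compute edges in arcsinh space
    cofactor: float = 5.0

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be positive")
        ref = self.reference_bin if self.reference_bin is not None else self.n_bins
        if not (1 <= ref <= self.n_bins):
            raise ValueError("reference_bin outside 1..n_bins")
        if any(b < 1 or b > self.n_bins for b in self.negative_bins):
            raise ValueError("negative_bins outside 1..n_bins")

    @property
    def ref_bin(self) -> int:
        return self.reference_bin if self.reference_bin is not None else self.n_bins


@dataclass
class BinAssignment:
    """Equal-width edges plus per-event bin ids (1..n_bins)."""

    edges: np.ndarray
    bin_ids: np.ndarray
    spec: BinningSpec


@dataclass
class BinSummary:
    """Per-(condition, bin) target medians/counts plus pooled negative medians."""

    edges: np.ndarray
    table: pd.DataFrame  # columns: condition_id, bin, count, median, flagged
    negative_median: dict  # condition -> pooled median over negative-bin events
    spec: BinningSpec
    target_channel: str = ""

    def median(self, condition, bin_id: int) -> float:
        row = self.table[
            (self.table.condition_id == condition) & (self.table.bin == bin_id)
        ]
        if row.empty or row.flagged.iloc[0]:
            raise ValueError(
                f"bin {bin_id} of condition {condition!r} is empty or below the count floor"
            )
        return float(row["median"].iloc[0])


def define_bins(table: EventTable, spec: BinningSpec = BinningSpec()) -> BinAssignment:
    """Equal-width partition of the pooled reference-channel range.

    Edges span [min, max] of the bin channel over ALL conditions so bins
    are comparable across cycle conditions.  Interior bins are left-closed
    right-open; the last bin is right-closed so the maximum lands in bin
    n_bins.
    """
    if table.n_events == 0:
        raise ValueError("cannot bin an empty table")
    x = table.channel(spec.bin_channel)
    if spec.transformed_bins:
        x = np.arcsinh(x / spec.cofactor)
    lo, hi = float(x.min()), float(x.max())
    if not hi > lo:
        raise ValueError(f"channel {spec.bin_channel!r} is degenerate (constant)")
    edges = np.linspace(lo, hi, spec.n_bins + 1)
    bin_ids = np.searchsorted(edges, x, side="right")
    np.clip(bin_ids, 1, spec.n_bins, out=bin_ids)
    return BinAssignment(edges=edges, bin_ids=bin_ids.astype(int), spec=spec)


def summarize_bins(
    table: EventTable,
    bins: BinAssignment,
    target_channel: str,
    transformed: bool = False,
) -> BinSummary:
    """Median of the target channel per (condition, bin) with a count floor.

    Medians are of raw counts by default (set ``transformed`` for arcsinh
    space).  Bins holding fewer than ``min_bin_count`` events are flagged
    and their median reported as NaN.  Also records, per condition, the
    pooled median over all events in the negative bins (the SNR noise
    floor).
    """
    spec = bins.spec
    y = table.channel(target_channel)
    if transformed:
        y = np.arcsinh(y / spec.cofactor)
    cond = table.require_meta("condition_id").to_numpy()
    rows = []
    neg_median = {}
    neg_set = set(spec.negative_bins)
    for c in table.conditions():
        sel = cond == c
        ids = bins.bin_ids[sel]
        yc = y[sel]
        for b in range(1, spec.n_bins + 1):
            yb = yc[ids == b]
            flagged = yb.size < spec.min_bin_count
            rows.append(
                {
                    "condition_id": c,
                    "bin": b,
                    "count": int(yb.size),
                    "median": float(np.median(yb)) if not flagged else np.nan,
                    "flagged": bool(flagged),
                }
            )
        neg_mask = np.isin(ids, list(neg_set))
        neg_median[c] = float(np.median(yc[neg_mask])) if neg_mask.any() else np.nan
    return BinSummary(
        edges=bins.edges,
        table=pd.DataFrame(rows),
        negative_median=neg_median,
        spec=spec,
        target_channel=target_channel,
    )


def linearity_ratios(summary: BinSummary, spec: BinningSpec | None = None) -> pd.DataFrame:
    """Per-(condition, bin) ratio of the bin median to the reference-bin median.

    Under unbiased amplification the ratio profile is (up to sampling
    noise) identical across cycle conditions; the ratio at the reference
    bin is exactly 1.
    """
    spec = spec or summary.spec
    out = []
    for c, grp in summary.table.groupby("condition_id", sort=False):
        ref_rows = grp[grp.bin == spec.ref_bin]
        if ref_rows.empty or ref_rows.flagged.iloc[0]:
            raise ValueError(f"reference bin unoccupied in condition {c!r}")
        ref = float(ref_rows["median"].iloc[0])
        if ref == 0:
            raise ValueError(f"reference-bin median is zero in condition {c!r}")
        for _, row in grp.iterrows():
            out.append(
                {
                    "condition_id": c,
                    "bin": int(row["bin"]),
                    "ratio_to_reference_bin": (
                        row["median"] / ref if not row["flagged"] else np.nan
                    ),
                }
            )
    df = pd.DataFrame(out)
    # force exactness at the reference bin (guards against fp round-off)
    df.loc[df.bin == spec.ref_bin, "ratio_to_reference_bin"] = 1.0
    return df


def fold_and_snr(summary: BinSummary, baseline_condition) -> pd.DataFrame:
    """Fold amplification and SNR per condition, relative to a baseline.

    fold = reference-bin median(condition) / reference-bin median(baseline);
    snr = reference-bin median / pooled negative-bin median (per condition);
    snr_enhancement = snr(condition) / snr(baseline).  Computed on whatever
    scale the summary holds (raw counts by default).
    """
    spec = summary.spec
    conds = list(summary.table.condition_id.drop_duplicates())
    if baseline_condition not in conds:
        raise ValueError(f"baseline condition {baseline_condition!r} not present")
    ref_med = {c: summary.median(c, spec.ref_bin) for c in conds}
    if ref_med[baseline_condition] == 0:
        raise ValueError("baseline reference-bin median is zero")
    snr = {}
    for c in conds:
        neg = summary.negative_median.get(c, np.nan)
        snr[c] = ref_med[c] / neg if neg and np.isfinite(neg) and neg > 0 else np.nan
    base_snr = snr[baseline_condition]
    return pd.DataFrame(
        {
            "condition_id": conds,
            "fold_vs_baseline": [ref_med[c] / ref_med[baseline_condition] for c in conds],
            "snr": [snr[c] for c in conds],
            "snr_enhancement": [
                snr[c] / base_snr if np.isfinite(base_snr) and base_snr > 0 else np.nan
                for c in conds
            ],
        }
    )


def concordance(
    table: EventTable, channel_x: str, channel_y: str, cofactor: float = 5.0
) -> float:
    """Pearson correlation of two channels on transformed values."""
    x = np.arcsinh(table.channel(channel_x) / cofactor)
    y = np.arcsinh(table.channel(channel_y) / cofactor)
    if x.size < 2:
        raise ValueError("need at least 2 events for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant channel")
    return float(stats.pearsonr(x, y)[0])


class AmplificationQuantifier(BaseEstimator):
    """End-to-end binned amplification analysis as an sklearn-style estimator.

    Parameters mirror :class:`BinningSpec`; ``fit`` takes an
    :class:`EventTable` with condition metadata and raw counts.

    Attributes
    ----------
    edges_ : ndarray of shape (n_bins + 1,)
        Pooled equal-width bin edges (transformed scale by default).
    bin_summary_ : BinSummary
        Per-(condition, bin) target-channel medians and counts.
    ratios_ : DataFrame
        Linearity ratios to the reference bin.
    report_ : DataFrame
        Per condition: fold_vs_baseline, snr, snr_enhancement, pearson_r.
    """

    def __init__(
        self,
        n_bins: int = 10,
        bin_channel: str = "reference",
        target_channel: str = "ace",
        baseline_condition=None,
        negative_bins: tuple[int, ...] = (1, 2, 3),
        reference_bin: int | None = None,
        min_bin_count: int = 10,
        transformed_bins: bool = True,
        transformed_medians: bool = False,
        cofactor: float = 5.0,
    ):
        self.n_bins = n_bins
        self.bin_channel = bin_channel
        self.target_channel = target_channel
        self.baseline_condition = baseline_condition
        self.negative_bins = negative_bins
        self.reference_bin = reference_bin
        self.min_bin_count = min_bin_count
        self.transformed_bins = transformed_bins
        self.transformed_medians = transformed_medians
        self.cofactor = cofactor

    def _spec(self) -> BinningSpec:
        return BinningSpec(
            n_bins=self.n_bins,
            bin_channel=self.bin_channel,
            negative_bins=tuple(self.negative_bins),
            reference_bin=self.reference_bin,
            min_bin_count=self.min_bin_count,
            transformed_bins=self.transformed_bins,
            cofactor=self.cofactor,
        )

    def fit(self, X: EventTable, y=None):
        spec = self._spec()
        assignment = define_bins(X, spec)
        summary = summarize_bins(
            X, assignment, self.target_channel, transformed=self.transformed_medians
        )
        baseline = self.baseline_condition
        if baseline is None:
            baseline = X.conditions()[0]
        report = fold_and_snr(summary, baseline)
        cond = X.require_meta("condition_id").to_numpy()
        report["pearson_r"] = [
            concordance(
                X.subset(cond == c), self.target_channel, self.bin_channel, self.cofactor
            )
            for c in report.condition_id
        ]
        self.edges_ = assignment.edges
        self.assignment_ = assignment
        self.bin_summary_ = summary
        self.ratios_ = linearity_ratios(summary, spec)
        self.report_ = report
        self.baseline_condition_ = baseline
        return self
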