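"""Per-cell summarization of imaging mass cytometry label masks.

Converts a 2-D integer label mask (0 = background) plus per-channel
intensity images into an event table with one row per segmented cell:
objects with fewer than ``min_pixels`` pixels (default 30) are removed,
and each retained object's channel value is the arithmetic mean of its
pixels' ion counts.  Label semantics are respected as-is — an id's pixels
are summarized together even if spatially disconnected, and ids need not
be contiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .events import EventTable

__all__ = ["LabelImage", "CellMeanSummarizer", "summarize_mask"]


@dataclass
class LabelImage:
    """Integer label mask plus a same-shaped stack of channel images."""

    labels: np.ndarray
    channels: np.ndarray  # (n_channels, H, W)
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim == 2:
            self.channels = self.channels[None]
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D array")
        if self.channels.shape[1:] != self.labels.shape:
            raise ValueError(
                f"channel shape {self.channels.shape[1:]} != mask shape {self.labels.shape}"
            )
        if len(self.channel_names) != self.channels.shape[0]:
            raise ValueError("one name per channel required")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.all(self.labels == np.round(self.labels)):
                raise ValueError("labels must be integers")
            self.labels = self.labels.astype(np.int64)
        if self.labels.min() < 0:
            raise ValueError("negative labels are not allowed")


def summarize_mask(
    image: LabelImage, min_pixels: int = 30, exclude_border: bool = False
) -> tuple[EventTable, dict]:
    """One row of per-channel pixel means per retained object, plus a report.

    Removal is strictly "fewer than min_pixels": a 30-pixel object
    survives the default floor of 30.  Background (label 0) is never
    summarized.  Rows are ordered by ascending object id.  The report
    counts removed objects; with ``exclude_border`` objects touching the
    image edge are also dropped (off by default — no border rule is
    assumed).
    """
    if min_pixels < 1:
        raise ValueError("min_pixels must be >= 1")
    labels = image.labels
    flat = labels.ravel()
    max_id = int(flat.max()) if flat.size else 0
    counts = np.bincount(flat, minlength=max_id + 1)
    ids = np.nonzero(counts)[0]
    ids = ids[ids > 0]

    border_ids: set[int] = set()
    if exclude_border and labels.size:
        for edge in (labels[0], labels[-1], labels[:, 0], labels[:, -1]):
            border_ids.update(int(v) for v in np.unique(edge) if v > 0)

    kept = [k for k in ids if counts[k] >= min_pixels and k not in border_ids]
    removed_small = [k for k in ids if counts[k] < min_pixels]
    removed_border = [k for k in ids if counts[k] >= min_pixels and k in border_ids]

    sums = np.stack(
        [np.bincount(flat, weights=ch.ravel(), minlength=max_id + 1) for ch in image.channels]
    )
    values = np.array(
        [[sums[c, k] / counts[k] for c in range(len(image.channel_names))] for k in kept]
    ).reshape(len(kept), len(image.channel_names))
    meta = pd.DataFrame(
        {
            "condition_id": "image",
            "object_id": kept,
            "n_pixels": [int(counts[k]) for k in kept],
        }
    )
    table = EventTable(values, image.channel_names, meta)
    report = {
        "n_objects": int(ids.size),
        "n_retained": len(kept),
        "n_removed_small": len(removed_small),
        "removed_small_ids": [int(k) for k in removed_small],
        "n_removed_border": len(removed_border),
        "min_pixels": int(min_pixels),
    }
    return table, report


class CellMeanSummarizer(TransformerMixin, BaseEstimator):
    """Mask-to-event-table summarization as an sklearn-style transformer.

    ``transform`` accepts a :class:`LabelImage` and returns the per-cell
    :class:`EventTable`; the removal report from the last call is kept in
    ``report_``.
    """

    def __init__(self, min_pixels: int = 30, exclude_border: bool = False):
        self.min_pixels = min_pixels
        self.exclude_border = exclude_border

    def fit(self, X: LabelImage, y=None):
        return self

    def transform(self, X: LabelImage) -> EventTable:
        table, report = summarize_mask(
            X, min_pixels=self.min_pixels, exclude_border=self.exclude_border
        )
        self.report_ = report
        return table
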