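"""Event-level data model and I/O for mass cytometry dual-count tables.

The central container is :class:`EventTable`: a cells x channels matrix of
nonnegative ion ("dual") counts plus per-event metadata (condition, timepoint
in minutes, thermal-cycle count, optional phase label).  Channels resolve to
:class:`ChannelInfo` panel records carrying marker, metal, mass number and
initiator/detector identity.

Counts are variance-stabilized with the inverse hyperbolic sine transform
``asinh(x / cofactor)`` (cofactor 5 by default, the standard CyTOF choice);
:class:`ArcsinhTransform` exposes it as an sklearn transformer so it can sit
in a pipeline, and :func:`arcsinh_transform` applies it to a whole table.
"""

from __future__ import annotations

import dataclasses
import pathlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "EventTable",
    "ChannelInfo",
    "TransformSpec",
    "ArcsinhTransform",
    "arcsinh_transform",
    "inverse_arcsinh_transform",
    "load_events",
    "write_events",
]

#: metadata columns carried alongside the count matrix
META_COLUMNS = ("condition_id", "timepoint_min", "cycle_count", "phase_label")


@dataclass(frozen=True)
class ChannelInfo:
    """Panel record for one measurement channel.

    Parameters
    ----------
    channel_name : str
        Identifier matching an :class:`EventTable` column.
    marker : str
        Biological target (e.g. ``"p-ERK1/2"``).
    metal : str
        Isotope label (e.g. ``"Yb"``).
    mass_number : int
        Isotope mass in Da; adjacency in mass (+/-1) is the instrument
        spillover axis, distinct from sequence crosstalk.
    role : str
        One of ``{"target", "reference", "dna", "control"}``.
    initiator_id, detector_id : int, optional
        Barcode indices for single-stain crosstalk panels; a matched pair
        has ``initiator_id == detector_id``.
    """

    channel_name: str
    marker: str = ""
    metal: str = ""
    mass_number: int = 0
    role: str = "target"
    initiator_id: int | None = None
    detector_id: int | None = None

    def __post_init__(self) -> None:
        if self.role not in ("target", "reference", "dna", "control"):
            raise ValueError(f"unknown channel role {self.role!r}")
        if self.mass_number < 0:
            raise ValueError("mass_number must be nonnegative")


@dataclass(frozen=True)
class TransformSpec:
    """Arcsinh variance-stabilization parameters (cofactor > 0, default 5)."""

    cofactor: float = 5.0

    def __post_init__(self) -> None:
        if not self.cofactor > 0:
            raise ValueError(f"cofactor must be positive, got {self.cofactor}")


class EventTable:
    """Cells x channels nonnegative count matrix with per-event metadata.

    Parameters
    ----------
    values : array-like or DataFrame, shape (n_events, n_channels)
        Nonnegative, finite ion counts (raw or transformed).
    channel_names : sequence of str, optional
        Required when ``values`` is not a DataFrame; must be unique.
    meta : DataFrame, optional
        One row per event.  Recognised columns: ``condition_id`` (str),
        ``timepoint_min`` (float, minutes), ``cycle_count`` (int),
        ``phase_label`` (str).  Missing columns are permitted; stages that
        need one fail fast with a named-field error.
    """

    def __init__(
        self,
        values,
        channel_names: Sequence[str] | None = None,
        meta: pd.DataFrame | None = None,
    ) -> None:
        if isinstance(values, pd.DataFrame):
            if channel_names is None:
                channel_names = [str(c) for c in values.columns]
            values = values.to_numpy(dtype=float)
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D events x channels matrix")
        if channel_names is None:
            raise ValueError("channel_names required for array input")
        channel_names = [str(c) for c in channel_names]
        if len(channel_names) != values.shape[1]:
            raise ValueError(
                f"{len(channel_names)} channel names for {values.shape[1]} columns"
            )
        if len(set(channel_names)) != len(channel_names):
            raise ValueError("channel_names must be unique")
        if not np.all(np.isfinite(values)):
            bad = [channel_names[j] for j in np.where(~np.isfinite(values).all(axis=0))[0]]
            raise ValueError(f"non-finite values in channel(s) {bad}")
        if np.any(values < 0):
            bad = [channel_names[j] for j in np.where((values < 0).any(axis=0))[0]]
            raise ValueError(f"negative values in channel(s) {bad}")
        if meta is None:
            meta = pd.DataFrame(index=range(values.shape[0]))
        if len(meta) != values.shape[0]:
            raise ValueError(
                f"meta has {len(meta)} rows for {values.shape[0]} events"
            )
        self.values = values
        self.channel_names = list(channel_names)
        self.meta = meta.reset_index(drop=True)

    # -- basic protocol ---------------------------------------------------
    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def __len__(self) -> int:
        return self.n_events

    def __repr__(self) -> str:
        return (
            f"EventTable({self.n_events} events x {self.n_channels} channels: "
            f"{self.channel_names})"
        )

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's values as a 1-D array."""
        try:
            j = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in table (have {self.channel_names})"
            ) from None
        return self.values[:, j]

    def require_meta(self, column: str) -> pd.Series:
        """Return a metadata column, failing fast with a named-field error."""
        if column not in self.meta.columns or self.meta[column].isna().all():
            raise KeyError(f"event metadata field {column!r} is required but missing")
        return self.meta[column]

    def subset(self, mask) -> "EventTable":
        mask = np.asarray(mask)
        return EventTable(
            self.values[mask], self.channel_names, self.meta.loc[mask].reset_index(drop=True)
        )

    def to_frame(self) -> pd.DataFrame:
        """Counts and metadata side by side in one DataFrame."""
        df = pd.DataFrame(self.values, columns=self.channel_names)
        for col in self.meta.columns:
            df[col] = self.meta[col].to_numpy()
        return df

    def conditions(self) -> list:
        """Distinct condition ids in stable order of first appearance."""
        cond = self.require_meta("condition_id")
        return list(dict.fromkeys(cond))


class ArcsinhTransform(TransformerMixin, BaseEstimator):
    """Inverse-hyperbolic-sine variance stabilization, x -> asinh(x / cofactor).

    Strictly increasing, maps 0 to 0, and is exactly invertible via
    ``cofactor * sinh(y)``.  Stateless: ``fit`` only validates.
    """

    def __init__(self, cofactor: float = 5.0):
        self.cofactor = cofactor

    def fit(self, X, y=None):
        if not self.cofactor > 0:
            raise ValueError(f"cofactor must be positive, got {self.cofactor}")
        self.n_features_in_ = np.asarray(X).shape[1] if np.ndim(X) == 2 else 1
        return self

    def transform(self, X):
        if not self.cofactor > 0:
            raise ValueError(f"cofactor must be positive, got {self.cofactor}")
        return np.arcsinh(np.asarray(X, dtype=float) / self.cofactor)

    def inverse_transform(self, X):
        return self.cofactor * np.sinh(np.asarray(X, dtype=float))


def arcsinh_transform(table: EventTable, spec: TransformSpec | float = TransformSpec()) -> EventTable:
    """Apply ``asinh(x / cofactor)`` to every count; metadata unchanged."""
    cofactor = spec.cofactor if isinstance(spec, TransformSpec) else float(spec)
    tr = ArcsinhTransform(cofactor=cofactor)
    return EventTable(tr.fit_transform(table.values), table.channel_names, table.meta)


def inverse_arcsinh_transform(table: EventTable, spec: TransformSpec | float = TransformSpec()) -> EventTable:
    """Undo :func:`arcsinh_transform` (exact analytic inverse)."""
    cofactor = spec.cofactor if isinstance(spec, TransformSpec) else float(spec)
    return EventTable(
        ArcsinhTransform(cofactor=cofactor).fit(table.values).inverse_transform(table.values),
        table.channel_names,
        table.meta,
    )


# -- file I/O -------------------------------------------------------------

def _validate_against_panel(table: EventTable, panel: Sequence[ChannelInfo] | None) -> None:
    if panel is None:
        return
    panel_names = {c.channel_name for c in panel}
    missing = [c for c in table.channel_names if c not in panel_names]
    if missing:
        raise ValueError(f"channels {missing} not described by the panel")


def load_events(
    path,
    format: str = "csv",
    panel: Sequence[ChannelInfo] | None = None,
) -> EventTable:
    """Read an :class:`EventTable` from CSV or FCS.

    CSV: one header row; metadata travels in the reserved sidecar columns
    ``condition_id``, ``timepoint_min``, ``cycle_count``, ``phase_label``.
    FCS (3.0/3.1 list-mode float): metadata, having no standard per-event
    slot in FCS, is read from a companion ``<stem>.meta.csv`` keyed by
    0-based event index when that file exists.
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        df = pd.read_csv(path)
        meta_cols = [c for c in META_COLUMNS if c in df.columns]
        meta = df[meta_cols].copy() if meta_cols else None
        chan_cols = [c for c in df.columns if c not in META_COLUMNS]
        for c in chan_cols:
            if len(df) and not pd.api.types.is_numeric_dtype(df[c]):
                raise ValueError(f"non-numeric values in channel column {c!r}")
        if not len(df):
            return EventTable(np.empty((0, len(chan_cols))), chan_cols, meta)
        table = EventTable(df[chan_cols], meta=meta)
    elif format == "fcs":
        from . import _fcs

        values, names = _fcs.read_fcs(path)
        meta_path = path.with_suffix(".meta.csv")
        meta = pd.read_csv(meta_path) if meta_path.exists() else None
        table = EventTable(values, names, meta=meta)
    else:
        raise ValueError(f"unknown format {format!r}")
    _validate_against_panel(table, panel)
    return table


def write_events(table: EventTable, path, format: str = "csv"):
    """Write an :class:`EventTable`; the result round-trips via :func:`load_events`.

    CSV is comma-separated, UTF-8, '.' decimal, header row.  FCS output is
    3.1 list-mode float32 with the event metadata in a companion
    ``<stem>.meta.csv``.
    """
    path = pathlib.Path(path)
    if format == "csv":
        table.to_frame().to_csv(path, index=False)
    elif format == "fcs":
        from . import _fcs

        _fcs.write_fcs(path, table.values, table.channel_names)
        if len(table.meta.columns):
            table.meta.to_csv(path.with_suffix(".meta.csv"), index=False)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path
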