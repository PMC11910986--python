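"""Minimal FCS 3.0/3.1 list-mode reader and writer.

Covers the subset the pipeline needs: DATATYPE F (32-bit) or D (64-bit)
floating point, MODE L, single data segment, little- or big-endian BYTEORD.
ANALYSIS segments and compensation keywords are ignored with a warning.
The writer emits FCS3.1 / DATATYPE D / little-endian so that round-trips
are exact.
"""

from __future__ import annotations

import logging
import pathlib
import struct

import numpy as np

log = logging.getLogger(__name__)

_DELIM = b"/"


def _build_text(keywords: dict[str, str]) -> bytes:
    parts = [_DELIM]
    for k, v in keywords.items():
        parts.append(k.encode("ascii") + _DELIM + str(v).encode("utf-8") + _DELIM)
    return b"".join(parts)


def write_fcs(path, values: np.ndarray, channel_names: list[str]) -> None:
    values = np.ascontiguousarray(values, dtype="<f8")
    n_events, n_par = values.shape
    keywords = {
        "$DATATYPE": "D",
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4,5,6,7,8",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
        "$NEXTDATA": "0",
    }
    for j, name in enumerate(channel_names, start=1):
        keywords[f"$P{j}N"] = name
        keywords[f"$P{j}B"] = "64"
        keywords[f"$P{j}E"] = "0,0"
        keywords[f"$P{j}R"] = str(int(np.ceil(values[:, j - 1].max())) + 1 if n_events else 1)

    # two-pass: offsets depend on TEXT length, which depends on the offsets
    data_nbytes = values.nbytes
    header_len = 58  # "FCS3.1    " + 8 offset fields of 8 chars
    begin_text = header_len
    text = b""
    for _ in range(3):
        kw = dict(keywords)
        end_text = begin_text + len(text) - 1 if text else 0
        begin_data = begin_text + len(text)
        kw["$BEGINDATA"] = str(begin_data)
        kw["$ENDDATA"] = str(begin_data + data_nbytes - 1)
        new_text = _build_text(kw)
        if len(new_text) == len(text):
            text = new_text
            break
        text = new_text
    end_text = begin_text + len(text) - 1
    begin_data = begin_text + len(text)
    end_data = begin_data + data_nbytes - 1

    def _off(x: int) -> bytes:
        s = str(x) if x <= 99_999_999 else "0"
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + b"".join(
        _off(x) for x in (begin_text, end_text, begin_data, end_data, 0, 0)
    )
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(values.tobytes())


def _parse_text(raw: bytes) -> dict[str, str]:
    delim = raw[:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    tokens = body.split(delim)
    if len(tokens) % 2:
        tokens = tokens[:-1]
    return {
        tokens[i].decode("utf-8", "replace").strip(): tokens[i + 1].decode("utf-8", "replace")
        for i in range(0, len(tokens), 2)
    }


def read_fcs(path) -> tuple[np.ndarray, list[str]]:
    """Return ``(values, channel_names)`` from an FCS 3.0/3.1 file."""
    path = pathlib.Path(path)
    raw = path.read_bytes()
    version = raw[:6].decode("ascii", "replace")
    if not version.startswith("FCS3"):
        raise ValueError(f"unsupported FCS version {version!r} in {path}")
    offs = [int(raw[10 + 8 * i : 18 + 8 * i].strip() or 0) for i in range(6)]
    begin_text, end_text = offs[0], offs[1]
    kw = _parse_text(raw[begin_text : end_text + 1])

    begin_data = int(kw.get("$BEGINDATA", offs[2]) or offs[2])
    end_data = int(kw.get("$ENDDATA", offs[3]) or offs[3])
    if offs[4] or kw.get("$BEGINANALYSIS", "0").strip() not in ("", "0"):
        log.warning("%s: ANALYSIS segment present; ignored", path)
    if any(k.upper().startswith(("$SPILLOVER", "$COMP", "SPILL")) for k in kw):
        log.warning("%s: compensation keywords present; ignored", path)

    mode = kw.get("$MODE", "L").strip().upper()
    if mode != "L":
        raise ValueError(f"unsupported FCS mode {mode!r} (list mode only)")
    dtype_code = kw.get("$DATATYPE", "F").strip().upper()
    if dtype_code not in ("F", "D"):
        raise ValueError(f"unsupported FCS datatype {dtype_code!r} (float only)")
    byteord = kw.get("$BYTEORD", "1,2,3,4").strip()
    endian = "<" if byteord.startswith("1") else ">"
    itemsize = 4 if dtype_code == "F" else 8
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])

    widths = {int(kw.get(f"$P{j}B", itemsize * 8)) for j in range(1, n_par + 1)}
    if widths != {itemsize * 8}:
        raise ValueError(f"mixed parameter bit widths {widths} unsupported")

    data = raw[begin_data : end_data + 1]
    expected = n_par * n_tot * itemsize
    if len(data) < expected:
        raise ValueError(f"truncated DATA segment in {path}")
    values = np.frombuffer(data[:expected], dtype=f"{endian}f{itemsize}")
    values = values.reshape(n_tot, n_par).astype(float)
    names = [kw.get(f"$P{j}N", f"P{j}").strip() for j in range(1, n_par + 1)]
    return values, names
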