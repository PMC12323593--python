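"""Minimal FCS 3.0/3.1 list-mode reader and writer.

Supports the subset of the FCS standard produced by benchtop cytometers in
list mode: a single data segment with ``$MODE L``, ``$DATATYPE`` F (float32),
D (float64) or I (unsigned integers of uniform ``$PnB`` width), and a uniform
byte order.  Analysis segments and multi-dataset files are ignored.

The writer emits FCS 3.1 float32 files and exists mainly so the reader can be
exercised round-trip without shipping binary fixtures.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

__all__ = ["is_fcs", "read_fcs", "write_fcs"]

_VERSIONS = (b"FCS3.0", b"FCS3.1")


def is_fcs(path: str | Path) -> bool:
    """True when the file starts with an FCS3.x version string."""
    with open(path, "rb") as fh:
        return fh.read(6) in _VERSIONS


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FormatError("empty FCS TEXT segment")
    delim = raw[0:1]
    parts = raw[1:].split(delim)
    if parts and parts[-1] == b"":
        parts = parts[:-1]
    if len(parts) % 2:
        raise FormatError("FCS TEXT segment has an odd number of fields")
    out: dict[str, str] = {}
    for key, val in zip(parts[::2], parts[1::2]):
        out[key.decode("ascii", "replace").strip().upper()] = val.decode(
            "ascii", "replace"
        ).strip()
    return out


def read_fcs(path: str | Path) -> pd.DataFrame:
    """Read an FCS 3.0/3.1 list-mode file into a DataFrame.

    Columns are named from ``$PnN``; one row per event.
    """
    blob = Path(path).read_bytes()
    if blob[:6] not in _VERSIONS:
        raise FormatError(f"{path}: not an FCS 3.0/3.1 file")
    try:
        text_start = int(blob[10:18])
        text_end = int(blob[18:26])
        data_start = int(blob[26:34])
        data_end = int(blob[34:42])
    except ValueError as exc:
        raise FormatError(f"{path}: malformed FCS header offsets") from exc
    text = _parse_text_segment(blob[text_start : text_end + 1])
    if text.get("$MODE", "L").upper() != "L":
        raise FormatError("only list-mode ($MODE L) FCS files are supported")
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    if data_start == 0:
        data_start = int(text["$BEGINDATA"])
        data_end = int(text["$ENDDATA"])
    datatype = text.get("$DATATYPE", "F").upper()
    byteord = text.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    bits = {int(text.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)}
    if len(bits) != 1:
        raise FormatError("mixed per-parameter bit widths are not supported")
    nbytes = bits.pop() // 8
    if datatype == "F":
        dtype = np.dtype(f"{endian}f4")
    elif datatype == "D":
        dtype = np.dtype(f"{endian}f8")
    elif datatype == "I":
        dtype = np.dtype(f"{endian}u{nbytes}")
    else:
        raise FormatError(f"unsupported FCS $DATATYPE {datatype!r}")
    if dtype.itemsize != nbytes:
        raise FormatError("$PnB inconsistent with $DATATYPE")
    raw = blob[data_start : data_end + 1]
    expected = n_par * n_tot * dtype.itemsize
    if len(raw) < expected:
        raise FormatError("FCS data segment shorter than $PAR * $TOT events")
    arr = np.frombuffer(raw[:expected], dtype=dtype).reshape(n_tot, n_par)
    names = [text.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    return pd.DataFrame(arr.astype(float), columns=names)


def write_fcs(data: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as a little-endian float32 FCS 3.1 file."""
    if data.shape[1] == 0:
        raise FormatError("cannot write an FCS file with no parameters")
    values = data.to_numpy(dtype="<f4")
    n_tot, n_par = values.shape
    delim = "/"
    kv: list[tuple[str, str]] = [
        ("$MODE", "L"),
        ("$DATATYPE", "F"),
        ("$BYTEORD", "1,2,3,4"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
        ("$NEXTDATA", "0"),
    ]
    for i, name in enumerate(data.columns, start=1):
        kv += [(f"$P{i}N", str(name)), (f"$P{i}B", "32"), (f"$P{i}R", "262144"), (f"$P{i}E", "0,0")]

    header_len = 58  # version + 6 offset fields of 8 chars
    data_bytes = values.tobytes()

    def render(begin_data: int, end_data: int) -> bytes:
        pairs = kv + [("$BEGINDATA", str(begin_data)), ("$ENDDATA", str(end_data))]
        body = delim + delim.join(f"{k}{delim}{v}" for k, v in pairs) + delim
        return body.encode("ascii")

    # fixed-point iteration: data offsets depend on TEXT length and vice versa
    begin_data = end_data = 0
    for _ in range(4):
        text = render(begin_data, end_data)
        new_begin = header_len + len(text)
        new_end = new_begin + len(data_bytes) - 1
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end
    text = render(begin_data, end_data)
    text_start = header_len
    text_end = text_start + len(text) - 1
    header = b"FCS3.1    " + (
        f"{text_start:8d}{text_end:8d}{begin_data:8d}{end_data:8d}{0:8d}{0:8d}"
    ).encode("ascii")
    assert len(header) == header_len
    Path(path).write_bytes(header + text + data_bytes)
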