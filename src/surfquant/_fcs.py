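"""Minimal reader/writer for FCS 3.0/3.1 flow-cytometry event files.

Covers the subset of the standard the flow path needs: list-mode data
(``$MODE L``), float (``F``/``D``) or unsigned-integer (``I``) data types,
uniform bit widths, and both byte orders.  Compensation, analysis segments
and multi-dataset files are out of scope.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["read_fcs", "write_fcs"]

_HEADER_LEN = 58


def _parse_text(raw: bytes) -> dict[str, str]:
    delim = raw[0:1].decode("latin-1")
    # escaped delimiters (doubled) are not handled; rare in practice
    parts = raw[1:].decode("latin-1").split(delim)
    kv = {}
    for i in range(0, len(parts) - 1, 2):
        key = parts[i].strip().upper()
        if key:
            kv[key] = parts[i + 1]
    return kv


def read_fcs(path) -> tuple[dict[str, str], pd.DataFrame]:
    """Read an FCS 3.0/3.1 file -> (text-segment keywords, events table).

    The events table has one column per parameter, named by ``$PnN``.
    """
    with open(path, "rb") as fh:
        buf = fh.read()
    version = buf[0:6].decode("ascii", "replace")
    if not version.startswith("FCS3"):
        raise ValueError(f"unsupported FCS version {version!r} (need FCS 3.0/3.1)")
    text_begin = int(buf[10:18])
    text_end = int(buf[18:26])
    text = _parse_text(buf[text_begin : text_end + 1])

    data_begin = int(text.get("$BEGINDATA", buf[26:34] or 0) or int(buf[26:34]))
    data_end = int(text.get("$ENDDATA", buf[34:42] or 0) or int(buf[34:42]))
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    datatype = text["$DATATYPE"].strip().upper()
    mode = text.get("$MODE", "L").strip().upper()
    if mode != "L":
        raise ValueError(f"only list mode ($MODE L) supported, got {mode!r}")
    byteord = text["$BYTEORD"].strip()
    endian = "<" if byteord.startswith("1") else ">"
    bits = {int(text[f"$P{i}B"]) for i in range(1, n_par + 1)}
    if len(bits) != 1:
        raise ValueError("mixed per-parameter bit widths are not supported")
    nbits = bits.pop()
    if datatype == "F":
        dtype = np.dtype(f"{endian}f4")
    elif datatype == "D":
        dtype = np.dtype(f"{endian}f8")
    elif datatype == "I":
        dtype = np.dtype(f"{endian}u{nbits // 8}")
    else:
        raise ValueError(f"unsupported $DATATYPE {datatype!r}")
    if nbits != dtype.itemsize * 8:
        raise ValueError(f"$PnB={nbits} inconsistent with $DATATYPE {datatype}")
    raw = buf[data_begin : data_end + 1]
    events = np.frombuffer(raw, dtype=dtype, count=n_par * n_tot)
    events = events.reshape(n_tot, n_par).astype(np.float64)
    names = [text.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    return text, pd.DataFrame(events, columns=names)


def write_fcs(path, events: pd.DataFrame, extra_keywords: dict[str, str] | None = None) -> None:
    """Write an events table as a little-endian float32 FCS 3.1 file."""
    data = np.ascontiguousarray(events.to_numpy(dtype="<f4"))
    n_tot, n_par = data.shape
    kv = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
    }
    for i, name in enumerate(events.columns, start=1):
        kv[f"$P{i}N"] = str(name)
        kv[f"$P{i}B"] = "32"
        kv[f"$P{i}E"] = "0,0"
        kv[f"$P{i}R"] = str(int(max(1.0, np.nanmax(data[:, i - 1]) + 1)) if n_tot else 1)
    if extra_keywords:
        kv.update(extra_keywords)

    # fixed-width offsets so the TEXT length does not depend on their values
    def render(begin_data: int, end_data: int, begin_text: int, end_text: int) -> bytes:
        kv["$BEGINDATA"] = f"{begin_data:010d}"
        kv["$ENDDATA"] = f"{end_data:010d}"
        body = "|".join(f"{k}|{v}" for k, v in sorted(kv.items()))
        text = ("|" + body + "|").encode("latin-1")
        header = (
            b"FCS3.1    "
            + f"{begin_text:8d}".encode()
            + f"{end_text:8d}".encode()
            + f"{begin_data:8d}".encode()
            + f"{end_data:8d}".encode()
            + f"{0:8d}".encode()
            + f"{0:8d}".encode()
        )
        return header + text

    kv["$BEGINDATA"] = f"{0:010d}"
    kv["$ENDDATA"] = f"{0:010d}"
    probe = render(0, 0, 0, 0)
    text_begin = _HEADER_LEN
    text_end = len(probe) - 1
    data_begin = len(probe)
    data_end = data_begin + data.nbytes - 1
    final = render(data_begin, data_end, text_begin, text_end)
    if len(final) != data_begin:
        raise AssertionError("FCS offset bookkeeping error")
    with open(path, "wb") as fh:
        fh.write(final)
        fh.write(data.tobytes())
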