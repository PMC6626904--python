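"""Minimal FCS 3.0/3.1 list-mode codec.

Reads and writes the subset of the FCS standard that cytometry analysis
actually exchanges: list-mode (``$MODE L``) floating-point data
(``$DATATYPE F`` or ``D``) with a single data segment.  Integer data,
analysis segments, and multi-dataset files are out of scope; TSV is the
text-format alternative for anything this codec does not cover.
"""

from __future__ import annotations

import numpy as np

__all__ = ["read_fcs", "write_fcs", "FcsFormatError"]

_DELIM = "/"


class FcsFormatError(ValueError):
    pass


def write_fcs(path, channel_names: list[str], data: np.ndarray) -> None:
    """Write events x channels float data as FCS 3.1 (float32, little-endian)."""
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 2 or data.shape[1] != len(channel_names):
        raise ValueError("data shape does not match channel names")
    n_events, n_par = data.shape
    for name in channel_names:
        if _DELIM in name:
            raise FcsFormatError(f"channel name may not contain {_DELIM!r}: {name}")

    keywords: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_events)),
    ]
    rng = float(np.abs(data).max()) if data.size else 1.0
    for i, name in enumerate(channel_names, start=1):
        keywords.append((f"$P{i}B", "32"))
        keywords.append((f"$P{i}E", "0,0"))
        keywords.append((f"$P{i}N", name))
        keywords.append((f"$P{i}R", str(int(np.ceil(rng)) + 1)))

    header_len = 58
    data_bytes = data.tobytes(order="C")

    # Offsets appear inside TEXT, so sizes are resolved by fixed-width
    # zero-padded placeholders (12 digits cover any realistic file).
    def build_text(begin_data: int, end_data: int) -> bytes:
        items = [("$BEGINDATA", f"{begin_data:012d}"), ("$ENDDATA", f"{end_data:012d}")]
        items += keywords
        text = _DELIM + _DELIM.join(f"{k}{_DELIM}{v}" for k, v in items) + _DELIM
        return text.encode("ascii")

    text = build_text(0, 0)
    text_begin = header_len
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + len(data_bytes) - 1
    text = build_text(data_begin, data_end)

    header = (
        f"FCS3.1    "
        f"{text_begin:>8d}{text_end:>8d}"
        f"{(data_begin if data_end <= 99999999 else 0):>8d}"
        f"{(data_end if data_end <= 99999999 else 0):>8d}"
        f"{0:>8d}{0:>8d}"
    ).encode("ascii")
    assert len(header) == header_len

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data_bytes)


def read_fcs(path) -> tuple[list[str], np.ndarray]:
    """Read an FCS 3.0/3.1 file; returns (channel names, events x channels)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 58 or not raw[:3] == b"FCS":
        raise FcsFormatError("not an FCS file")
    version = raw[:6].decode("ascii", "replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FcsFormatError(f"unsupported FCS version {version!r}")

    def _off(a: int, b: int) -> int:
        s = raw[a:b].decode("ascii").strip()
        return int(s) if s else 0

    text_begin, text_end = _off(10, 18), _off(18, 26)
    data_begin, data_end = _off(26, 34), _off(34, 42)

    text = raw[text_begin : text_end + 1].decode("utf-8", "replace")
    if not text:
        raise FcsFormatError("empty TEXT segment")
    delim = text[0]
    parts = text[1:].rstrip(delim).split(delim)
    if len(parts) % 2:
        parts = parts[:-1]
    kw = {parts[i].strip().upper(): parts[i + 1] for i in range(0, len(parts), 2)}

    if kw.get("$MODE", "L").upper() != "L":
        raise FcsFormatError("only list-mode ($MODE L) data is supported")
    dtype_code = kw.get("$DATATYPE", "F").upper()
    if dtype_code not in ("F", "D"):
        raise FcsFormatError("only floating-point data ($DATATYPE F/D) is supported")
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]

    byteord = kw.get("$BYTEORD", "1,2,3,4").strip()
    endian = "<" if byteord.startswith("1") else ">"
    itemsize = 4 if dtype_code == "F" else 8
    np_dtype = np.dtype(f"{endian}f{itemsize}")

    if not data_begin:
        data_begin = int(kw["$BEGINDATA"])
        data_end = int(kw["$ENDDATA"])
    n_bytes = n_par * n_tot * itemsize
    if data_end - data_begin + 1 < n_bytes:
        raise FcsFormatError("DATA segment shorter than $PAR x $TOT values")
    buf = raw[data_begin : data_begin + n_bytes]
    data = np.frombuffer(buf, dtype=np_dtype).reshape(n_tot, n_par).astype(float)
    return names, data
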