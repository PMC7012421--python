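"""Minimal FCS 3.0/3.1 list-mode reader.

Supports the common case of cytometry exports: list mode (``$MODE=L``),
floating-point or integer data (``$DATATYPE`` F, D or I), little- or
big-endian byte order, uniform or per-parameter bit widths.  Log-amplified
integer parameters (``$PnE`` with a nonzero exponent) are decoded to the
linear scale.  Compensation/spillover is not applied; input is assumed to be
compensated upstream.
"""

from __future__ import annotations

import numpy as np

__all__ = ["FcsFormatError", "read_fcs"]


class FcsFormatError(ValueError):
    """The file is not a readable FCS 3.0/3.1 list-mode file."""


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FcsFormatError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    # double-delimiter escaping is rare; split and re-join empties
    parts = body.split(delim)
    fields: list[str] = []
    for p in parts:
        fields.append(p.decode("utf-8", errors="replace"))
    if len(fields) % 2 != 0:
        fields = fields[: len(fields) - 1]
    keywords = {}
    for key, val in zip(fields[::2], fields[1::2]):
        keywords[key.strip().upper()] = val.strip()
    return keywords


def read_fcs(path: str) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Read an FCS file; returns ``(data, channel_names, keywords)``.

    Channel names come from ``$PnS`` (stain name) when present, otherwise
    ``$PnN`` (short name).
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 58:
        raise FcsFormatError("file too short to be FCS")
    version = raw[0:6].decode("ascii", errors="replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FcsFormatError(f"unsupported FCS version {version!r}")
    try:
        text_begin = int(raw[10:18])
        text_end = int(raw[18:26])
        data_begin = int(raw[26:34])
        data_end = int(raw[34:42])
    except ValueError as exc:
        raise FcsFormatError("malformed header offsets") from exc

    kw = _parse_text_segment(raw[text_begin : text_end + 1])
    if kw.get("$MODE", "L").upper() != "L":
        raise FcsFormatError("only list-mode ($MODE=L) files are supported")

    if data_begin == 0:
        data_begin = int(kw.get("$BEGINDATA", 0))
        data_end = int(kw.get("$ENDDATA", 0))
    if data_begin <= 0 or data_end < data_begin:
        raise FcsFormatError("missing data segment offsets")

    try:
        n_par = int(kw["$PAR"])
        n_tot = int(kw["$TOT"])
        datatype = kw["$DATATYPE"].upper()
        byteord = kw["$BYTEORD"]
    except KeyError as exc:
        raise FcsFormatError(f"missing required keyword {exc}") from exc

    if byteord.replace(" ", "") in ("1,2,3,4", "1,2"):
        endian = "<"
    elif byteord.replace(" ", "") in ("4,3,2,1", "2,1"):
        endian = ">"
    else:
        raise FcsFormatError(f"unsupported $BYTEORD {byteord!r}")

    bits = [int(kw.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]
    names = []
    for i in range(1, n_par + 1):
        names.append(kw.get(f"$P{i}S") or kw.get(f"$P{i}N") or f"P{i}")

    blob = raw[data_begin : data_end + 1]
    if datatype == "F":
        if any(b != 32 for b in bits):
            raise FcsFormatError("$DATATYPE=F requires 32-bit parameters")
        arr = np.frombuffer(blob[: 4 * n_par * n_tot], dtype=endian + "f4")
    elif datatype == "D":
        if any(b != 64 for b in bits):
            raise FcsFormatError("$DATATYPE=D requires 64-bit parameters")
        arr = np.frombuffer(blob[: 8 * n_par * n_tot], dtype=endian + "f8")
    elif datatype == "I":
        if len(set(bits)) != 1 or bits[0] not in (8, 16, 32):
            raise FcsFormatError("integer data requires uniform 8/16/32-bit widths")
        arr = np.frombuffer(
            blob[: bits[0] // 8 * n_par * n_tot], dtype=f"{endian}u{bits[0] // 8}"
        )
    else:
        raise FcsFormatError(f"unsupported $DATATYPE {datatype!r}")

    if arr.size != n_par * n_tot:
        raise FcsFormatError("data segment size disagrees with $PAR * $TOT")
    data = arr.reshape(n_tot, n_par).astype(np.float64)

    if datatype == "I":
        for i in range(1, n_par + 1):
            pne = kw.get(f"$P{i}E", "0,0").split(",")
            decades = float(pne[0])
            if decades > 0:
                r = float(kw.get(f"$P{i}R", 2 ** bits[i - 1]))
                offset = float(pne[1]) if len(pne) > 1 and float(pne[1]) != 0 else 1.0
                data[:, i - 1] = offset * 10 ** (decades * data[:, i - 1] / r)

    return data, names, kw
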