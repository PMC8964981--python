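"""Minimal FCS 3.1 writer/reader for list-mode float data.

Covers exactly what this pipeline needs to round-trip its own cohorts:
single-dataset files, $MODE L, $DATATYPE F (little-endian float32), marker
names carried in $PnS with short names in $PnN. It is not a general FCS
parser; CSV is the pipeline's primary interchange format.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

_DELIM = "/"
_HEADER_LEN = 58
_OFFSET_WIDTH = 10  # zero-padded so TEXT length is independent of the values


def write_fcs(path: str | Path, matrix: np.ndarray, marker_names: list[str] | tuple[str, ...]) -> None:
    """Write a cells x markers matrix as an FCS 3.1 file (float32 data)."""
    matrix = np.asarray(matrix, dtype=np.float32)
    if matrix.ndim != 2:
        raise ValueError("matrix must be 2-D")
    n_cells, n_par = matrix.shape
    if n_par != len(marker_names):
        raise ValueError("marker_names length does not match matrix columns")

    keywords: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        ("$BEGINDATA", "0".zfill(_OFFSET_WIDTH)),
        ("$ENDDATA", "0".zfill(_OFFSET_WIDTH)),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_cells)),
    ]
    for i, name in enumerate(marker_names, start=1):
        if _DELIM in name:
            raise ValueError(f"marker name contains the TEXT delimiter: {name!r}")
        keywords += [
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}N", f"P{i}"),
            (f"$P{i}S", name),
            (f"$P{i}R", str(int(max(1.0, float(np.ceil(matrix[:, i - 1].max(initial=0.0) + 1))))) ),
        ]

    def render(kws: list[tuple[str, str]]) -> bytes:
        parts = [_DELIM]
        for k, v in kws:
            parts += [k, _DELIM, v, _DELIM]
        return "".join(parts).encode("ascii")

    text = render(keywords)
    text_start = _HEADER_LEN
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + 4 * n_cells * n_par - 1
    if data_end > 99_999_999:
        raise ValueError("matrix too large for this minimal FCS writer")
    keywords = [
        (k, str(data_start).zfill(_OFFSET_WIDTH)) if k == "$BEGINDATA"
        else (k, str(data_end).zfill(_OFFSET_WIDTH)) if k == "$ENDDATA"
        else (k, v)
        for k, v in keywords
    ]
    text = render(keywords)

    header = (
        b"FCS3.1    "
        + f"{text_start:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + f"{data_start:>8d}".encode()
        + f"{data_end:>8d}".encode()
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    assert len(header) == _HEADER_LEN
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(matrix.astype("<f4").tobytes())


def read_fcs(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    """Read an FCS file written by :func:`write_fcs`.

    Returns (cells x markers float32 matrix, marker names from $PnS/$PnN).
    """
    raw = Path(path).read_bytes()
    if not raw.startswith(b"FCS3"):
        raise ValueError(f"not an FCS 3.x file: {path}")
    text_start = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_start : text_end + 1].decode("ascii")
    delim = text[0]
    fields = text.strip(delim).split(delim)
    kw = dict(zip(fields[::2], fields[1::2]))

    if kw.get("$DATATYPE") != "F" or kw.get("$MODE") != "L":
        raise ValueError("only list-mode float32 FCS data is supported")
    order = kw.get("$BYTEORD", "1,2,3,4")
    dtype = "<f4" if order == "1,2,3,4" else ">f4"
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    data_start = int(kw.get("$BEGINDATA") or raw[26:34])
    data = np.frombuffer(raw, dtype=dtype, count=n_par * n_tot, offset=data_start)
    names = tuple(
        kw.get(f"$P{i}S", kw.get(f"$P{i}N", f"P{i}")) for i in range(1, n_par + 1)
    )
    return data.reshape(n_tot, n_par).copy(), names
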