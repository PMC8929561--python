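"""Parsing of MD-analysis per-frame interaction series files.

Two whitespace-separated table dialects are supported, mirroring the
series output of trajectory hydrogen-bond and (native/non-native) contact
analyses: a header row names one interaction per column, and every
subsequent row holds the frame index followed by the per-frame values.

Header token grammars (``RES`` = residue name, ``NUM`` = residue number):

* ``hbond-series``:   ``RES_NUM@ATOM-RES_NUM@ATOM-HATOM``
  (acceptor, donor, donated hydrogen; the record connects donor heavy
  atom and acceptor).
* ``contacts-series``: ``RES_NUM@ATOM_RES_NUM@ATOM``

Series files carry no chain information; all atoms are placed on chain
``A``.  Several files (e.g. native and non-native contact series) may be
parsed together: columns naming the same atom pair and type are merged by
frame-wise maximum, which for binary series is the logical OR.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ..network import Timeline, TimelineRecord

__all__ = ["parse_timeseries", "DIALECTS"]

DIALECTS = ("hbond-series", "contacts-series")

_ATOM_RE = re.compile(r"^([A-Za-z0-9]+)_(-?\d+)@([A-Za-z0-9'*]+)$")


def _parse_atom(token: str, context: str) -> str:
    m = _ATOM_RE.match(token)
    if not m:
        raise ValueError(f"unparseable atom token {token!r} in {context!r}")
    res_name, res_num, atom = m.groups()
    return f"A:{res_num}:{res_name}:{atom}"


def _parse_header_token(token: str, dialect: str) -> tuple[str, str, str]:
    """Return (source_atom, target_atom, kind) for one column header."""
    if dialect == "hbond-series":
        parts = token.split("-")
        if len(parts) != 3:
            raise ValueError(f"unparseable hbond header token {token!r}")
        acceptor = _parse_atom(parts[0], token)
        donor = _parse_atom(parts[1], token)
        return donor, acceptor, "hbond"
    # contacts: underscores both inside atom tokens and as the separator;
    # split on '@' to recover the two RES_NUM/ATOM halves
    parts = token.split("@")
    if len(parts) != 3:
        raise ValueError(f"unparseable contact header token {token!r}")
    first = parts[0]
    mid = parts[1].split("_", 1)
    if len(mid) != 2:
        raise ValueError(f"unparseable contact header token {token!r}")
    a = _parse_atom(f"{first}@{mid[0]}", token)
    b = _parse_atom(f"{mid[1]}@{parts[2]}", token)
    return a, b, "contact"


def _read_table(path: Path) -> tuple[list[str], np.ndarray]:
    header: list[str] | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if header is None:
                if not line.startswith("#"):
                    raise ValueError(f"{path}:{lineno}: missing header row")
                header = line.lstrip("#").split()
                continue
            fields = line.split()
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}: row {lineno} has {len(fields)} fields, "
                    f"header declares {len(header)}"
                )
            rows.append([float(f) for f in fields])
    if header is None or not rows:
        raise ValueError(f"{path}: no data rows")
    return header, np.asarray(rows)


def parse_timeseries(
    paths: Sequence[str | Path] | str | Path, dialect: str
) -> list[TimelineRecord]:
    """Parse per-frame series files into atomistic timeline records.

    One record per interaction column; columns for the same (pair, type)
    across files or within a file are merged frame-wise by maximum (OR for
    binary series).  All files must agree on the frame count.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if isinstance(paths, (str, Path)):
        paths = [paths]
    merged: dict[tuple[str, str, str], np.ndarray] = {}
    n_frames: int | None = None
    for path in paths:
        path = Path(path)
        header, table = _read_table(path)
        if n_frames is None:
            n_frames = table.shape[0]
        elif table.shape[0] != n_frames:
            raise ValueError(
                f"{path}: frame count {table.shape[0]} differs from "
                f"previous files ({n_frames})"
            )
        # first column is the frame index
        for col, token in enumerate(header[1:], start=1):
            src, tgt, kind = _parse_header_token(token, dialect)
            u, v = (src, tgt) if src <= tgt else (tgt, src)
            series = np.rint(table[:, col]).astype(np.int64)
            key = (u, v, kind)
            if key in merged:
                merged[key] = np.maximum(merged[key], series)
            else:
                merged[key] = series
    return [
        TimelineRecord(u, v, kind, Timeline(series))
        for (u, v, kind), series in merged.items()
    ]
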