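"""Line-oriented interaction-timeline exchange format ("AIF dialect").

A structured text format listing atom-atom interaction timelines, meant to
be easy to create, inspect and edit by hand.  Grammar (version 1):

    #AIF 1
    #frames <T>
    #fields source target type flags timeline
    <source-atom> <target-atom> <type> <flags|-> <v1,v2,...,vT>

Atom identifiers are ``chain:resnum[inscode]:resname:atomname``; flags are
a comma-separated list or ``-`` when empty; timeline values are
nonnegative integers, exactly T of them per record.  ``read_aif`` and
``write_aif`` round-trip records bit-exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ..network import Timeline, TimelineRecord

__all__ = ["read_aif", "write_aif", "AIF_VERSION"]

AIF_VERSION = 1


def write_aif(records: Sequence[TimelineRecord], path: str | Path) -> None:
    """Write timeline records to an AIF-dialect text file."""
    records = list(records)
    if not records:
        raise ValueError("refusing to write an empty record list")
    n_frames = len(records[0].timeline)
    for rec in records:
        if len(rec.timeline) != n_frames:
            raise ValueError(
                f"record {rec.source}--{rec.target} ({rec.kind}): timeline "
                f"length {len(rec.timeline)} != {n_frames}"
            )
    with open(path, "w") as fh:
        fh.write(f"#AIF {AIF_VERSION}\n")
        fh.write(f"#frames {n_frames}\n")
        fh.write("#fields source target type flags timeline\n")
        for rec in records:
            flags = ",".join(rec.flags) if rec.flags else "-"
            values = ",".join(str(v) for v in rec.timeline.values)
            fh.write(f"{rec.source} {rec.target} {rec.kind} {flags} {values}\n")


def read_aif(path: str | Path) -> tuple[list[TimelineRecord], int]:
    """Read an AIF-dialect file; returns (records, frame count)."""
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or not lines[0].startswith("#AIF"):
        raise ValueError(f"{path}: missing '#AIF <version>' header")
    try:
        version = int(lines[0].split()[1])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{path}: malformed version header {lines[0]!r}") from exc
    if version != AIF_VERSION:
        raise ValueError(f"{path}: unsupported AIF version {version}")
    n_frames: int | None = None
    records: list[TimelineRecord] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        if line.startswith("#"):
            fields = line.lstrip("#").split()
            if fields and fields[0] == "frames":
                n_frames = int(fields[1])
            continue
        if n_frames is None:
            raise ValueError(f"{path}: record before '#frames' header")
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
        source, target, kind, flags_field, values_field = parts
        values = np.array([int(v) for v in values_field.split(",")])
        if values.size != n_frames:
            raise ValueError(
                f"{path}:{lineno}: record {source}--{target} ({kind}) has "
                f"{values.size} values, header declares {n_frames} frames"
            )
        flags = () if flags_field == "-" else tuple(flags_field.split(","))
        records.append(TimelineRecord(source, target, kind, Timeline(values), flags))
    if n_frames is None:
        raise ValueError(f"{path}: missing '#frames' header")
    return records, n_frames
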