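"""Readers and writers for encounter-history files.

Two plain-text dialects are supported:

* the classic capture-history ``.inp`` layout used by mark-recapture
  software: one line per individual, ``<history> <male> <female>;`` with
  the two group-frequency columns ordered (male, female) and an optional
  ``/* id */`` comment prefix that survives a round-trip;
* a CSV layout with columns ``individual_id, entity_id, sex, h1..hT``.
"""

from __future__ import annotations

import re
from os import PathLike
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd

from .simulator import CaptureDataset

__all__ = ["write_inp", "read_inp", "write_csv", "read_csv"]

_INP_LINE = re.compile(
    r"^\s*(?:/\*\s*(?P<comment>.*?)\s*\*/)?\s*"
    r"(?P<history>[01]+)\s+(?P<male>\d+)\s+(?P<female>\d+)\s*;\s*$"
)


def write_inp(
    data: CaptureDataset,
    destination: str | PathLike | IO[str],
    include_ids: bool = False,
) -> None:
    """Write one ``<history> <male> <female>;`` line per individual.

    With ``include_ids`` the individual's index is kept in a ``/* id */``
    comment prefix, which the reader tolerates and preserves.
    """
    lines = []
    for i, (history, sex) in enumerate(zip(data.history_strings(), data.sex)):
        male, female = (1, 0) if sex == "M" else (0, 1)
        prefix = f"/* {i} */ " if include_ids else ""
        lines.append(f"{prefix}{history} {male} {female};\n")
    text = "".join(lines)
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text)


def read_inp(source: str | PathLike | IO[str]) -> CaptureDataset:
    """Parse an ``.inp`` file back into a :class:`CaptureDataset`.

    Entity indices are not represented in this dialect; each individual
    is read back as its own entity.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    histories: list[list[int]] = []
    sexes: list[str] = []
    length: int | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip():
            continue
        match = _INP_LINE.match(raw)
        if match is None:
            raise ValueError(f"line {lineno}: cannot parse {raw!r}")
        history = match["history"]
        if length is None:
            length = len(history)
        elif len(history) != length:
            raise ValueError(
                f"line {lineno}: history length {len(history)} != {length}"
            )
        male, female = int(match["male"]), int(match["female"])
        if male + female != 1:
            raise ValueError(
                f"line {lineno}: expected exactly one of the male/female "
                f"columns to be 1, got {male} {female}"
            )
        histories.append([int(c) for c in history])
        sexes.append("M" if male else "F")
    if not histories:
        raise ValueError("no encounter histories found")
    n = len(histories)
    return CaptureDataset(
        histories=np.array(histories, dtype=np.int8),
        sex=np.array(sexes),
        entity_index=np.arange(n),
    )


def write_csv(data: CaptureDataset, destination: str | PathLike | IO[str]) -> None:
    """Write the CSV dialect (individual_id, entity_id, sex, h1..hT)."""
    T = data.n_occasions
    frame = pd.DataFrame(
        {
            "individual_id": np.arange(data.n_individuals),
            "entity_id": data.entity_index,
            "sex": data.sex,
        }
    )
    for t in range(T):
        frame[f"h{t + 1}"] = data.histories[:, t]
    frame.to_csv(destination, index=False)


def read_csv(source: str | PathLike | IO[str]) -> CaptureDataset:
    """Read the CSV dialect back into a :class:`CaptureDataset`."""
    frame = pd.read_csv(source)
    required = {"individual_id", "entity_id", "sex"}
    if not required <= set(frame.columns):
        raise ValueError(f"missing required columns {sorted(required - set(frame.columns))}")
    hcols = sorted(
        (c for c in frame.columns if re.fullmatch(r"h\d+", c)),
        key=lambda c: int(c[1:]),
    )
    if not hcols:
        raise ValueError("no history columns h1..hT found")
    if not frame["sex"].isin(["M", "F"]).all():
        raise ValueError("sex column must contain only 'M' and 'F'")
    return CaptureDataset(
        histories=frame[hcols].to_numpy(dtype=np.int8),
        sex=frame["sex"].to_numpy(),
        entity_index=frame["entity_id"].to_numpy(dtype=np.int64),
    )
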