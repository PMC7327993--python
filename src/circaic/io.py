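"""Reading and writing angle files.

Plain text (one value per line, ``#`` comments and blank lines skipped) or
CSV with a named/indexed column.  Degrees are the default unit for files —
the field convention in orientation biology — and are converted to radians
exactly once on read.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .angles import AngleSample

logger = logging.getLogger("circaic")


@dataclass(frozen=True)
class AngleFileSpec:
    """Where and how to read a sample of angles."""

    path: Union[str, Path]
    units: str = "deg"
    column: Optional[Union[str, int]] = None  # CSV column name or index


def read_angles(spec: Union[AngleFileSpec, str, Path], units: str = "deg",
                column: Optional[Union[str, int]] = None) -> AngleSample:
    """Read an angle file into an :class:`AngleSample`.

    Accepts an :class:`AngleFileSpec` or a bare path plus keyword options.
    Unparsable lines produce warnings with their line numbers; the read
    fails only if no line parses at all.
    """
    if not isinstance(spec, AngleFileSpec):
        spec = AngleFileSpec(spec, units=units, column=column)
    path = Path(spec.path)
    if path.suffix.lower() == ".csv" or spec.column is not None:
        values = _read_csv(path, spec.column)
    else:
        values = _read_plain(path)
    if len(values) == 0:
        raise ValueError(f"{path}: no parsable angle values")
    return AngleSample(np.asarray(values, dtype=float), units=spec.units)


def _read_plain(path: Path) -> list:
    values, bad = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                values.append(float(line))
            except ValueError:
                bad.append(lineno)
    for lineno in bad:
        warnings.warn(f"{path}:{lineno}: unparsable line skipped", stacklevel=2)
    return values


def _read_csv(path: Path, column) -> list:
    df = pd.read_csv(path, comment="#")
    if column is None:
        column = "angle" if "angle" in df.columns else df.columns[0]
    col = df.iloc[:, column] if isinstance(column, int) else df[column]
    numeric = pd.to_numeric(col, errors="coerce")
    bad = numeric.index[numeric.isna() & col.notna()]
    for idx in bad:
        warnings.warn(f"{path}: row {idx + 2}: unparsable value skipped", stacklevel=2)
    return numeric.dropna().tolist()


def write_angles(sample: AngleSample, path: Union[str, Path], units: str = "rad") -> None:
    """Write one angle per line (plain text) or, for ``.csv`` paths, a CSV
    with a single ``angle`` column."""
    path = Path(path)
    a = sample.angles if units == "rad" else np.rad2deg(sample.angles)
    if path.suffix.lower() == ".csv":
        pd.DataFrame({"angle": a}).to_csv(path, index=False)
    else:
        with open(path, "w") as fh:
            for v in a:
                fh.write(f"{float(v)!r}\n")
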