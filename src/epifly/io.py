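"""Plain-text record I/O (one ASCII sample per line, the Bonn dialect)."""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

__all__ = ["read_signal_txt", "write_signal_txt", "read_record_dir"]


def read_signal_txt(path) -> np.ndarray:
    """Read a record of one numeric sample per line; trailing blank lines are
    ignored and a malformed line is reported with its line number."""
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {text!r} on line {lineno}") from None
    if not values:
        raise ValueError(f"{path}: file contains no samples")
    return np.asarray(values, dtype=float)


def write_signal_txt(path, signal) -> None:
    path = Path(path)
    x = np.asarray(signal, dtype=float).ravel()
    with open(path, "w") as fh:
        for v in x:
            fh.write(f"{v:.10g}\n")


def read_record_dir(directory) -> tuple[list[np.ndarray], list[str]]:
    """All ``*.txt`` records of a directory, sorted by file name.

    Returns the signals and their record ids (file stems).
    """
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".txt")
    if not paths:
        raise ValueError(f"{directory}: no .txt records found")
    return [read_signal_txt(p) for p in paths], [p.stem for p in paths]
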