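"""Shared table and FASTQ I/O helpers.

All tabular outputs are tab-separated with ``#``-prefixed metadata header
lines carrying the tool version and the parameters that produced the
table, so every artifact is self-describing and reproducible.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import IO, Any, Mapping

import pandas as pd


def open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    """Open a possibly gzip-compressed text file based on its suffix."""
    path = Path(path)
    if path.suffix == ".gz":
        return _io.TextIOWrapper(gzip.open(path, mode.replace("t", "") + "b"), newline="")
    return open(path, mode, newline="")


def metadata_header(command: str, params: Mapping[str, Any] | None = None) -> str:
    from qaseq import __version__

    parts = [f"qaseq v{__version__}", f"command={command}"]
    for key, value in (params or {}).items():
        parts.append(f"{key}={value}")
    return "# " + " | ".join(parts)


def write_table(
    frame: pd.DataFrame,
    path: str | Path,
    command: str,
    params: Mapping[str, Any] | None = None,
) -> None:
    """Write a DataFrame as TSV preceded by a ``#`` metadata line."""
    with open_text(path, "wt") as handle:
        handle.write(metadata_header(command, params) + "\n")
        frame.to_csv(handle, sep="\t", index=False)


def read_table(path: str | Path, **kwargs: Any) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`, skipping metadata lines."""
    with open_text(path, "rt") as handle:
        return pd.read_csv(handle, sep="\t", comment="#", **kwargs)
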