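"""UMI family grouping, family-size filtering and absolute molecule counts.

The atom of absolute counting is the UMI family: all reads sharing one
(module, UMI) pair.  The *existence* of a family counts one input
molecule; its size only matters for filtering.  Families smaller than
``max(min_reads, fraction × mean(top-3 family sizes))`` are discarded
as products of polymerase/sequencing error, and the surviving family
count is the per-module absolute molecule count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from qaseq.errors import DomainError
from qaseq.io import read_table, write_table
from qaseq.panel import Panel
from qaseq.read_proc import AssignedRead

BASE_ORDER = "ACGTN"
_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}
# ASCII -> column index in base_counts; unknown codes count as N
_ASCII_TO_COL = np.full(256, 4, dtype=np.uint8)
for _b, _i in _BASE_INDEX.items():
    _ASCII_TO_COL[ord(_b)] = _i


@dataclass
class UmiFamily:
    """Reads sharing one (module, UMI) key.

    ``base_counts`` is an (amplicon_length × 5) matrix of per-position
    base counts over A/C/G/T/N accumulated from the insert sequences;
    reads shorter than the amplicon contribute only to the positions
    they cover.
    """

    module_id: str
    umi: str
    size: int
    base_counts: np.ndarray


def group_families(
    assignments: Iterable[AssignedRead], panel: Panel
) -> list[UmiFamily]:
    """Group assigned reads into UMI families; unassigned reads are ignored."""
    amplicon_len = {m.module_id: len(m.amplicon_seq) for m in panel.modules}
    table: dict[tuple[str, str], UmiFamily] = {}
    for rec in assignments:
        if not rec.assigned:
            continue
        key = (rec.module_id, rec.umi)
        fam = table.get(key)
        if fam is None:
            fam = UmiFamily(
                module_id=rec.module_id,
                umi=rec.umi,
                size=0,
                base_counts=np.zeros((amplicon_len[rec.module_id], 5), dtype=np.uint32),
            )
            table[key] = fam
        fam.size += 1
        insert = rec.insert_seq[: fam.base_counts.shape[0]]
        if insert:
            cols = _ASCII_TO_COL[np.frombuffer(insert.encode("ascii"), dtype=np.uint8)]
            fam.base_counts[np.arange(len(insert)), cols] += 1
    return list(table.values())


def family_size_cutoff(
    sizes: Sequence[int], fraction: float = 0.05, min_reads: int = 3
) -> float:
    """Family-size threshold: max(min_reads, fraction × mean of top-3 sizes).

    With fewer than 3 families the mean is taken over the available
    sizes.  Families with size >= the (possibly fractional) threshold
    pass.
    """
    sizes = np.asarray(sizes)
    if sizes.size == 0:
        raise DomainError("family_size_cutoff requires a nonempty size list")
    top = np.sort(sizes)[-3:]
    return max(float(min_reads), fraction * float(np.mean(top)))


@dataclass
class ModuleCount:
    module_id: str
    n_families_raw: int
    size_cutoff: float  # NaN when the module saw no families
    molecule_count: int
    conversion_yield: float | None = None


@dataclass
class MoleculeCountTable:
    """Per-module filtered family counts plus optional conversion yields."""

    rows: list[ModuleCount]
    expected_molecules: float | None = None

    def counts(self) -> dict[str, int]:
        return {r.module_id: r.molecule_count for r in self.rows}

    def __getitem__(self, module_id: str) -> ModuleCount:
        for row in self.rows:
            if row.module_id == module_id:
                return row
        raise KeyError(module_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "module_id": r.module_id,
                    "n_families_raw": r.n_families_raw,
                    "size_cutoff": r.size_cutoff,
                    "molecule_count": r.molecule_count,
                    "conversion_yield": r.conversion_yield
                    if r.conversion_yield is not None
                    else np.nan,
                }
                for r in self.rows
            ]
        )

    def write(self, path: str | Path, params: dict | None = None) -> None:
        write_table(self.to_frame(), path, "count", params)

    @classmethod
    def read(cls, path: str | Path) -> "MoleculeCountTable":
        frame = read_table(path)
        rows = [
            ModuleCount(
                module_id=str(r.module_id),
                n_families_raw=int(r.n_families_raw),
                size_cutoff=float(r.size_cutoff),
                molecule_count=int(r.molecule_count),
                conversion_yield=None
                if pd.isna(r.conversion_yield)
                else float(r.conversion_yield),
            )
            for r in frame.itertuples(index=False)
        ]
        return cls(rows=rows)


def conversion_yield(count: int, expected_molecules: float) -> float:
    """Fraction of expected input molecules observed as counted families."""
    if expected_molecules <= 0:
        raise DomainError("expected_molecules must be positive")
    return count / expected_molecules


def count_molecules(
    families: Sequence[UmiFamily],
    panel: Panel,
    fraction: float = 0.05,
    min_reads: int = 3,
    expected_molecules: float | None = None,
) -> MoleculeCountTable:
    """Apply per-module family-size cutoffs and count surviving families.

    The cutoff is computed per module (family-size scale varies with
    amplification efficiency per amplicon).  When ``expected_molecules``
    is given, a per-module conversion yield is recorded; yields above 1
    are possible (flagged by the caller, not clamped).
    """
    by_module: dict[str, list[int]] = {m.module_id: [] for m in panel.modules}
    for fam in families:
        by_module.setdefault(fam.module_id, []).append(fam.size)
    rows = []
    for module in panel.modules:
        sizes = by_module[module.module_id]
        if not sizes:
            rows.append(
                ModuleCount(module.module_id, 0, float("nan"), 0,
                            0.0 if expected_molecules else None)
            )
            continue
        cutoff = family_size_cutoff(sizes, fraction=fraction, min_reads=min_reads)
        count = int(sum(1 for s in sizes if s >= cutoff))
        cy = conversion_yield(count, expected_molecules) if expected_molecules else None
        rows.append(ModuleCount(module.module_id, len(sizes), cutoff, count, cy))
    return MoleculeCountTable(rows=rows, expected_molecules=expected_molecules)


def passing_families(
    families: Sequence[UmiFamily],
    panel: Panel,
    fraction: float = 0.05,
    min_reads: int = 3,
) -> list[UmiFamily]:
    """Subset of families surviving the per-module size cutoff."""
    sizes_by_module: dict[str, list[int]] = {}
    for fam in families:
        sizes_by_module.setdefault(fam.module_id, []).append(fam.size)
    cutoffs = {
        module_id: family_size_cutoff(sizes, fraction=fraction, min_reads=min_reads)
        for module_id, sizes in sizes_by_module.items()
    }
    return [fam for fam in families if fam.size >= cutoffs[fam.module_id]]


def collapse_umis(
    families: list[UmiFamily], max_hamming: int = 1, min_ratio: float = 10.0
) -> list[UmiFamily]:
    """Optional UMI error collapse (off by default in the CLI).

    A family is merged into another family of the same module that is at
    least ``min_ratio`` times larger and whose UMI is within
    ``max_hamming`` mismatches; sizes and base counts are pooled.
    """
    by_module: dict[str, list[UmiFamily]] = {}
    for fam in families:
        by_module.setdefault(fam.module_id, []).append(fam)
    out: list[UmiFamily] = []
    for fams in by_module.values():
        fams = sorted(fams, key=lambda f: -f.size)
        absorbed = [False] * len(fams)
        for i in range(len(fams) - 1, -1, -1):
            small = fams[i]
            for j in range(i):
                big = fams[j]
                if absorbed[j] or big.size < min_ratio * small.size:
                    continue
                dist = sum(a != b for a, b in zip(big.umi, small.umi))
                if dist <= max_hamming:
                    big.size += small.size
                    if big.base_counts.shape == small.base_counts.shape:
                        big.base_counts += small.base_counts
                    absorbed[i] = True
                    break
        out.extend(f for f, gone in zip(fams, absorbed) if not gone)
    return out


@dataclass
class LognormalFit:
    mu: float
    sigma: float
    skewness: float
    n: int
    reliable: bool


def lognormal_diagnostic(
    sizes: Sequence[int], cutoff: float, min_families: int = 50
) -> LognormalFit:
    """Fit a normal to log(size | size >= cutoff) and report shape.

    Returns the fitted location/scale and the sample skewness of the
    log sizes as the goodness statistic (|skewness| well below ~0.5
    is consistent with log-normal family sizes).
    """
    sizes = np.asarray(sizes, dtype=float)
    kept = sizes[sizes >= cutoff]
    if kept.size == 0:
        raise DomainError("no family sizes above cutoff")
    logs = np.log(kept)
    mu = float(np.mean(logs))
    if kept.size <= 1 or np.ptp(kept) == 0:
        sigma = 0.0
    else:
        sigma = float(np.std(logs, ddof=1))
    skewness = float(stats.skew(logs)) if sigma > 0 else 0.0
    return LognormalFit(
        mu=mu, sigma=sigma, skewness=skewness, n=int(kept.size),
        reliable=kept.size >= min_families,
    )
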