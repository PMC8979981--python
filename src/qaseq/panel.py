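"""Quantitation panel model: modules, genes, roles and testability rules.

A panel is a collection of quantitation modules (one amplicon / primer
pair each) grouped by gene.  Modules play one of three roles: ``target``
(gene of interest), ``reference`` (copy-number-neutral loci used as the
denominator for ploidy), or ``excluded`` (kept in the table, e.g. sex
chromosome loci, but never entering CNV statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import pandas as pd

from qaseq.errors import PanelFormatError, PanelValidationError
from qaseq.io import open_text, metadata_header

VALID_ROLES = frozenset({"target", "reference", "excluded"})
DNA_BASES = frozenset("ACGT")

PANEL_COLUMNS = [
    "module_id",
    "gene",
    "role",
    "chrom",
    "start",
    "end",
    "fwd_primer",
    "rev_primer",
    "amplicon_seq",
    "variant_loci",
]


def _check_dna(seq: str, what: str, module_id: str) -> None:
    if not seq or not set(seq) <= DNA_BASES:
        raise PanelValidationError(
            f"module {module_id!r}: {what} must be a nonempty A/C/G/T string, got {seq!r}"
        )


@dataclass(frozen=True)
class QuantModule:
    """One amplicon-level absolute-quantitation unit.

    Coordinates are 0-based half-open and purely annotational; amplicon
    identity within the pipeline is determined by primer sequence alone.
    ``variant_loci`` lists (offset into ``amplicon_seq``, reference base)
    pairs marking positions monitored for mutations.
    """

    module_id: str
    gene: str
    role: str
    chromosome: str = "."
    amplicon_start: int = 0
    amplicon_end: int = 1
    fwd_primer: str = ""
    rev_primer: str = ""
    amplicon_seq: str = ""
    variant_loci: tuple[tuple[int, str], ...] = ()

    def validate(self) -> None:
        if self.role not in VALID_ROLES:
            raise PanelValidationError(
                f"module {self.module_id!r}: role {self.role!r} not in {sorted(VALID_ROLES)}"
            )
        _check_dna(self.fwd_primer, "fwd_primer", self.module_id)
        _check_dna(self.rev_primer, "rev_primer", self.module_id)
        _check_dna(self.amplicon_seq, "amplicon_seq", self.module_id)
        if self.amplicon_end <= self.amplicon_start:
            raise PanelValidationError(
                f"module {self.module_id!r}: amplicon_end must exceed amplicon_start"
            )
        for offset, ref in self.variant_loci:
            if not 0 <= offset < len(self.amplicon_seq):
                raise PanelValidationError(
                    f"module {self.module_id!r}: variant locus offset {offset} "
                    f"outside amplicon of length {len(self.amplicon_seq)}"
                )
            if self.amplicon_seq[offset] != ref:
                raise PanelValidationError(
                    f"module {self.module_id!r}: variant locus ref base {ref!r} does not "
                    f"match amplicon base {self.amplicon_seq[offset]!r} at offset {offset}"
                )


@dataclass
class Panel:
    """A validated collection of quantitation modules.

    ``min_modules_per_gene_for_test`` is the minimum number of
    non-excluded modules a gene needs before its ploidy can be tested
    with a rank test (default 3).
    """

    modules: list[QuantModule]
    umi_length: int = 12
    min_modules_per_gene_for_test: int = 3

    def __post_init__(self) -> None:
        if self.umi_length < 1:
            raise PanelValidationError("umi_length must be positive")
        if self.min_modules_per_gene_for_test < 1:
            raise PanelValidationError("min_modules_per_gene_for_test must be positive")
        seen: set[str] = set()
        for module in self.modules:
            module.validate()
            if module.module_id in seen:
                raise PanelValidationError(f"duplicate module_id {module.module_id!r}")
            seen.add(module.module_id)
        if not self.reference_module_ids:
            raise PanelValidationError("panel must contain at least one reference module")

    @property
    def reference_module_ids(self) -> set[str]:
        return {m.module_id for m in self.modules if m.role == "reference"}

    @property
    def excluded_module_ids(self) -> set[str]:
        return {m.module_id for m in self.modules if m.role == "excluded"}

    def module(self, module_id: str) -> QuantModule:
        for m in self.modules:
            if m.module_id == module_id:
                return m
        raise KeyError(module_id)

    def modules_by_gene(self, include_excluded: bool = False) -> dict[str, list[QuantModule]]:
        out: dict[str, list[QuantModule]] = {}
        for m in self.modules:
            if m.role == "excluded" and not include_excluded:
                continue
            out.setdefault(m.gene, []).append(m)
        return out

    def target_genes(self) -> set[str]:
        return {m.gene for m in self.modules if m.role == "target"}


def testable_genes(panel: Panel) -> set[str]:
    """Genes of interest with enough modules to support a rank test.

    A gene qualifies when it carries at least one ``target`` module and
    at least ``min_modules_per_gene_for_test`` non-excluded modules;
    genes below the threshold cannot be tested and are reported as
    untestable downstream.
    """
    by_gene = panel.modules_by_gene()
    targets = panel.target_genes()
    return {
        gene
        for gene, mods in by_gene.items()
        if gene in targets and len(mods) >= panel.min_modules_per_gene_for_test
    }


def _format_variant_loci(loci: tuple[tuple[int, str], ...]) -> str:
    return ";".join(f"{offset}:{ref}" for offset, ref in loci) or "."


def _parse_variant_loci(text: str, module_id: str) -> tuple[tuple[int, str], ...]:
    text = (text or "").strip()
    if text in ("", ".", "-", "nan"):
        return ()
    loci = []
    for item in text.split(";"):
        try:
            offset_str, ref = item.split(":")
            loci.append((int(offset_str), ref.strip().upper()))
        except ValueError as exc:
            raise PanelFormatError(
                f"module {module_id!r}: cannot parse variant locus {item!r} "
                "(expected 'offset:refbase')"
            ) from exc
    return tuple(loci)


def load_panel(
    path: str | Path,
    umi_length: int = 12,
    min_modules_per_gene_for_test: int = 3,
) -> Panel:
    """Load and validate a panel from a tab-separated table.

    The table must carry the header columns ``module_id, gene, role,
    chrom, start, end, fwd_primer, rev_primer, amplicon_seq,
    variant_loci``; role strings are normalized case-insensitively and
    row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"panel file not found: {path}")
    with open_text(path, "rt") as handle:
        frame = pd.read_csv(handle, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in PANEL_COLUMNS if c not in frame.columns]
    if missing:
        raise PanelFormatError(f"panel table missing required column(s): {', '.join(missing)}")
    modules = []
    for row in frame.itertuples(index=False):
        module_id = str(row.module_id).strip()
        try:
            start, end = int(row.start), int(row.end)
        except ValueError as exc:
            raise PanelFormatError(
                f"module {module_id!r}: non-integer start/end coordinates"
            ) from exc
        modules.append(
            QuantModule(
                module_id=module_id,
                gene=str(row.gene).strip(),
                role=str(row.role).strip().lower(),
                chromosome=str(row.chrom).strip(),
                amplicon_start=start,
                amplicon_end=end,
                fwd_primer=str(row.fwd_primer).strip().upper(),
                rev_primer=str(row.rev_primer).strip().upper(),
                amplicon_seq=str(row.amplicon_seq).strip().upper(),
                variant_loci=_parse_variant_loci(str(row.variant_loci), module_id),
            )
        )
    return Panel(
        modules=modules,
        umi_length=umi_length,
        min_modules_per_gene_for_test=min_modules_per_gene_for_test,
    )


def write_panel(panel: Panel, path: str | Path) -> None:
    """Write a panel back to the TSV format accepted by :func:`load_panel`."""
    rows = [
        {
            "module_id": m.module_id,
            "gene": m.gene,
            "role": m.role,
            "chrom": m.chromosome,
            "start": m.amplicon_start,
            "end": m.amplicon_end,
            "fwd_primer": m.fwd_primer,
            "rev_primer": m.rev_primer,
            "amplicon_seq": m.amplicon_seq,
            "variant_loci": _format_variant_loci(m.variant_loci),
        }
        for m in panel.modules
    ]
    frame = pd.DataFrame(rows, columns=PANEL_COLUMNS)
    with open_text(path, "wt") as handle:
        handle.write(metadata_header("panel-write", {"umi_length": panel.umi_length}) + "\n")
        frame.to_csv(handle, sep="\t", index=False)


def validate_panel_file(path: str | Path) -> list[str]:
    """Return a list of validation issues for a panel file (empty = valid)."""
    try:
        load_panel(path)
    except (PanelFormatError, PanelValidationError, FileNotFoundError) as exc:
        return [str(exc)]
    return []
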