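"""Synthetic amplicon-library simulator with ground-truth bookkeeping.

The generative model mirrors the statistical structure the downstream
analysis assumes:

1. input molecules per module drawn Poisson from a mass/ploidy model;
2. incomplete barcoding — each molecule yields a counted UMI family only
   with probability ``conversion_yield``;
3. exponential amplification by a Galton–Watson branching process with
   per-family per-cycle efficiency jitter, so family sizes come out
   log-normal-shaped *emergently* rather than by assumption.  The first
   ``high_efficiency_cycles`` cycles (the long-anneal barcoding and
   nested cycles, run to near completion) are deterministic doublings;
4. sequencing depth allocated to families by multinomial sampling over
   relative family sizes;
5. per-base substitution errors, off-target/dimer reads, and variants
   spiked at known molecule-level allele fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from qaseq.errors import DomainError
from qaseq.io import open_text, metadata_header
from qaseq.panel import Panel

# Default pg of DNA per haploid human genome; chosen so that 10 ng of
# input corresponds to exactly 2,790 haploid copies.
HAPLOID_GENOME_MASS_PG = 3.584

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# ASCII code -> 0..3 lookup (A,C,G,T); other codes map to 0 but are never hit.
_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

PHRED33_Q30 = "?"


def mass_to_copies(mass_ng: float, haploid_genome_mass_pg: float = HAPLOID_GENOME_MASS_PG) -> int:
    """Expected haploid genome copies contained in ``mass_ng`` of DNA."""
    if mass_ng <= 0 or haploid_genome_mass_pg <= 0:
        raise DomainError("mass_to_copies requires positive mass arguments")
    return round(mass_ng * 1000.0 / haploid_genome_mass_pg)


@dataclass(frozen=True)
class SpikedVariant:
    """A variant planted at known molecule-level allele fraction."""

    module_id: str
    offset: int
    alt_base: str
    vaf: float


@dataclass
class SimConfig:
    """Parameters of one simulated sequencing run.

    Exactly one of ``input_mass_ng`` / ``input_copies`` must be set.
    ``pcr_cycles`` counts all post-barcoding cycles; the first
    ``high_efficiency_cycles`` of them duplicate deterministically and
    the rest follow branching with success probability drawn uniformly
    in ``per_cycle_efficiency ± efficiency_jitter`` per family per
    cycle (clipped to [0, 1]).
    """

    input_mass_ng: float | None = None
    input_copies: int | None = None
    haploid_genome_mass_pg: float = HAPLOID_GENOME_MASS_PG
    ploidy_map: dict[str, float] = field(default_factory=dict)
    conversion_yield: float = 0.86
    pcr_cycles: int = 12
    per_cycle_efficiency: float = 0.9
    high_efficiency_cycles: int = 3
    efficiency_jitter: float = 0.1
    mean_depth_per_module: float = 90000.0
    per_base_error_rate: float = 0.002
    off_target_fraction: float = 0.4
    spiked_variants: list[SpikedVariant] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_mass_ng is None) == (self.input_copies is None):
            raise DomainError("exactly one of input_mass_ng / input_copies must be set")
        for name in ("conversion_yield", "per_base_error_rate", "off_target_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise DomainError(f"{name} must be in [0, 1], got {value}")
        if self.off_target_fraction >= 1.0:
            raise DomainError("off_target_fraction must be < 1")
        if not 0.0 < self.per_cycle_efficiency <= 1.0:
            raise DomainError("per_cycle_efficiency must be in (0, 1]")
        if self.pcr_cycles < 0:
            raise DomainError("pcr_cycles must be >= 0")
        if not 0 <= self.high_efficiency_cycles <= self.pcr_cycles:
            raise DomainError("high_efficiency_cycles must be in [0, pcr_cycles]")
        for sv in self.spiked_variants:
            if not 0.0 <= sv.vaf <= 1.0:
                raise DomainError(f"spiked VAF must be in [0, 1], got {sv.vaf}")

    @property
    def expected_copies(self) -> float:
        if self.input_copies is not None:
            return float(self.input_copies)
        return float(mass_to_copies(self.input_mass_ng, self.haploid_genome_mass_pg))

    def gene_ploidy(self, gene: str) -> float:
        return float(self.ploidy_map.get(gene, 2.0))


@dataclass
class ModuleTruth:
    """Ground truth for one module in one simulated run."""

    module_id: str
    true_input_molecules: int
    true_barcoded_molecules: int
    family_sizes: np.ndarray  # pre-sequencing copy count per family
    reads_per_family: np.ndarray  # multinomial read allocation


@dataclass
class SimTruth:
    """Run-level ground truth emitted alongside the FASTQ."""

    modules: dict[str, ModuleTruth]
    # (module_id, offset, alt_base) -> number of barcoded alt families
    variant_alt_families: dict[tuple[int | str, ...], int]
    n_on_target_reads: int
    n_off_target_reads: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mt in self.modules.values():
            rows.append(
                {
                    "record": "module",
                    "module_id": mt.module_id,
                    "true_input_molecules": mt.true_input_molecules,
                    "true_barcoded_molecules": mt.true_barcoded_molecules,
                    "family_sizes": ",".join(map(str, mt.family_sizes.tolist())),
                    "detail": ".",
                }
            )
        for (module_id, offset, alt), count in self.variant_alt_families.items():
            rows.append(
                {
                    "record": "variant",
                    "module_id": module_id,
                    "true_input_molecules": 0,
                    "true_barcoded_molecules": count,
                    "family_sizes": ".",
                    "detail": f"{offset}:{alt}",
                }
            )
        rows.append(
            {
                "record": "reads",
                "module_id": ".",
                "true_input_molecules": self.n_on_target_reads,
                "true_barcoded_molecules": self.n_off_target_reads,
                "family_sizes": ".",
                "detail": "on_target,off_target",
            }
        )
        return pd.DataFrame(rows)

    def write(self, path: str | Path, seed: int | None = None) -> None:
        with open_text(path, "wt") as handle:
            handle.write(metadata_header("simulate-truth", {"seed": seed}) + "\n")
            self.to_frame().to_csv(handle, sep="\t", index=False)


def sample_input_molecules(
    cfg: SimConfig, panel: Panel, rng: np.random.Generator | None = None
) -> dict[str, int]:
    """Draw Poisson input-molecule counts for every module.

    The Poisson mean for a module in gene *g* is
    ``expected_copies × ploidy(g) / 2`` (haploid copies scale with half
    the gene ploidy).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    counts: dict[str, int] = {}
    for module in panel.modules:
        mean = cfg.expected_copies * cfg.gene_ploidy(module.gene) / 2.0
        counts[module.module_id] = int(rng.poisson(mean)) if mean > 0 else 0
    return counts


def _random_umis(n: int, length: int, rng: np.random.Generator) -> list[str]:
    if n == 0:
        return []
    codes = rng.integers(0, 4, size=(n, length), dtype=np.uint8)
    flat = _BASES[codes]
    return [bytes(row).decode("ascii") for row in flat]


def attach_umis(
    counts: Mapping[str, int], cfg: SimConfig, panel: Panel, rng: np.random.Generator | None = None
) -> dict[str, list[str]]:
    """Barcode each input molecule with probability ``conversion_yield``.

    UMIs are drawn uniformly over 4^umi_length; collisions are allowed
    (and negligible at the default UMI length).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    out: dict[str, list[str]] = {}
    for module_id, n in counts.items():
        n_barcoded = int(rng.binomial(n, cfg.conversion_yield)) if n > 0 else 0
        out[module_id] = _random_umis(n_barcoded, panel.umi_length, rng)
    return out


def amplify_families(n: int, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Vectorized branching-process amplification of ``n`` families."""
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    sizes = np.ones(n, dtype=np.int64)
    sizes <<= cfg.high_efficiency_cycles
    stochastic_cycles = cfg.pcr_cycles - cfg.high_efficiency_cycles
    eff, jitter = cfg.per_cycle_efficiency, cfg.efficiency_jitter
    for _ in range(stochastic_cycles):
        if jitter > 0:
            e = np.clip(rng.uniform(eff - jitter, eff + jitter, size=n), 0.0, 1.0)
        else:
            e = eff
        sizes = sizes + rng.binomial(sizes, e)
    return sizes


def amplify_family(cfg: SimConfig, rng: np.random.Generator | None = None) -> int:
    """Amplify a single barcoded molecule; returns the final copy count.

    With ``high_efficiency_cycles=0`` and ``efficiency_jitter=0`` this is
    a pure Galton–Watson process with mean (1 + efficiency)^cycles.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    return int(amplify_families(1, cfg, rng)[0])


def expected_family_size(cfg: SimConfig) -> float:
    """Mean of the amplification process (jitter is mean-preserving)."""
    h = cfg.high_efficiency_cycles
    return 2.0**h * (1.0 + cfg.per_cycle_efficiency) ** (cfg.pcr_cycles - h)


def _apply_errors(reads: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute bases in-place with probability ``rate`` per base."""
    if rate <= 0 or reads.size == 0:
        return reads
    mask = rng.random(reads.shape) < rate
    idx = np.nonzero(mask)
    if idx[0].size:
        old = _CODE[reads[idx]]
        new = (old + rng.integers(1, 4, size=old.shape, dtype=np.uint8)) % 4
        reads[idx] = _BASES[new]
    return reads


def simulate_run(
    cfg: SimConfig,
    panel: Panel,
    out_fastq: str | Path | None = None,
    out_truth: str | Path | None = None,
) -> SimTruth:
    """Simulate one sequencing run; returns ground truth, writes FASTQ/truth.

    Read layout (single-end): ``[UMI][fwd_primer][amplicon_seq]`` with
    per-base substitution errors applied to the whole read.  Spiked
    variants are assigned at the *molecule* level: every read of an alt
    family carries the alt base pre-error.  Fully reproducible given
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    input_counts = sample_input_molecules(cfg, panel, rng)
    umis = attach_umis(input_counts, cfg, panel, rng)

    spiked_by_module: dict[str, list[SpikedVariant]] = {}
    for sv in cfg.spiked_variants:
        spiked_by_module.setdefault(sv.module_id, []).append(sv)

    module_truth: dict[str, ModuleTruth] = {}
    variant_truth: dict[tuple[int | str, ...], int] = {}
    fastq_chunks: list[str] = []
    read_index = 0
    n_on_target = 0
    read_lengths: list[int] = []

    for module in panel.modules:
        module_umis = umis[module.module_id]
        n_families = len(module_umis)
        sizes = amplify_families(n_families, cfg, rng)

        # molecule-level variant assignment: which families are alt
        amplicon = module.amplicon_seq
        alt_sequences: dict[int, str] = {}  # family index -> mutated amplicon
        for sv in spiked_by_module.get(module.module_id, ()):
            expected_alt = sv.vaf * n_families
            if 0 < expected_alt < 1:
                import warnings

                warnings.warn(
                    f"spiked variant {sv.module_id}:{sv.offset}{sv.alt_base} expects "
                    f"{expected_alt:.2f} < 1 alt molecules; it may be absent",
                    stacklevel=2,
                )
            alt_flags = rng.random(n_families) < sv.vaf
            n_alt = int(alt_flags.sum())
            variant_truth[(module.module_id, sv.offset, sv.alt_base)] = n_alt
            for fam_idx in np.nonzero(alt_flags)[0]:
                base_seq = alt_sequences.get(int(fam_idx), amplicon)
                alt_sequences[int(fam_idx)] = (
                    base_seq[: sv.offset] + sv.alt_base + base_seq[sv.offset + 1 :]
                )

        # sequencing-depth allocation: multinomial over relative family sizes
        if n_families > 0 and sizes.sum() > 0:
            n_reads = int(round(cfg.mean_depth_per_module))
            reads_per_family = rng.multinomial(n_reads, sizes / sizes.sum())
        else:
            reads_per_family = np.zeros(n_families, dtype=np.int64)

        module_truth[module.module_id] = ModuleTruth(
            module_id=module.module_id,
            true_input_molecules=input_counts[module.module_id],
            true_barcoded_molecules=n_families,
            family_sizes=sizes,
            reads_per_family=reads_per_family,
        )

        if reads_per_family.sum() == 0:
            continue

        # build one template row per family: UMI + primer + (possibly alt) insert
        suffix = module.fwd_primer + amplicon
        read_len = panel.umi_length + len(suffix)
        templates = np.empty((n_families, read_len), dtype=np.uint8)
        suffix_arr = np.frombuffer(suffix.encode("ascii"), dtype=np.uint8)
        for fam_idx, umi in enumerate(module_umis):
            templates[fam_idx, : panel.umi_length] = np.frombuffer(
                umi.encode("ascii"), dtype=np.uint8
            )
            if fam_idx in alt_sequences:
                alt_suffix = module.fwd_primer + alt_sequences[fam_idx]
                templates[fam_idx, panel.umi_length :] = np.frombuffer(
                    alt_suffix.encode("ascii"), dtype=np.uint8
                )
            else:
                templates[fam_idx, panel.umi_length :] = suffix_arr

        reads = np.repeat(templates, reads_per_family, axis=0)
        _apply_errors(reads, cfg.per_base_error_rate, rng)
        qual = PHRED33_Q30 * read_len
        payload = reads.tobytes().decode("ascii")
        for row in range(reads.shape[0]):
            seq = payload[row * read_len : (row + 1) * read_len]
            fastq_chunks.append(f"@qsim.{read_index}\n{seq}\n+\n{qual}\n")
            read_index += 1
        n_on_target += int(reads.shape[0])
        read_lengths.append(read_len)

    # off-target / dimer reads: random primer regions, unassignable downstream
    f_off = cfg.off_target_fraction
    n_off = int(round(n_on_target * f_off / (1.0 - f_off))) if f_off > 0 else 0
    if n_off > 0:
        off_len = int(np.median(read_lengths)) if read_lengths else panel.umi_length + 40
        codes = rng.integers(0, 4, size=(n_off, off_len), dtype=np.uint8)
        off_reads = _BASES[codes]
        qual = PHRED33_Q30 * off_len
        payload = off_reads.tobytes().decode("ascii")
        for row in range(n_off):
            seq = payload[row * off_len : (row + 1) * off_len]
            fastq_chunks.append(f"@qsim.{read_index}\n{seq}\n+\n{qual}\n")
            read_index += 1

    truth = SimTruth(
        modules=module_truth,
        variant_alt_families=variant_truth,
        n_on_target_reads=n_on_target,
        n_off_target_reads=n_off,
    )

    if out_fastq is not None:
        with open_text(out_fastq, "wt") as handle:
            handle.write("".join(fastq_chunks))
    if out_truth is not None:
        truth.write(out_truth, seed=cfg.seed)
    return truth


def simulate_count_tables(
    cfg: SimConfig, panel: Panel, n_replicates: int, rng: np.random.Generator | None = None
) -> list[dict[str, int]]:
    """Counts-level replicate simulation (no reads).

    Draws Poisson input molecules and binomial barcoding per module for
    ``n_replicates`` independent libraries, returning per-replicate
    molecule-count maps.  Used for precision studies (CV vs module
    count, LoD, replicate discrimination) where only molecule counts
    matter; the read-level path is :func:`simulate_run`.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    tables = []
    for _ in range(n_replicates):
        counts = sample_input_molecules(cfg, panel, rng)
        tables.append(
            {
                module_id: int(rng.binomial(n, cfg.conversion_yield)) if n > 0 else 0
                for module_id, n in counts.items()
            }
        )
    return tables


def read_truth(path: str | Path) -> tuple[dict[str, dict], dict[tuple, int]]:
    """Load a truth TSV back into per-module and per-variant dictionaries."""
    from qaseq.io import read_table

    frame = read_table(path, dtype=str)
    modules: dict[str, dict] = {}
    variants: dict[tuple, int] = {}
    for row in frame.itertuples(index=False):
        if row.record == "module":
            sizes = (
                np.array([int(x) for x in row.family_sizes.split(",")], dtype=np.int64)
                if row.family_sizes not in (".", "")
                else np.zeros(0, dtype=np.int64)
            )
            modules[row.module_id] = {
                "true_input_molecules": int(row.true_input_molecules),
                "true_barcoded_molecules": int(row.true_barcoded_molecules),
                "family_sizes": sizes,
            }
        elif row.record == "variant":
            offset_str, alt = row.detail.split(":")
            variants[(row.module_id, int(offset_str), alt)] = int(row.true_barcoded_molecules)
    return modules, variants
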