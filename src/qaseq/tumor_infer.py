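"""cfDNA mixture model: forward ploidy/VAF mixing and tumor-ploidy inversion.

Plasma cfDNA is modeled as a mixture of tumor-derived DNA (one or more
clones) and normal DNA at ploidy 2.  Forward:

    ploidy(cfDNA) = sum_i ploidy_i * f_i + 2 * (1 - sum_i f_i)
    vaf(cfDNA)    = sum_i vaf_i * f_i

Inversion assumes a single clone whose mutation is monoallelic
(VAF in pure tumor = 50%), so tumor fraction = 2 × cfDNA VAF, and

    ploidy(tumor) = (ploidy(cfDNA) - 2 * (1 - f)) / f.

If the mutation is actually biallelic the inferred fraction is exactly
2-fold the truth, and the inferred ploidy is within two-fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from qaseq.errors import DomainError

# VAF window for trusting a somatic mutation as a tumor-fraction anchor
# (avoids germline SNPs at ~50% and noise near 0).
DEFAULT_VAF_WINDOW = (0.01, 0.30)


@dataclass
class TumorMixture:
    """Multi-clone tumor/normal cfDNA mixture (forward model only)."""

    clone_fractions: list[float] = field(default_factory=list)
    clone_ploidies: list[float] = field(default_factory=list)
    clone_vafs: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.clone_fractions)
        if len(self.clone_ploidies) != n or len(self.clone_vafs) != n:
            raise DomainError("clone lists must have equal length")
        if any(f < 0 or f > 1 for f in self.clone_fractions):
            raise DomainError("clone fractions must be in [0, 1]")
        if sum(self.clone_fractions) > 1 + 1e-12:
            raise DomainError("clone fractions must sum to <= 1")
        if any(p < 0 for p in self.clone_ploidies):
            raise DomainError("clone ploidies must be >= 0")
        if any(v < 0 or v > 1 for v in self.clone_vafs):
            raise DomainError("clone VAFs must be in [0, 1]")


def cfdna_ploidy_forward(tumor_ploidy: float, tumor_fraction: float) -> float:
    """Single-clone forward mixture: tumor ploidy diluted into normal DNA."""
    if not 0.0 <= tumor_fraction <= 1.0:
        raise DomainError("tumor_fraction must be in [0, 1]")
    if tumor_ploidy < 0:
        raise DomainError("tumor_ploidy must be >= 0")
    return tumor_ploidy * tumor_fraction + 2.0 * (1.0 - tumor_fraction)


def cfdna_forward_multiclone(mix: TumorMixture) -> tuple[float, float]:
    """Forward mixture over clones: returns (cfDNA ploidy, cfDNA VAF)."""
    total_fraction = sum(mix.clone_fractions)
    ploidy = (
        sum(p * f for p, f in zip(mix.clone_ploidies, mix.clone_fractions))
        + 2.0 * (1.0 - total_fraction)
    )
    vaf = sum(v * f for v, f in zip(mix.clone_vafs, mix.clone_fractions))
    return ploidy, vaf


def tumor_fraction_from_vaf(cfdna_vaf: float) -> float:
    """Tumor fraction under the monoallelic (pure-tumor VAF = 50%) assumption.

    If the mutation is biallelic the result is 2-fold the true fraction.
    """
    if not 0.0 <= cfdna_vaf <= 0.5:
        raise DomainError(
            "cfdna_vaf must be in [0, 0.5]; higher values imply a germline or "
            "biallelic variant for which the inversion is invalid"
        )
    return 2.0 * cfdna_vaf


@dataclass
class TumorInference:
    tumor_fraction: float
    tumor_ploidy: float
    valid: bool
    notes: tuple[str, ...] = ()


def infer_tumor_ploidy(
    cfdna_ploidy: float,
    cfdna_vaf: float,
    vaf_window: tuple[float, float] = DEFAULT_VAF_WINDOW,
) -> TumorInference:
    """Invert the single-clone mixture to recover tumor gene ploidy.

    ``vaf_window`` marks the VAF range within which the anchoring
    mutation is trusted; outside it the result is still computed but
    annotated.  A negative inferred ploidy flags inconsistent inputs
    rather than being clamped.
    """
    if cfdna_ploidy < 0:
        raise DomainError("cfdna_ploidy must be non-negative")
    if cfdna_vaf <= 0:
        raise DomainError("cfdna_vaf must be positive (no tumor signal at 0)")
    fraction = tumor_fraction_from_vaf(cfdna_vaf)
    ploidy = (cfdna_ploidy - 2.0 * (1.0 - fraction)) / fraction
    notes = ["single-clone monoallelic model; inferred ploidy within two-fold of truth"]
    valid = True
    if not vaf_window[0] <= cfdna_vaf <= vaf_window[1]:
        notes.append(
            f"cfDNA VAF {cfdna_vaf:.4f} outside trusted window "
            f"[{vaf_window[0]}, {vaf_window[1]}]"
        )
    if ploidy < 0:
        valid = False
        notes.append("negative inferred ploidy: cfDNA ploidy/VAF inputs are inconsistent")
    return TumorInference(
        tumor_fraction=fraction, tumor_ploidy=ploidy, valid=valid, notes=tuple(notes)
    )
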