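"""UMI-consensus mutation calling at the molecule (family) level.

Each size-filtered family is collapsed to a consensus sequence (modal
base per position, N when concordance drops below a threshold); variants
are then counted in units of families, so VAF = alt families / total
non-N families at the locus.  This is what UMI error correction buys:
a sequencing error must dominate a whole family to survive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from qaseq.errors import DomainError
from qaseq.panel import Panel
from qaseq.umi_quant import BASE_ORDER, UmiFamily


@dataclass
class ConsensusFamily:
    module_id: str
    umi: str
    consensus_seq: str
    min_position_concordance: float


def family_consensus(family: UmiFamily, min_concordance: float = 0.8) -> ConsensusFamily:
    """Collapse a family to its consensus sequence.

    Per position the consensus is the modal base if its fraction of the
    family size reaches ``min_concordance``; otherwise N.  Positions not
    covered by any read are N.
    """
    counts = family.base_counts
    if counts.size == 0:
        return ConsensusFamily(family.module_id, family.umi, "", 1.0)
    modal_idx = np.argmax(counts[:, :4], axis=1)
    modal_count = counts[np.arange(counts.shape[0]), modal_idx]
    frac = modal_count / family.size
    bases = np.array(list("ACGT"))[modal_idx]
    bases[frac < min_concordance] = "N"
    covered = frac[modal_count > 0]
    min_conc = float(covered.min()) if covered.size else 0.0
    return ConsensusFamily(
        module_id=family.module_id,
        umi=family.umi,
        consensus_seq="".join(bases),
        min_position_concordance=min_conc,
    )


@dataclass
class VariantCall:
    module_id: str
    offset: int
    ref_base: str
    alt_base: str
    alt_families: int
    total_families: int

    @property
    def vaf(self) -> float:
        return self.alt_families / self.total_families if self.total_families else 0.0


def call_variants(
    consensus_families: Sequence[ConsensusFamily],
    panel: Panel,
    min_alt_families: int = 3,
) -> list[VariantCall]:
    """Call substitutions from family consensus sequences.

    For every (module, offset, alt base) the number of families whose
    consensus carries the alt base is counted against the total non-N
    families at that offset; calls are emitted when the alt-family count
    reaches ``min_alt_families``.
    """
    by_module: dict[str, list[ConsensusFamily]] = {}
    for fam in consensus_families:
        by_module.setdefault(fam.module_id, []).append(fam)
    calls: list[VariantCall] = []
    for module in panel.modules:
        fams = by_module.get(module.module_id)
        if not fams:
            continue
        ref = module.amplicon_seq
        length = len(ref)
        matrix = np.full((len(fams), length), b"N"[0], dtype=np.uint8)
        for i, fam in enumerate(fams):
            seq = fam.consensus_seq[:length]
            matrix[i, : len(seq)] = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        ref_arr = np.frombuffer(ref.encode("ascii"), dtype=np.uint8)
        n_code = ord("N")
        non_n = matrix != n_code
        totals = non_n.sum(axis=0)
        is_alt = non_n & (matrix != ref_arr[np.newaxis, :])
        alt_positions = np.nonzero(is_alt.sum(axis=0) >= min_alt_families)[0]
        for pos in alt_positions:
            column = matrix[is_alt[:, pos], pos]
            for alt_code in np.unique(column):
                n_alt = int((column == alt_code).sum())
                if n_alt >= min_alt_families:
                    calls.append(
                        VariantCall(
                            module_id=module.module_id,
                            offset=int(pos),
                            ref_base=chr(ref_arr[pos]),
                            alt_base=chr(alt_code),
                            alt_families=n_alt,
                            total_families=int(totals[pos]),
                        )
                    )
    return calls


def variants_to_frame(calls: Sequence[VariantCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "module_id": c.module_id,
                "offset": c.offset,
                "ref": c.ref_base,
                "alt": c.alt_base,
                "alt_families": c.alt_families,
                "total_families": c.total_families,
                "vaf": c.vaf,
            }
            for c in calls
        ],
        columns=["module_id", "offset", "ref", "alt", "alt_families", "total_families", "vaf"],
    )


def vaf_fold_change(vaf_t1: float, vaf_t0: float) -> float:
    """Fold change of VAF between two time points (t1 relative to t0)."""
    if vaf_t0 < 0 or vaf_t1 < 0:
        raise DomainError("VAFs must be non-negative")
    if vaf_t0 == 0:
        warnings.warn("baseline VAF is zero; fold change is infinite", stacklevel=2)
        return math.inf
    return vaf_t1 / vaf_t0
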