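"""Shared fixtures: synthetic panels and small simulated runs."""

from __future__ import annotations

import numpy as np
import pytest

from qaseq.panel import Panel, QuantModule

_BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def build_panel(
    seed: int = 11,
    gene_spec: list[tuple[str, str, int]] | None = None,
    primer_len: int = 15,
    amplicon_len: int = 30,
    umi_length: int = 12,
) -> Panel:
    """Build a synthetic panel from (gene, role, n_modules) triples."""
    rng = np.random.default_rng(seed)
    if gene_spec is None:
        gene_spec = [("TG1", "target", 3), ("REFA", "reference", 2), ("REFB", "reference", 2)]
    modules = []
    used_primers: set[str] = set()
    for gene, role, n in gene_spec:
        for i in range(n):
            while True:
                fwd = random_seq(rng, primer_len)
                if fwd not in used_primers:
                    used_primers.add(fwd)
                    break
            modules.append(
                QuantModule(
                    module_id=f"{gene}.{i}",
                    gene=gene,
                    role=role,
                    chromosome="chrS",
                    amplicon_start=1000 * len(modules),
                    amplicon_end=1000 * len(modules) + amplicon_len,
                    fwd_primer=fwd,
                    rev_primer=random_seq(rng, primer_len),
                    amplicon_seq=random_seq(rng, amplicon_len),
                )
            )
    return Panel(modules=modules, umi_length=umi_length)


@pytest.fixture
def small_panel() -> Panel:
    """8-module fixture: 3-module target gene, 4 reference, 1 excluded."""
    return build_panel(
        seed=11,
        gene_spec=[
            ("TG1", "target", 3),
            ("REFA", "reference", 2),
            ("REFB", "reference", 2),
            ("XG", "excluded", 1),
        ],
    )


@pytest.fixture(scope="session")
def cnv_panel() -> Panel:
    """49 target + 123 reference module panel mirroring the CNV design."""
    return build_panel(seed=23, gene_spec=[("ERBB2", "target", 49), ("REF", "reference", 123)])
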