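"""Targeted RNA expression: yield-adjusted gene counts and log2 normalization.

Per-gene expression is the mean of yield-adjusted amplicon molecule
counts, normalized to the reference genes in log2 scale:
expr(g) = log2(count_g) − mean_r log2(count_r), i.e. relative to the
geometric mean of the reference-gene counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from qaseq.errors import DomainError


def gene_count(amplicon_counts: Sequence[float], yields: Sequence[float] | None = None) -> float:
    """Gene-level count: mean over amplicons of count / conversion yield."""
    counts = np.asarray(amplicon_counts, dtype=float)
    if counts.size == 0:
        raise DomainError("gene_count requires at least one amplicon count")
    if yields is None:
        adjusted = counts
    else:
        y = np.asarray(yields, dtype=float)
        if y.shape != counts.shape:
            raise DomainError("counts and yields must have equal length")
        if (y <= 0).any() or (y > 1).any():
            raise DomainError("yields must be in (0, 1]")
        adjusted = counts / y
    return float(adjusted.mean())


def relative_log2(
    gene_counts: Mapping[str, float], reference_genes: set[str] | Sequence[str]
) -> dict[str, float]:
    """log2 expression relative to the geometric mean of reference genes.

    Genes with non-positive counts are excluded with a warning and
    reported as missing from the result.
    """
    reference_genes = set(reference_genes)
    if not reference_genes:
        raise DomainError("reference gene set must be nonempty")
    missing = reference_genes - set(gene_counts)
    if missing:
        raise DomainError(f"reference gene(s) absent from counts: {sorted(missing)}")
    for ref in reference_genes:
        if gene_counts[ref] <= 0:
            raise DomainError(f"reference gene {ref!r} has non-positive count")
    ref_log_mean = float(np.mean([math.log2(gene_counts[r]) for r in sorted(reference_genes)]))
    out: dict[str, float] = {}
    for gene, count in gene_counts.items():
        if count <= 0:
            warnings.warn(
                f"gene {gene!r} has non-positive count {count}; excluded from expression",
                stacklevel=2,
            )
            continue
        out[gene] = math.log2(count) - ref_log_mean
    return out


@dataclass
class ExpressionTable:
    """Per-gene expression results for one sample."""

    gene_counts: dict[str, float]
    log2_relative_expression: dict[str, float]
    n_amplicons: dict[str, int]
    reference_genes: set[str]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": gene,
                "n_amplicons": self.n_amplicons.get(gene, 0),
                "gene_count": self.gene_counts[gene],
                "log2_relative_expression": self.log2_relative_expression.get(gene, np.nan),
                "is_reference": gene in self.reference_genes,
            }
            for gene in sorted(self.gene_counts)
        ]
        return pd.DataFrame(rows)


def expression_table(
    amplicon_counts_by_gene: Mapping[str, Sequence[float]],
    reference_genes: set[str] | Sequence[str],
    yields_by_gene: Mapping[str, Sequence[float]] | None = None,
) -> ExpressionTable:
    """Build a per-gene expression table from per-amplicon molecule counts."""
    counts = {
        gene: gene_count(
            vals, None if yields_by_gene is None else yields_by_gene.get(gene)
        )
        for gene, vals in amplicon_counts_by_gene.items()
    }
    expr = relative_log2(counts, reference_genes)
    return ExpressionTable(
        gene_counts=counts,
        log2_relative_expression=expr,
        n_amplicons={g: len(v) for g, v in amplicon_counts_by_gene.items()},
        reference_genes=set(reference_genes),
    )


def replicate_sd_vs_amplicons(
    replicate_amplicon_counts: Sequence[Mapping[str, Sequence[float]]],
    reference_genes: set[str] | Sequence[str],
    m_values: Sequence[int],
) -> tuple[dict[int, dict[str, float]], dict[int, float]]:
    """Replicate SD of relative expression as amplicons per gene increase.

    For each m, expression is recomputed with only the first m amplicons
    per gene (amplicon lists are ordered 5'→3', so this keeps the
    5'-most amplicons); genes with fewer than m amplicons are skipped
    with a warning.  Returns ({m: {gene: sd}}, {m: median sd}).
    """
    if len(replicate_amplicon_counts) < 2:
        raise DomainError("replicate_sd_vs_amplicons requires at least 2 replicates")
    reference_genes = set(reference_genes)
    sd_by_m: dict[int, dict[str, float]] = {}
    median_by_m: dict[int, float] = {}
    for m in m_values:
        per_replicate_expr: list[dict[str, float]] = []
        for rep in replicate_amplicon_counts:
            usable = {}
            for gene, vals in rep.items():
                if len(vals) < m:
                    if gene not in reference_genes:
                        warnings.warn(
                            f"gene {gene!r} has {len(vals)} < {m} amplicons; skipped",
                            stacklevel=2,
                        )
                        continue
                    usable[gene] = gene_count(vals)
                else:
                    usable[gene] = gene_count(list(vals)[:m])
            per_replicate_expr.append(relative_log2(usable, reference_genes))
        common = set.intersection(*(set(e) for e in per_replicate_expr))
        sds = {
            gene: float(np.std([e[gene] for e in per_replicate_expr], ddof=1))
            for gene in sorted(common)
            if gene not in reference_genes
        }
        sd_by_m[m] = sds
        median_by_m[m] = float(np.median(list(sds.values()))) if sds else math.nan
    return sd_by_m, median_by_m


def dynamic_range_check(
    expected: Sequence[float], observed: Sequence[float]
) -> tuple[float, float]:
    """Slope and Pearson correlation of log10(observed) vs log10(expected).

    Non-positive pairs are excluded pairwise; requires >= 5 usable pairs
    spanning at least two decades of expected counts.
    """
    exp = np.asarray(expected, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if exp.shape != obs.shape:
        raise DomainError("expected and observed must have equal length")
    keep = (exp > 0) & (obs > 0)
    exp, obs = exp[keep], obs[keep]
    if exp.size < 5:
        raise DomainError("dynamic_range_check requires >= 5 positive pairs")
    lx, ly = np.log10(exp), np.log10(obs)
    if lx.max() - lx.min() < 2.0:
        raise DomainError("expected counts must span at least 2 decades")
    if np.std(ly) == 0:
        raise DomainError("observed counts are constant; correlation undefined")
    fit = stats.linregress(lx, ly)
    return float(fit.slope), float(fit.rvalue)
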