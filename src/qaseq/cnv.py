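"""Ploidy estimation, rank-test CNV calling and stochastic-precision analysis.

Gene ploidy is 2 × the ratio of mean molecule counts between the gene's
modules and the reference modules.  CNVs are called by ordered
Mann–Whitney U tests of per-module ploidies against the reference
modules, with Benjamini–Hochberg correction; genes without a
significant difference are reported at exactly 2.00.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from qaseq.errors import DomainError
from qaseq.panel import Panel, testable_genes
from qaseq.umi_quant import MoleculeCountTable


def equivalent_assay_count(n_modules: int) -> int:
    """Number of distinct pairwise assays spanned by an n-module panel."""
    if n_modules < 2:
        raise DomainError("equivalent_assay_count requires n >= 2")
    return n_modules * (n_modules - 1) // 2


def _reference_counts(counts: Mapping[str, int], panel: Panel) -> np.ndarray:
    ref_ids = panel.reference_module_ids
    return np.array([counts[mid] for mid in ref_ids if mid in counts], dtype=float)


def module_ploidy(counts: MoleculeCountTable | Mapping[str, int], panel: Panel) -> dict[str, float]:
    """Per-module ploidy: 2 × count / mean(reference counts)."""
    count_map = counts.counts() if isinstance(counts, MoleculeCountTable) else dict(counts)
    ref = _reference_counts(count_map, panel)
    if ref.size == 0 or ref.mean() <= 0:
        raise DomainError("reference modules have zero mean molecule count")
    ref_mean = ref.mean()
    return {
        m.module_id: 2.0 * count_map[m.module_id] / ref_mean
        for m in panel.modules
        if m.module_id in count_map
    }


def gene_ploidy(
    counts: MoleculeCountTable | Mapping[str, int], panel: Panel, gene: str
) -> float:
    """Gene ploidy: 2 × mean(gene module counts) / mean(reference counts)."""
    count_map = counts.counts() if isinstance(counts, MoleculeCountTable) else dict(counts)
    gene_modules = [
        m for m in panel.modules if m.gene == gene and m.role != "excluded"
    ]
    if not gene_modules:
        raise DomainError(f"gene {gene!r} has no non-excluded modules")
    ref = _reference_counts(count_map, panel)
    if ref.size == 0 or ref.mean() <= 0:
        raise DomainError("reference modules have zero mean molecule count")
    gene_counts = np.array([count_map[m.module_id] for m in gene_modules], dtype=float)
    return 2.0 * gene_counts.mean() / ref.mean()


def mw_test_gene(
    gene_ploidies: Sequence[float],
    reference_ploidies: Sequence[float],
    min_modules: int = 3,
) -> float:
    """Two-sided Mann–Whitney U p-value of gene vs reference module ploidies.

    Uses the exact null distribution when both samples have <= 8
    observations and no ties; otherwise the normal approximation with
    tie correction.  Refuses to test genes with fewer than
    ``min_modules`` module ploidies.
    """
    x = np.asarray(gene_ploidies, dtype=float)
    y = np.asarray(reference_ploidies, dtype=float)
    if x.size < min_modules:
        raise DomainError(
            f"gene has {x.size} modules; at least {min_modules} required for the rank test"
        )
    if y.size < 1:
        raise DomainError("reference ploidy sample is empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) else "asymptotic"
    result = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(result.pvalue)
    return min(p, 1.0) if math.isfinite(p) else 1.0


@dataclass
class PloidyCall:
    gene: str
    n_modules: int
    ploidy_estimate: float
    p_value: float
    adjusted_p: float
    call: str  # loss | neutral | gain
    reported_ploidy: float


def call_cnvs(
    counts: MoleculeCountTable | Mapping[str, int],
    panel: Panel,
    alpha: float = 0.05,
    correction: str = "bh",
) -> list[PloidyCall]:
    """Call per-gene CNVs with ordered rank tests against the reference.

    Procedure: (1) per-module ploidy against the full reference;
    (2) rank testable genes by |gene ploidy − 2| descending;
    (3) in that order, Mann–Whitney U test of the gene's module
    ploidies vs the (panel-fixed) reference module ploidies;
    (4) Benjamini–Hochberg correction across tested genes;
    (5) significant genes report their point estimate (gain if > 2,
    loss otherwise); everything else is reported at exactly 2.00.
    """
    count_map = counts.counts() if isinstance(counts, MoleculeCountTable) else dict(counts)
    per_module = module_ploidy(count_map, panel)
    by_gene = panel.modules_by_gene()
    ref_ids = panel.reference_module_ids
    ref_ploidies = [per_module[mid] for mid in ref_ids if mid in per_module]

    genes = sorted(testable_genes(panel))
    if not genes:
        import warnings

        warnings.warn("no testable genes in panel; returning no CNV calls", stacklevel=2)
        return []

    estimates = {g: gene_ploidy(count_map, panel, g) for g in genes}
    ordered = sorted(genes, key=lambda g: -abs(estimates[g] - 2.0))
    p_values = []
    for gene in ordered:
        ploidies = [per_module[m.module_id] for m in by_gene[gene] if m.module_id in per_module]
        p_values.append(
            mw_test_gene(ploidies, ref_ploidies, min_modules=panel.min_modules_per_gene_for_test)
        )
    if correction == "bh":
        adjusted = stats.false_discovery_control(p_values, method="bh")
    elif correction == "none":
        adjusted = np.asarray(p_values)
    else:
        raise DomainError(f"unknown correction {correction!r}")

    calls = []
    for gene, p, adj in zip(ordered, p_values, adjusted):
        estimate = estimates[gene]
        significant = adj < alpha
        if significant:
            call = "gain" if estimate > 2.0 else "loss"
            reported = estimate
        else:
            call = "neutral"
            reported = 2.00
        calls.append(
            PloidyCall(
                gene=gene,
                n_modules=len(by_gene[gene]),
                ploidy_estimate=float(estimate),
                p_value=float(p),
                adjusted_p=float(adj),
                call=call,
                reported_ploidy=float(reported),
            )
        )
    calls.sort(key=lambda c: c.gene)
    return calls


def calls_to_frame(calls: Sequence[PloidyCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": c.gene,
                "n_modules": c.n_modules,
                "ploidy_estimate": c.ploidy_estimate,
                "p_value": c.p_value,
                "adjusted_p": c.adjusted_p,
                "call": c.call,
                "reported_ploidy": c.reported_ploidy,
            }
            for c in calls
        ]
    )


@dataclass
class LodEstimate:
    mean_ploidy: float
    sd_ploidy: float
    lod_loss: float
    lod_gain: float
    k_sigma: float = 3.0


def lod_from_replicates(replicate_ploidies: Sequence[float], k_sigma: float = 3.0) -> LodEstimate:
    """Limit of detection from technical replicates: mean ± k·sd (sample sd)."""
    values = np.asarray(replicate_ploidies, dtype=float)
    if values.size < 3:
        raise DomainError("lod_from_replicates requires at least 3 replicates")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return LodEstimate(
        mean_ploidy=mean,
        sd_ploidy=sd,
        lod_loss=mean - k_sigma * sd,
        lod_gain=mean + k_sigma * sd,
        k_sigma=k_sigma,
    )


@dataclass
class CvCurve:
    module_counts: list[int]
    cv: list[float]
    theoretical_cv: list[float]
    n_random_selections: int = 30

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_modules": self.module_counts,
                "cv": self.cv,
                "theoretical_cv": self.theoretical_cv,
            }
        )


def cv_vs_modules(
    replicate_counts: Sequence[MoleculeCountTable | Mapping[str, int]],
    panel: Panel,
    gene: str,
    m_values: Sequence[int],
    n_random: int = 30,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CvCurve:
    """Replicate CV of gene ploidy as a function of module-count m.

    For each m, ``n_random`` random m-module subsets of the gene's
    modules are drawn; gene ploidy is computed per replicate from the
    subset; the CV across replicates is averaged over draws.  The
    theoretical curve is the Poisson prediction
    sqrt(1/(m·N) + 1/(m_ref·N)) with N the mean molecule count per
    module.
    """
    if len(replicate_counts) < 2:
        raise DomainError("cv_vs_modules requires at least 2 replicates")
    rng = rng if rng is not None else np.random.default_rng(seed)
    count_maps = [
        c.counts() if isinstance(c, MoleculeCountTable) else dict(c) for c in replicate_counts
    ]
    gene_module_ids = [
        m.module_id for m in panel.modules if m.gene == gene and m.role != "excluded"
    ]
    ref_ids = sorted(panel.reference_module_ids)
    n_available = len(gene_module_ids)
    ref_means = [np.mean([cm[mid] for mid in ref_ids]) for cm in count_maps]

    all_counts = [cm[mid] for cm in count_maps for mid in cm]
    mean_count = float(np.mean(all_counts))
    m_ref = len(ref_ids)

    cvs: list[float] = []
    theory: list[float] = []
    for m in m_values:
        if m > n_available:
            raise DomainError(f"m={m} exceeds the {n_available} modules available for {gene!r}")
        draws = []
        for _ in range(n_random):
            chosen = rng.choice(n_available, size=m, replace=False)
            subset = [gene_module_ids[i] for i in chosen]
            ploidies = [
                2.0 * np.mean([cm[mid] for mid in subset]) / ref_mean
                for cm, ref_mean in zip(count_maps, ref_means)
            ]
            mean_p = np.mean(ploidies)
            draws.append(np.std(ploidies, ddof=1) / mean_p if mean_p > 0 else np.nan)
        cvs.append(float(np.nanmean(draws)))
        theory.append(math.sqrt(1.0 / (m * mean_count) + 1.0 / (m_ref * mean_count)))
    return CvCurve(
        module_counts=list(m_values), cv=cvs, theoretical_cv=theory, n_random_selections=n_random
    )


def chi_square_independence(
    table: Sequence[Sequence[int]], continuity: bool = False
) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2×2 table.

    No Yates continuity correction by default.  Returns (statistic,
    p-value) with df = 1.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise DomainError("chi_square_independence requires a non-negative 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DomainError("chi_square_independence requires positive margins")
    statistic, p, _dof, _exp = stats.chi2_contingency(arr, correction=continuity)
    return float(statistic), float(p)


def two_sample_t(
    group_a: Sequence[float], group_b: Sequence[float], equal_var: bool = True
) -> float:
    """Two-sided t-test p-value between two replicate groups.

    Pooled-variance (Student) by default: with tiny replicate groups
    (e.g. 4 vs 2 technical replicates) the Welch approximation has
    almost no power, and only the pooled test reproduces printed
    p-values at this design scale.  Pass ``equal_var=False`` for Welch.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError("two_sample_t requires at least 2 values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    result = stats.ttest_ind(a, b, equal_var=equal_var)
    p = float(result.pvalue)
    return p if math.isfinite(p) else 1.0
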