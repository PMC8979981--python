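import itertools
import math

import numpy as np
import pytest

from qaseq.cnv import (
    CvCurve,
    call_cnvs,
    chi_square_independence,
    cv_vs_modules,
    equivalent_assay_count,
    gene_ploidy,
    lod_from_replicates,
    module_ploidy,
    mw_test_gene,
    two_sample_t,
)
from qaseq.errors import DomainError
from qaseq.simulate import SimConfig, simulate_count_tables

from conftest import build_panel


def exact_mw_p_oracle(x, y):
    """Brute-force two-sided Mann-Whitney p by enumerating all rank splits."""
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    dist = []
    for combo in itertools.combinations(range(n1 + n2), n1):
        group = set(combo)
        u = sum(1 for i in group for j in range(n1 + n2) if j not in group and i > j)
        dist.append(u)
    dist = np.array(dist)
    p_le = np.mean(dist <= u_obs)
    p_ge = np.mean(dist >= u_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestEquivalentAssayCount:
    def test_printed_value(self):
        assert equivalent_assay_count(175) == 15225

    def test_minimal(self):
        assert equivalent_assay_count(2) == 1

    def test_liquid_biopsy_scale(self):
        assert equivalent_assay_count(223) == 223 * 222 // 2 == 24753

    def test_too_small(self):
        with pytest.raises(DomainError):
            equivalent_assay_count(1)


class TestPloidy:
    def test_module_ploidy_identity(self, small_panel):
        counts = {m.module_id: 100 for m in small_panel.modules}
        ploidies = module_ploidy(counts, small_panel)
        assert all(v == pytest.approx(2.0) for v in ploidies.values())

    def test_module_ploidy_linearity(self, small_panel):
        counts = {m.module_id: 100 for m in small_panel.modules}
        target = small_panel.modules[0].module_id
        counts[target] = 150
        # reference modules all still at 100
        assert module_ploidy(counts, small_panel)[target] == pytest.approx(3.0)

    def test_gene_ploidy_mean_of_modules(self, small_panel):
        counts = {m.module_id: 100 for m in small_panel.modules}
        tg_ids = [m.module_id for m in small_panel.modules if m.gene == "TG1"]
        for mid, c in zip(tg_ids, [110, 90, 100]):
            counts[mid] = c
        assert gene_ploidy(counts, small_panel, "TG1") == pytest.approx(2.00)

    def test_two_plex_equal_counts(self):
        panel = build_panel(seed=31, gene_spec=[("ERBB2", "target", 1), ("EIF2C1", "reference", 1)])
        counts = {"ERBB2.0": 2400, "EIF2C1.0": 2400}
        assert gene_ploidy(counts, panel, "ERBB2") == pytest.approx(2.00)

    def test_zero_reference_rejected(self, small_panel):
        counts = {m.module_id: 0 for m in small_panel.modules}
        with pytest.raises(DomainError):
            module_ploidy(counts, small_panel)

    def test_simulated_small_gain_recovered(self, cnv_panel):
        cfg = SimConfig(input_copies=2316, ploidy_map={"ERBB2": 2.05}, seed=32)
        tables = simulate_count_tables(cfg, cnv_panel, 10)
        estimates = [gene_ploidy(t, cnv_panel, "ERBB2") for t in tables]
        se = np.std(estimates, ddof=1) / math.sqrt(len(estimates))
        assert abs(np.mean(estimates) - 2.05) < 3 * se + 0.005


class TestMannWhitney:
    def test_identical_constant_samples(self):
        assert mw_test_gene([2.0, 2.0, 2.0], [2.0] * 20) == 1.0

    def test_clear_separation(self):
        reference = [2.0 + 0.001 * i for i in range(20)]
        p = mw_test_gene([3.0, 3.1, 2.9], reference)
        assert p < 0.01

    def test_refuses_below_min_modules(self):
        with pytest.raises(DomainError, match="at least 3"):
            mw_test_gene([3.0, 3.1], [2.0] * 20)

    @pytest.mark.parametrize("n1,n2", [(3, 3), (3, 6), (4, 5), (5, 5), (6, 6)])
    def test_exact_p_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(100 + 10 * n1 + n2)
        for _ in range(3):
            x = rng.normal(2.5, 0.5, size=n1)
            y = rng.normal(2.0, 0.5, size=n2)
            assert mw_test_gene(x, y) == pytest.approx(exact_mw_p_oracle(x, y), abs=1e-12)


class TestCallCnvs:
    def test_null_all_neutral(self, small_panel):
        rng = np.random.default_rng(33)
        counts = {m.module_id: int(rng.poisson(2000)) for m in small_panel.modules}
        calls = call_cnvs(counts, small_panel)
        assert len(calls) == 1
        assert calls[0].call == "neutral"
        assert calls[0].reported_ploidy == 2.00

    def test_strong_gain_called(self, cnv_panel):
        cfg = SimConfig(input_copies=2316, ploidy_map={"ERBB2": 6.0}, seed=34)
        table = simulate_count_tables(cfg, cnv_panel, 1)[0]
        calls = call_cnvs(table, cnv_panel)
        erbb2 = [c for c in calls if c.gene == "ERBB2"][0]
        assert erbb2.call == "gain"
        assert erbb2.reported_ploidy == pytest.approx(6.0, rel=0.05)
        assert all(c.call == "neutral" for c in calls if c.gene != "ERBB2")

    def test_loss_called(self, cnv_panel):
        cfg = SimConfig(input_copies=2316, ploidy_map={"ERBB2": 1.0}, seed=35)
        table = simulate_count_tables(cfg, cnv_panel, 1)[0]
        calls = call_cnvs(table, cnv_panel)
        erbb2 = [c for c in calls if c.gene == "ERBB2"][0]
        assert erbb2.call == "loss"
        assert erbb2.reported_ploidy == pytest.approx(1.0, rel=0.05)

    def test_two_module_gene_untestable(self):
        panel = build_panel(
            seed=36, gene_spec=[("G2", "target", 2), ("REF", "reference", 20)]
        )
        rng = np.random.default_rng(36)
        counts = {m.module_id: int(rng.poisson(2000)) for m in panel.modules}
        for m in panel.modules:
            if m.gene == "G2":
                counts[m.module_id] *= 3  # real CNV, but untestable
        with pytest.warns(UserWarning, match="no testable genes"):
            calls = call_cnvs(counts, panel)
        assert calls == []

    def test_neutral_iff_reported_two(self, cnv_panel):
        cfg = SimConfig(input_copies=2316, ploidy_map={"ERBB2": 2.3}, seed=37)
        table = simulate_count_tables(cfg, cnv_panel, 1)[0]
        for call in call_cnvs(table, cnv_panel):
            assert (call.call == "neutral") == (call.reported_ploidy == 2.00)

    def test_null_calibration(self):
        # fraction of genes called non-neutral under the null stays <= alpha
        panel = build_panel(
            seed=38,
            gene_spec=[(f"G{i}", "target", 5) for i in range(6)] + [("REF", "reference", 40)],
        )
        cfg = SimConfig(input_copies=2000, seed=38)
        rng = np.random.default_rng(38)
        tables = simulate_count_tables(cfg, panel, 50, rng)
        tested = rejected = 0
        for table in tables:
            for call in call_cnvs(table, panel, alpha=0.05):
                tested += 1
                rejected += call.call != "neutral"
        assert tested == 300
        assert rejected / tested <= 0.05

    def test_parameter_recovery(self):
        panel = build_panel(
            seed=39,
            gene_spec=[("G15", "target", 10), ("G22", "target", 10),
                       ("G30", "target", 10), ("G60", "target", 10),
                       ("REF", "reference", 60)],
        )
        truth = {"G15": 1.5, "G22": 2.2, "G30": 3.0, "G60": 6.0}
        cfg = SimConfig(input_copies=2300, ploidy_map=truth, conversion_yield=1.0, seed=39)
        table = simulate_count_tables(cfg, panel, 1)[0]
        for gene, expected in truth.items():
            assert gene_ploidy(table, panel, gene) == pytest.approx(expected, rel=0.05)


class TestLod:
    def test_zero_variance(self):
        lod = lod_from_replicates([2.00, 2.00, 2.00])
        assert (lod.lod_loss, lod.lod_gain) == (2.00, 2.00)

    def test_printed_cv_brackets(self):
        # direct formula oracle: mean 2.00, sd 0.0138 (CV 0.69%) ->
        # 2.00 -/+ 3 * 0.0138 = (1.959, 2.041) at 3 decimals
        values = [2.00 - 0.0138, 2.00, 2.00 + 0.0138]  # sample sd exactly 0.0138
        lod = lod_from_replicates(values)
        assert lod.sd_ploidy == pytest.approx(0.0138)
        assert round(lod.lod_loss, 3) == 1.959
        assert round(lod.lod_gain, 3) == 2.041

    def test_mean_sd_formula(self):
        reps = [1.98, 2.00, 2.02, 2.00, 2.00]
        lod = lod_from_replicates(reps, k_sigma=3)
        assert lod.lod_loss == pytest.approx(np.mean(reps) - 3 * np.std(reps, ddof=1))
        assert lod.lod_gain == pytest.approx(np.mean(reps) + 3 * np.std(reps, ddof=1))

    def test_k_zero(self):
        lod = lod_from_replicates([1.9, 2.0, 2.1], k_sigma=0)
        assert lod.lod_loss == lod.lod_gain == pytest.approx(2.0)

    def test_too_few_replicates(self):
        with pytest.raises(DomainError):
            lod_from_replicates([2.0, 2.0])


class TestCvCurve:
    def test_identical_replicates_zero_cv(self, small_panel):
        counts = {m.module_id: 1000 for m in small_panel.modules}
        curve = cv_vs_modules([counts, dict(counts)], small_panel, "TG1", [1, 3], seed=1)
        assert all(cv == 0.0 for cv in curve.cv)

    def test_theoretical_scaling(self, cnv_panel):
        cfg = SimConfig(input_copies=2300, seed=40)
        tables = simulate_count_tables(cfg, cnv_panel, 3)
        curve = cv_vs_modules(tables, cnv_panel, "ERBB2", [1, 4], seed=40)
        # 1/sqrt(m) scaling: quadrupling m halves the target term
        t1, t4 = curve.theoretical_cv
        ratio = t1 / t4
        assert 1.9 < ratio < 2.0  # slightly below 2 because of the reference term

    def test_m_too_large(self, small_panel):
        counts = {m.module_id: 1000 for m in small_panel.modules}
        with pytest.raises(DomainError):
            cv_vs_modules([counts, counts], small_panel, "TG1", [99], seed=1)

    def test_needs_two_replicates(self, small_panel):
        counts = {m.module_id: 1000 for m in small_panel.modules}
        with pytest.raises(DomainError):
            cv_vs_modules([counts], small_panel, "TG1", [1], seed=1)

    def test_deterministic_given_seed(self, cnv_panel):
        cfg = SimConfig(input_copies=2300, seed=41)
        tables = simulate_count_tables(cfg, cnv_panel, 3)
        a = cv_vs_modules(tables, cnv_panel, "ERBB2", [1, 4, 16], seed=7)
        b = cv_vs_modules(tables, cnv_panel, "ERBB2", [1, 4, 16], seed=7)
        assert a.cv == b.cv


class TestChiSquare:
    def test_printed_p_value(self):
        stat, p = chi_square_independence([[8, 0], [4, 3]])
        assert round(p, 3) == 0.038

    def test_hand_computed_statistic(self):
        # oracle: sum (O - E)^2 / E with E from margins of [[8,0],[4,3]]
        observed = np.array([[8.0, 0.0], [4.0, 3.0]])
        row = observed.sum(axis=1, keepdims=True)
        col = observed.sum(axis=0, keepdims=True)
        expected = row * col / observed.sum()
        oracle = ((observed - expected) ** 2 / expected).sum()
        stat, _ = chi_square_independence([[8, 0], [4, 3]])
        assert stat == pytest.approx(oracle)
        assert stat == pytest.approx(30 / 7)

    def test_perfect_independence(self):
        stat, p = chi_square_independence([[5, 5], [5, 5]])
        assert stat == 0.0
        assert p == 1.0

    def test_yates_changes_answer(self):
        _, p = chi_square_independence([[8, 0], [4, 3]], continuity=True)
        assert p > 0.1  # the corrected test cannot reproduce the printed value

    def test_zero_margin_rejected(self):
        with pytest.raises(DomainError):
            chi_square_independence([[0, 0], [4, 3]])


class TestTwoSampleT:
    def test_identical_groups(self):
        assert two_sample_t([2.0, 2.0, 2.0], [2.0, 2.0]) == 1.0

    def test_separated_groups(self):
        a = [2.00, 2.001, 1.999, 2.0005]
        b = [2.05, 2.0495]
        assert two_sample_t(a, b) < 0.05

    def test_too_small_groups(self):
        with pytest.raises(DomainError):
            two_sample_t([2.0], [2.0, 2.1])
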