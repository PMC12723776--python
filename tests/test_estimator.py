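"""Per-gene sd_g estimation: filters, MLE, bootstrap, matrix loop."""

import numpy as np
import pytest

from asevar import _fast
from asevar.bln import _hermgauss, _logpmf_arrays
from asevar.containers import HaplotypeCountMatrix
from asevar.estimator import (
    SIGMA_MIN,
    FitConfig,
    bootstrap_ci,
    eligible_genes,
    fit_gene,
    fit_matrix,
)
from asevar.simulate import SimConfig, simulate_population
from oracles import grid_search_sd


def _matrix_from_totals(totals_per_gene: dict) -> HaplotypeCountMatrix:
    n_samples = max(len(v) for v in totals_per_gene.values())
    genes = list(totals_per_gene)
    a = np.full((len(genes), n_samples), np.nan)
    b = np.full((len(genes), n_samples), np.nan)
    for gi, g in enumerate(genes):
        for si, tot in enumerate(totals_per_gene[g]):
            a[gi, si] = tot // 2
            b[gi, si] = tot - tot // 2
    return HaplotypeCountMatrix.from_arrays(genes, [f"s{i}" for i in range(n_samples)], a, b)


class TestEligibility:
    def test_boundary_semantics(self):
        m = _matrix_from_totals(
            {
                "exactly_at_threshold": [30] * 6,
                "five_deep_individuals": [100] * 5,
                "many_below_threshold": [29] * 200,
                "mixed": [30] * 5 + [29] * 100,
            }
        )
        assert eligible_genes(m) == ["exactly_at_threshold"]

    def test_thresholds_validated(self):
        m = _matrix_from_totals({"g": [30] * 6})
        with pytest.raises(ValueError):
            eligible_genes(m, min_total=0)

    def test_empty_matrix(self):
        m = HaplotypeCountMatrix.from_arrays([], [], np.empty((0, 0)), np.empty((0, 0)))
        assert eligible_genes(m) == []


class TestFitGene:
    def test_balanced_counts_hit_lower_bound(self):
        a = np.full(50, 500.0)
        est = fit_gene(a, a, "balanced")
        assert est.sd_g == SIGMA_MIN
        assert est.at_bound

    def test_bimodal_imbalance_gives_large_sd(self):
        rng = np.random.default_rng(5)
        totals = np.full(60, 30)
        a = np.where(rng.random(60) < 0.5, totals - rng.integers(0, 2, 60), rng.integers(0, 2, 60))
        est = fit_gene(a, totals - a, "bimodal")
        balanced = fit_gene(totals // 2, totals - totals // 2, "flat")
        assert est.sd_g > 1.0
        assert est.sd_g > balanced.sd_g

    def test_too_few_individuals_raises(self):
        with pytest.raises(ValueError, match="usable individuals"):
            fit_gene([20, 20, 20], [20, 20, 20], "tiny")

    def test_low_coverage_individuals_excluded(self):
        a = np.array([20.0] * 6 + [4.0] * 10)
        b = np.array([20.0] * 6 + [4.0] * 10)
        est = fit_gene(a, b, "g", min_count_in_fit=10)
        assert est.n_used == 6

    def test_label_swap_invariance(self):
        cfg = SimConfig(seed=9, n_genes=1, n_individuals=80, sd_g_law=("fixed", 0.3))
        counts, _ = simulate_population(cfg)
        a = counts.a.iloc[0].to_numpy()
        b = counts.b.iloc[0].to_numpy()
        swap = np.random.default_rng(0).random(a.size) < 0.5
        a2 = np.where(swap, b, a)
        b2 = np.where(swap, a, b)
        e1 = fit_gene(a, b, "g")
        e2 = fit_gene(a2, b2, "g")
        assert e1.sd_g == pytest.approx(e2.sd_g, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_ind = int(rng.integers(10, 40))
        sd = float(rng.uniform(0.05, 1.0))
        totals = np.exp(rng.uniform(np.log(10), np.log(500), n_ind)).astype(int)
        delta = rng.normal(0, sd, n_ind)
        a = rng.binomial(totals, 1 / (1 + np.exp(-delta)))

        def loglik(av, nv, s):
            return _logpmf_arrays(av, nv, 0.0, np.full(av.shape, s)).sum()

        oracle = grid_search_sd(a.astype(float), totals.astype(float), loglik)
        est = fit_gene(a, totals - a, "g")
        grid_step = np.log(5.0 / 1e-3) / 2000
        assert abs(np.log(est.sd_g) - np.log(oracle)) < 2 * grid_step

    def test_recovery_at_moderate_true_sd(self):
        errs = []
        for rep in range(8):
            cfg = SimConfig(seed=300 + rep, n_genes=1, n_individuals=600, sd_g_law=("fixed", 0.2))
            counts, _ = simulate_population(cfg)
            est = fit_gene(counts.a.iloc[0].to_numpy(), counts.b.iloc[0].to_numpy(), "g")
            errs.append(abs(est.sd_g - 0.2) / 0.2)
        assert np.median(errs) < 0.10


class TestFastKernel:
    """The jitted bootstrap likelihood must match the reference numpy path."""

    @pytest.mark.parametrize("sd", [0.02, 0.2, 0.8])
    def test_loglik_equivalence(self, sd):
        rng = np.random.default_rng(17)
        n = np.exp(rng.uniform(np.log(10), np.log(3000), 300)).astype(int).astype(float)
        delta = rng.normal(0, sd, 300)
        a = rng.binomial(n.astype(int), 1 / (1 + np.exp(-delta))).astype(float)
        t, lw = _hermgauss(21)
        fast = _fast.neg_loglik(a, n, np.log(sd), t, lw)
        ref = -_logpmf_arrays(a, n, 0.0, np.full(300, sd), 61).sum()
        assert fast == pytest.approx(ref, abs=1e-6)

    def test_golden_section_matches_scipy_optimum(self):
        cfg = SimConfig(seed=21, n_genes=1, n_individuals=200, sd_g_law=("fixed", 0.25))
        counts, _ = simulate_population(cfg)
        a = counts.a.iloc[0].to_numpy()
        n = a + counts.b.iloc[0].to_numpy()
        t, lw = _hermgauss(21)
        fast_sd = _fast.fit_sigma(a, n, t, lw, np.log(1e-3), np.log(5.0), 19)
        est = fit_gene(a, n - a, "g")
        assert np.log(fast_sd) == pytest.approx(np.log(est.sd_g), abs=0.02)


class TestBootstrap:
    @pytest.fixture(scope="class")
    def fitted(self):
        cfg = SimConfig(seed=33, n_genes=1, n_individuals=150, sd_g_law=("fixed", 0.25))
        counts, _ = simulate_population(cfg)
        a = counts.a.iloc[0].to_numpy()
        b = counts.b.iloc[0].to_numpy()
        return fit_gene(a, b, "g"), a + b

    def test_b_below_two_rejected(self, fitted):
        est, totals = fitted
        with pytest.raises(ValueError):
            bootstrap_ci(est, totals, B=1, seed=0)

    def test_degenerate_two_replicates(self, fitted):
        est, totals = fitted
        out = bootstrap_ci(est, totals, B=2, seed=5)
        assert out.ci_low <= est.sd_g <= out.ci_high

    def test_seed_determinism(self, fitted):
        est, totals = fitted
        r1 = bootstrap_ci(est, totals, B=50, seed=11)
        r2 = bootstrap_ci(est, totals, B=50, seed=11)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_interval_brackets_estimate(self, fitted):
        est, totals = fitted
        out = bootstrap_ci(est, totals, B=60, seed=2)
        assert 0 <= out.ci_low <= out.sd_g <= out.ci_high

    def test_ci_width_shrinks_with_cohort_size(self):
        widths = []
        for n_ind in [30, 100, 600]:
            w = []
            for rep in range(6):
                cfg = SimConfig(
                    seed=7000 + rep, n_genes=1, n_individuals=n_ind, sd_g_law=("fixed", 0.2)
                )
                counts, _ = simulate_population(cfg)
                a = counts.a.iloc[0].to_numpy()
                b = counts.b.iloc[0].to_numpy()
                est = bootstrap_ci(fit_gene(a, b, "g"), a + b, B=100, seed=rep)
                w.append(est.ci_high - est.ci_low)
            widths.append(np.mean(w))
        assert widths[0] >= widths[1] >= widths[2]


class TestFitMatrix:
    def test_count_conservation_and_skip_accounting(self):
        cfg = SimConfig(seed=50, n_genes=30, n_individuals=40, sd_g_law=("fixed", 0.2))
        counts, _ = simulate_population(cfg)
        # force 5 genes below the eligibility coverage threshold
        a = counts.a.copy()
        b = counts.b.copy()
        a.iloc[:5] = 10.0
        b.iloc[:5] = 10.0  # totals 20 < 30
        m = HaplotypeCountMatrix(a, b)
        est, skipped = fit_matrix(m, FitConfig())
        assert len(est) == 25
        assert len(skipped) == 5
        assert est["gene_id"].tolist() == m.gene_ids[5:]
        assert skipped["reason"].str.contains("total >= 30").all()

    def test_no_eligible_genes_warns(self):
        m = _matrix_from_totals({"g1": [10] * 8, "g2": [12] * 8})
        with pytest.warns(UserWarning, match="no eligible genes"):
            est, skipped = fit_matrix(m, FitConfig())
        assert est.empty and len(skipped) == 2

    def test_parallel_matches_serial(self):
        cfg = SimConfig(seed=51, n_genes=12, n_individuals=50, sd_g_law=("fixed", 0.3))
        counts, _ = simulate_population(cfg)
        serial, _ = fit_matrix(counts, FitConfig(bootstrap_B=20, seed=4, n_jobs=1))
        parallel, _ = fit_matrix(counts, FitConfig(bootstrap_B=20, seed=4, n_jobs=4))
        assert serial.equals(parallel)
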