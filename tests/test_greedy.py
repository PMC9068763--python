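import numpy as np
import pytest
from scipy import stats

from svargs.greedy import (
    FitConfig,
    det_ratio,
    entry_scan,
    exit_scan,
    extended_sbc,
    fit_block,
    gc_stat_pvalue,
    svargs_fit,
)
from svargs.var_core import (
    BlockPartition,
    Support,
    TimeSeries,
    demean,
    ols_fit,
    random_sparse_stable_var,
    simulate,
)

from conftest import strong_small_system, var_from_dense


def _config(order, **kw):
    return FitConfig.from_order(order, **kw)


class TestDetRatio:
    def test_identity_and_scalar(self):
        s = np.array([[2.0]])
        assert det_ratio(s, s) == pytest.approx(1.0)
        assert det_ratio(np.array([[2.0]]), np.array([[1.0]])) == pytest.approx(2.0)

    def test_nonpositive_determinant_rejected(self):
        with pytest.raises(ValueError):
            det_ratio(np.zeros((2, 2)), np.eye(2))

    def test_nested_ols_equals_brute_force_rss_ratio(self):
        rng = np.random.default_rng(4)
        model = random_sparse_stable_var(2, (1, 1), 0.5, seed=rng)
        ts = simulate(model, 200, seed=rng)
        part = BlockPartition.atomic(2)
        small = Support(frozenset({(0, 0, 1)}), part, (1,))
        large = Support(frozenset({(0, 0, 1), (0, 1, 1)}), part, (1,))
        _, s0, _ = ols_fit(ts, small, 0)
        _, s1, _ = ols_fit(ts, large, 0)
        ratio = det_ratio(s0, s1)
        assert ratio >= 1 - 1e-12
        assert ratio == pytest.approx(s0[0, 0] / s1[0, 0], abs=1e-10)


class TestGcStatPvalue:
    def test_ratio_one_gives_p_one(self):
        assert gc_stat_pvalue(1.0, 100, 1, 1, 2) == 1.0
        assert gc_stat_pvalue(0.5, 100, 1, 1, 2) == 1.0

    def test_scalar_case_matches_f_distribution(self):
        ratio, n, m = 1.17, 100, 2
        f_stat = (ratio - 1) * (n - m - 1)
        expected = stats.f.sf(f_stat, 1, n - m - 1)
        assert gc_stat_pvalue(ratio, n, 1, 1, m) == pytest.approx(expected, abs=1e-12)

    def test_block_case_is_chi_square(self):
        ratio, n = 1.1, 200
        expected = stats.chi2.sf(n * np.log(ratio), 6)
        assert gc_stat_pvalue(ratio, n, 2, 3, 4) == pytest.approx(expected, abs=1e-12)

    def test_insufficient_rows_rejected(self):
        with pytest.raises(ValueError):
            gc_stat_pvalue(1.5, 4, 1, 1, 3)

    def test_null_pvalues_uniform(self):
        # regress white noise on one irrelevant lagged regressor
        rng = np.random.default_rng(11)
        part = BlockPartition.atomic(2)
        empty = Support(frozenset(), part, (1,))
        one = Support(frozenset({(0, 1, 1)}), part, (1,))
        pvals = []
        for _ in range(2000):
            ts = TimeSeries((rng.standard_normal((2, 82)),))
            _, s0, n = ols_fit(ts, empty, 0)
            _, s1, _ = ols_fit(ts, one, 0)
            pvals.append(gc_stat_pvalue(det_ratio(s0, s1), n, 1, 1, 0))
        assert stats.kstest(pvals, "uniform").statistic < 0.03


class TestScans:
    def test_noise_free_single_term_found(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3, 100))
        y = np.zeros(100)
        y[3:] = 0.7 * x[1, :-3]  # depends only on channel 2 at lag 3
        data = np.vstack([y, x[1:]])
        ts = TimeSeries((data,))
        cand = entry_scan(ts, (), 0, _config(4))
        assert (cand.source_block, cand.lag) == (1, 3)

    def test_all_candidates_present_gives_none(self):
        rng = np.random.default_rng(1)
        ts = TimeSeries((rng.standard_normal((2, 60)),))
        full = tuple((lag, sb) for lag in (1,) for sb in range(2))
        assert entry_scan(ts, full, 0, _config(1)) is None
        assert exit_scan(ts, (), 0, _config(1)) is None

    def test_fast_scan_equals_exhaustive_refits(self):
        rng = np.random.default_rng(2)
        model = random_sparse_stable_var(3, (2, 3), 0.3, seed=rng)
        ts = simulate(model, 250, seed=rng)
        cfg = _config(3)
        for current in [(), ((1, 0),), ((1, 0), (2, 2))]:
            fast = entry_scan(ts, current, 0, cfg, use_fast=True)
            slow = entry_scan(ts, current, 0, cfg, use_fast=False)
            assert (fast.source_block, fast.lag) == (slow.source_block, slow.lag)
            assert fast.det_ratio == pytest.approx(slow.det_ratio, rel=1e-8)
            assert np.allclose(fast.coefficient_block, slow.coefficient_block,
                               atol=1e-8)
        fast = exit_scan(ts, ((1, 0), (2, 2)), 0, cfg, use_fast=True)
        slow = exit_scan(ts, ((1, 0), (2, 2)), 0, cfg, use_fast=False)
        assert (fast.source_block, fast.lag) == (slow.source_block, slow.lag)
        assert fast.det_ratio == pytest.approx(slow.det_ratio, rel=1e-8)

    def test_exit_scan_flags_irrelevant_term(self):
        rng = np.random.default_rng(3)
        model = var_from_dense([np.array([[0.0, 0.8], [0.0, 0.3]])])
        ts = simulate(model, 400, seed=rng)
        # support holds the strong true term and an irrelevant one
        worst = exit_scan(ts, ((1, 1), (1, 0)), 0, _config(1))
        assert (worst.lag, worst.source_block) == (1, 0)
        assert worst.det_ratio < 1.05


class TestExtendedSbc:
    def test_gamma_zero_reduces_to_bic(self, white_noise_ts):
        cfg0 = _config(2, ebic_gamma=1e-12)  # config requires gamma via default; 0 allowed
        support = ((1, 1),)
        part = BlockPartition.atomic(5)
        score = extended_sbc(white_noise_ts, support, 0, cfg0)
        sup = Support(frozenset({(0, 1, 1)}), part, (1, 2))
        _, sigma, n = ols_fit(demean(white_noise_ts), sup, 0)
        bic = n * np.log(sigma[0, 0]) + 1 * np.log(n)
        assert score == pytest.approx(bic, rel=1e-9)

    def test_empty_support_is_log_sample_covariance(self, white_noise_ts):
        cfg = _config(2)
        score = extended_sbc(white_noise_ts, (), 0, cfg)
        part = BlockPartition.atomic(5)
        sup = Support(frozenset(), part, (1, 2))
        _, sigma, n = ols_fit(demean(white_noise_ts), sup, 0)
        assert score == pytest.approx(n * np.log(sigma[0, 0]), rel=1e-9)

    def test_pure_noise_regressor_raises_score(self):
        cfg = _config(2)
        raised = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            model = var_from_dense([np.array([[0.5, 0.0], [0.0, 0.3]])])
            ts = simulate(model, 300, seed=rng)
            good = ((1, 0),)
            padded = ((1, 0), (2, 1))  # channel 2 never influences channel 1
            raised += (extended_sbc(ts, padded, 0, cfg)
                       > extended_sbc(ts, good, 0, cfg))
        assert raised >= 95


class TestFitBlock:
    def test_white_noise_yields_near_empty_support(self):
        cfg = _config(3, p_max=0.01)
        small = 0
        for s in range(100):
            rng = np.random.default_rng(1000 + s)
            ts = TimeSeries((rng.standard_normal((5, 400)),))
            support, _, _, _ = fit_block(ts, 0, cfg)
            small += len(support.entries) <= 1
        assert small >= 90

    def test_strong_sparse_equation_recovered(self):
        cfg = _config(4, p_max=0.01)
        exact = 0
        for s in range(100):
            model = strong_small_system(s, k=4, order_range=(1, 2),
                                        density=0.15)
            ts = simulate(model, 400, seed=3000 + s)
            cfg_s = _config(model.order + 2, p_max=0.01)
            support, _, _, _ = fit_block(ts, 0, cfg_s)
            truth = {(0, c, lag) for (r, c, lag) in model.support_triples()
                     if r == 0}
            exact += support.entries == truth
        assert exact >= 95

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        model = random_sparse_stable_var(4, (2, 3), 0.2, seed=rng)
        ts = simulate(model, 300, seed=rng)
        cfg = _config(5)
        s1, c1, _, _ = fit_block(ts, 1, cfg)
        s2, c2, _, _ = fit_block(ts, 1, cfg)
        assert s1.entries == s2.entries
        assert np.array_equal(c1, c2)

    def test_final_coefficients_equal_ols_refit(self):
        rng = np.random.default_rng(6)
        model = random_sparse_stable_var(4, (2, 3), 0.2, seed=rng)
        ts = simulate(model, 350, seed=rng)
        cfg = _config(5)
        support, coef, sigma, trace = fit_block(ts, 0, cfg)
        coef_ref, sigma_ref, _ = ols_fit(demean(ts), support, 0)
        assert np.allclose(coef, coef_ref, atol=1e-12)
        assert np.allclose(sigma, sigma_ref, atol=1e-12)
        assert all(np.isfinite(r.score) for r in trace.records)


class TestSvargsFit:
    def test_k1_reduces_to_fit_block(self):
        rng = np.random.default_rng(7)
        ts = simulate(var_from_dense([np.array([[0.6]])]), 300, seed=rng)
        cfg = _config(3)
        model = svargs_fit(ts, cfg)
        support, coef, _, _ = fit_block(ts, 0, cfg)
        triples = {(0, sb, lag) for (tb, sb, lag) in support.entries}
        assert {(r, c, l) for (r, c, l) in model.support_triples()} == \
            {(0, sb, lag) for (_, sb, lag) in support.entries}

    def test_atomic_partition_representations_agree(self):
        rng = np.random.default_rng(8)
        model = random_sparse_stable_var(3, (2, 2), 0.3, seed=rng)
        ts = simulate(model, 300, seed=rng)
        cfg = _config(4)
        fit_default = svargs_fit(ts, cfg)
        explicit = BlockPartition(((0,), (1,), (2,)))
        fit_explicit = svargs_fit(ts, cfg, explicit)
        assert fit_default.support_triples() == fit_explicit.support_triples()
        for lag in fit_default.coeffs:
            assert np.allclose(fit_default.coeff_dense(lag),
                               fit_explicit.coeff_dense(lag))

    def test_block_partition_fit_runs_and_is_stable_shape(self):
        rng = np.random.default_rng(9)
        model = random_sparse_stable_var(4, (2, 2), 0.25, seed=rng)
        ts = simulate(model, 400, seed=rng)
        part = BlockPartition(((0, 1), (2, 3)))
        fit = svargs_fit(ts, _config(4), part)
        assert fit.k == 4
        assert fit.sigma.shape == (4, 4)

    def test_accepted_entries_significant_along_trace(self):
        # dets are non-increasing across accepted entries within a level
        rng = np.random.default_rng(10)
        model = random_sparse_stable_var(3, (2, 3), 0.3, seed=rng)
        ts = simulate(model, 300, seed=rng)
        _, _, _, trace = fit_block(ts, 0, _config(5))
        sizes = [len(r.support) for r in trace.records]
        # trace exists and starts from the trivial model
        assert sizes[0] == 0 and len(sizes) >= 1
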