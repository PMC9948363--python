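"""Factor-number selectors: sensitivity scan, local greedy, elbow, BE."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pseudofactor as pf
from pseudofactor.io import ValidationError
from pseudofactor.select import SensitivityCurve, be_algorithm, compare_selectors, elbow, local_greedy

from conftest import loess_oracle


class TestSensitivityCurve:
    def test_pct_change_definition(self):
        curve = SensitivityCurve([0, 1, 2, 3], [100, 110, 110, 99])
        np.testing.assert_allclose(curve.pct_change, [10.0, 0.0, -10.0])

    def test_pct_change_undefined_at_zero_baseline(self):
        curve = SensitivityCurve([0, 1, 2], [0, 5, 10])
        pc = curve.pct_change
        assert np.isnan(pc[0]) and pc[1] == pytest.approx(100.0)


class TestLocalGreedy:
    def _curve_from_pct(self, pct):
        """Build an eGene curve whose percentage changes are (approximately) pct."""
        g = [1000]
        for p in pct:
            g.append(int(round(g[-1] * (1 + p / 100.0))))
        return SensitivityCurve(np.arange(len(g)), g)

    def test_always_negative_selects_zero(self):
        res = local_greedy(self._curve_from_pct([-1.0] * 8))
        assert res.k_opt == 0

    def test_always_positive_never_negative_warning(self):
        curve = self._curve_from_pct([1.0] * 8)
        res = local_greedy(curve)
        assert res.k_opt == int(curve.k_values[-1])
        assert "NEVER_NEGATIVE" in res.warnings

    def test_reference_curve_matches_independent_loess_oracle(self):
        g = np.array([100, 108, 114, 118, 120, 120, 119, 118, 117, 116, 115])
        curve = SensitivityCurve(np.arange(11), g)
        res = local_greedy(curve, span=0.75)
        # independent tricube local-linear oracle, same grid and rule
        x = curve.k_values[1:].astype(float)
        fitted = loess_oracle(x, curve.pct_change, 0.75)
        neg = np.flatnonzero(fitted < 0)
        oracle_k = int(x[x < x[neg[0]]][-1])
        assert res.k_opt == oracle_k == 5
        assert 4 <= res.k_opt <= 6

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError, match=">= 4"):
            local_greedy(SensitivityCurve([0, 1, 2], [10, 11, 12]))

    @settings(deadline=None, max_examples=20)
    @given(scale=st.integers(min_value=2, max_value=50))
    def test_invariant_to_uniform_count_rescaling(self, scale):
        g = np.array([100, 108, 114, 118, 120, 120, 119, 118, 117, 116, 115])
        r1 = local_greedy(SensitivityCurve(np.arange(11), g))
        r2 = local_greedy(SensitivityCurve(np.arange(11), g * scale))
        assert r1.k_opt == r2.k_opt


class TestElbow:
    def test_sharp_bend_matches_brute_force_distances(self):
        scree = np.array([10.0, 5.0, 1.0, 0.9, 0.8, 0.7])
        res = elbow(scree)
        pts = np.column_stack([np.arange(1, 7, dtype=float), scree])
        p0, p1 = pts[0], pts[-1]
        dists = []
        for pt in pts:
            num = abs(
                (p1[0] - p0[0]) * (p0[1] - pt[1]) - (p0[0] - pt[0]) * (p1[1] - p0[1])
            )
            dists.append(num / np.hypot(*(p1 - p0)))
        assert res.k_opt == int(np.argmax(dists) + 1)
        np.testing.assert_allclose(res.diagnostics["distances"], dists, atol=1e-12)

    def test_linear_scree_no_elbow_warning(self):
        res = elbow(np.linspace(10, 1, 8))
        assert "NO_ELBOW" in res.warnings

    def test_single_dominant_value(self):
        res = elbow(np.array([100.0, 1.0, 1.0, 1.0]))
        assert res.k_opt == 2

    def test_constant_scree_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            elbow(np.full(5, 3.0))


class TestBeAlgorithm:
    def test_defaults(self):
        import inspect

        sig = inspect.signature(be_algorithm)
        assert sig.parameters["B"].default == 20
        assert sig.parameters["alpha"].default == 0.05

    def test_pure_noise_selects_zero_most_seeds(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((100, 500))
        zeros = sum(be_algorithm(X, seed=s).k_opt == 0 for s in range(5))
        assert zeros >= 4

    def test_planted_factor_detected_every_seed(self):
        rng = np.random.default_rng(8)
        s = rng.standard_normal(80)
        load = rng.standard_normal(200) * np.sqrt(10.0 / 1.0)
        X = np.outer(s, load) + rng.standard_normal((80, 200))
        assert all(be_algorithm(X, seed=sd).k_opt >= 1 for sd in range(5))

    def test_seed_deterministic(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((40, 100))
        r1 = be_algorithm(X, seed=3)
        r2 = be_algorithm(X, seed=3)
        assert r1.k_opt == r2.k_opt
        np.testing.assert_array_equal(r1.diagnostics["p_values"], r2.diagnostics["p_values"])

    def test_tighter_alpha_never_keeps_more(self):
        rng = np.random.default_rng(10)
        s = rng.standard_normal((60, 3))
        load = rng.standard_normal((150, 3)) * 2.0
        X = s @ load.T + rng.standard_normal((60, 150))
        ks = [be_algorithm(X, alpha=a, seed=1).k_opt for a in (0.2, 0.1, 0.05, 0.01)]
        assert all(a >= b for a, b in zip(ks, ks[1:]))


class TestCompareSelectors:
    def _curve(self):
        return SensitivityCurve(np.arange(6), [100, 120, 140, 150, 148, 146])

    def test_argmax_choice_is_full_power(self):
        res = pf.SelectionResult(method="elbow", k_opt=3)
        table = compare_selectors(self._curve(), [res])
        assert table.loc[0, "pct_of_max_egenes"] == pytest.approx(100.0)
        assert table.loc[0, "pct_of_max_gain_retained"] == pytest.approx(100.0)

    def test_baseline_choice_retains_no_gain(self):
        res = pf.SelectionResult(method="local_greedy", k_opt=0)
        table = compare_selectors(self._curve(), [res])
        assert table.loc[0, "pct_of_max_gain_retained"] == pytest.approx(0.0)

    def test_hand_computed_table(self):
        results = [
            pf.SelectionResult(method="local_greedy", k_opt=2),
            pf.SelectionResult(method="be", k_opt=5),
        ]
        table = compare_selectors(self._curve(), results).set_index("method")
        assert table.loc["local_greedy", "egenes_at_k_opt"] == 140
        assert table.loc["local_greedy", "pct_of_max_gain_retained"] == pytest.approx(100 * 40 / 50)
        assert table.loc["be", "egenes_at_k_opt"] == 146
        assert table.loc["be", "pct_of_max_egenes"] == pytest.approx(100 * 146 / 150)


class TestScanOnSimulatedData:
    def test_confounded_scan_gains_power_and_selector_recovers_q(self):
        """With q=5 planted confounders the eGene curve rises and local greedy
        picks k near q (checked across 3 seeds, majority)."""
        wins_rise, k_opts = 0, []
        for seed in (1, 2, 3):
            cfg = pf.SimConfig(
                n_individuals=100, n_genes=300, n_cells_per_individual=50,
                n_snps=600, n_true_eqtl_genes=40, confounder_strength=0.6, seed=seed,
            )
            cm, gt, cov, ann, truth = pf.simulate(cfg)
            pb = pf.aggregate(cm, "all")
            stats = pf.gene_stats(pb)
            tm = pf.apply_option(pb, stats, 11)
            fs = pf.ard_fa(tm, K=12, max_iter=200)
            curve = pf.sensitivity_scan(tm, gt, cov, fs, ann=ann, k_max=10)
            if curve.egene_counts[5] > curve.egene_counts[0]:
                wins_rise += 1
            k_opts.append(local_greedy(curve).k_opt)
        assert wins_rise >= 2
        assert sum(3 <= k <= 8 for k in k_opts) >= 2  # q-2 .. q+3 with q=5
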