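import numpy as np
import pytest
from scipy.optimize import linprog
from scipy.stats import norm

from grmcat import screening as scr
from grmcat.scoring import full_test_estimate
from grmcat.synth import inject_local_dependence, reverse_item


@pytest.fixture(scope="module")
def theta_hats(bank, small_cohort):
    return np.array(
        [full_test_estimate(bank, r).theta for r in small_cohort.responses]
    )


class TestPolychoric:
    def test_recovers_latent_correlation_of_discretized_normal(self):
        # oracle: the generating rho of a discretized bivariate normal
        rng = np.random.default_rng(2)
        rho = 0.6
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=5000)
        cuts = [-1.0, 0.0, 0.8, 1.5]
        x = np.searchsorted(cuts, z[:, 0])
        y = np.searchsorted(cuts, z[:, 1])
        est = scr.polychoric_correlation(x, y, n_cat=5)
        assert est == pytest.approx(rho, abs=0.05)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 5, size=5000)
        y = rng.integers(0, 5, size=5000)
        assert abs(scr.polychoric_correlation(x, y, 5)) < 0.05

    def test_matrix_symmetric_unit_diagonal(self, small_cohort):
        m = scr.polychoric_matrix(small_cohort.responses[:, :6])
        np.testing.assert_allclose(m, m.T)
        np.testing.assert_allclose(np.diag(m), 1.0)

    def test_single_category_item_rejected(self):
        data = np.zeros((100, 2), dtype=int)
        data[:, 1] = np.arange(100) % 5
        with pytest.raises(scr.ScreeningError, match="single observed"):
            scr.polychoric_matrix(data)


class TestPCA:
    def test_identity_matrix_fails_both_flags(self):
        props, decision = scr.pca_variance_ratio(np.eye(8))
        np.testing.assert_allclose(props, 1 / 8)
        assert not decision["first_ge_20pct"]
        assert not decision["ratio_ge_4"]

    def test_equicorrelation_first_proportion_closed_form(self):
        # one factor, loadings 0.7 -> equicorrelation r = 0.49:
        # lambda_1 = 1 + (m-1) r, proportion = 0.49 + 0.51/m
        m = 10
        corr = np.full((m, m), 0.49)
        np.fill_diagonal(corr, 1.0)
        props, decision = scr.pca_variance_ratio(corr)
        assert props[0] == pytest.approx(0.49 + 0.51 / m, abs=1e-12)
        assert decision["first_ge_20pct"] and decision["ratio_ge_4"]

    def test_clean_bank_data_passes_dimensionality_screen(self, small_cohort):
        poly = scr.polychoric_matrix(small_cohort.responses)
        props, decision = scr.pca_variance_ratio(poly)
        assert props.sum() == pytest.approx(1.0)
        assert decision["first_ge_20pct"]
        assert decision["ratio_ge_4"]


class TestOneFactorResiduals:
    def test_exact_one_factor_matrix_leaves_no_residuals(self):
        lam = np.linspace(0.4, 0.9, 8)
        corr = np.outer(lam, lam)
        np.fill_diagonal(corr, 1.0)
        resid, flags = scr.one_factor_residuals(corr)
        assert np.max(np.abs(resid)) < 1e-6
        assert flags == []
        np.testing.assert_allclose(resid, resid.T, atol=1e-10)

    def test_planted_extra_correlation_is_flagged(self):
        lam = np.full(8, 0.7)
        corr = np.outer(lam, lam)
        np.fill_diagonal(corr, 1.0)
        corr[2, 5] = corr[5, 2] = corr[2, 5] + 0.3
        resid, flags = scr.one_factor_residuals(corr)
        assert any(f.items == (3, 6) for f in flags)

    def test_heywood_loading_clipped_with_warning(self):
        corr = np.array([[1.0, 0.99, 0.99], [0.99, 1.0, 0.8], [0.99, 0.8, 1.0]])
        with pytest.warns(UserWarning, match="Heywood"):
            scr.one_factor_residuals(corr)


class TestQ3:
    def test_model_true_data_shows_only_small_q3(self, bank, small_cohort, theta_hats):
        q3, flags = scr.q3_matrix(small_cohort.responses, bank, theta_hats)
        np.testing.assert_allclose(q3, q3.T, equal_nan=True)
        # mild negative bias about -1/(m-1) is expected; no large flags
        assert not [f for f in flags if f.diagnostic == "q3_large"]
        assert np.nanmean(q3) < 0

    def test_planted_dependent_pair_has_largest_q3(self, bank, small_cohort):
        data = inject_local_dependence(small_cohort, (7, 16), strength=2.0, seed=5)
        th = np.array([full_test_estimate(bank, r).theta for r in data])
        q3, flags = scr.q3_matrix(data, bank, th)
        iu = np.triu_indices(22, 1)
        top = np.nanargmax(np.abs(q3[iu]))
        assert (iu[0][top], iu[1][top]) == (6, 15)
        assert q3[6, 15] >= scr.Q3_MODERATE
        assert any(f.items == (7, 16) for f in flags)


class TestMokken:
    def test_guttman_data_has_unit_scalability(self):
        base = np.repeat(np.arange(5), 20)
        data = np.stack([base, base, base], axis=1)
        item_h, pair_h, scale_h, band = scr.mokken_scalability(data)
        assert scale_h == pytest.approx(1.0)
        np.testing.assert_allclose(item_h, 1.0)
        assert band == "strong"

    def test_independent_items_scale_near_zero(self):
        rng = np.random.default_rng(9)
        data = rng.integers(0, 5, size=(4000, 4))
        _, _, scale_h, band = scr.mokken_scalability(data)
        assert abs(scale_h) < 0.05
        assert band == "unscalable"

    def test_max_covariance_matches_linear_program_oracle(self):
        # oracle: maximize E[XY] over couplings with fixed marginals (LP)
        rng = np.random.default_rng(13)
        vals = np.arange(5)
        for _ in range(20):
            x = rng.integers(0, 5, size=200)
            y = rng.integers(0, 5, size=200)
            px = np.bincount(x, minlength=5) / 200
            py = np.bincount(y, minlength=5) / 200
            c = -(vals[:, None] * vals[None, :]).astype(float).ravel()
            a_eq = np.zeros((10, 25))
            for i in range(5):
                a_eq[i, i * 5 : (i + 1) * 5] = 1
                a_eq[5 + i, i::5] = 1
            res = linprog(c, A_eq=a_eq, b_eq=np.concatenate([px, py]), method="highs")
            lp_max = -res.fun - px @ vals * (py @ vals)
            assert scr.max_covariance(x, y, 5) == pytest.approx(lp_max, abs=1e-10)

    def test_bank_generated_data_is_at_least_moderate(self, small_cohort):
        item_h, _, scale_h, band = scr.mokken_scalability(small_cohort.responses)
        assert scale_h > 0.4
        assert (item_h > 0.25).all()


class TestMonotonicity:
    def test_model_true_data_has_no_violations(self, small_cohort):
        # 3 rest-score groups: at n=400 finer bins would mostly test noise
        violations = scr.monotonicity_check(small_cohort.responses, n_rest_groups=3)
        assert violations.sum() == 0

    def test_reversed_item_detected(self, small_cohort):
        data = reverse_item(small_cohort.responses, 0)
        violations = scr.monotonicity_check(data, n_rest_groups=3)
        assert violations[0] > 0
        assert violations[0] == violations.max()
        assert violations[1:].sum() == 0

    def test_single_bin_has_no_violations_by_construction(self, small_cohort):
        violations = scr.monotonicity_check(small_cohort.responses, n_rest_groups=1)
        assert violations.sum() == 0


class TestDIF:
    def test_random_groups_show_no_dif(self, bank, small_cohort, theta_hats):
        rng = np.random.default_rng(29)
        group = rng.integers(0, 2, size=len(theta_hats))
        df, flags = scr.dif_ordinal(
            small_cohort.responses[:, :6], theta_hats, group
        )
        assert flags == []
        assert (df.delta_r2.dropna() < 0.02).all()

    def test_delta_r2_nonnegative_for_nested_models(self, bank, small_cohort, theta_hats):
        rng = np.random.default_rng(31)
        group = rng.integers(0, 3, size=len(theta_hats))
        df, _ = scr.dif_ordinal(small_cohort.responses[:, :4], theta_hats, group)
        assert (df.delta_r2.dropna() >= 0).all()

    def test_planted_threshold_shift_detected(self, bank, grouped_cohort):
        from grmcat.synth import inject_dif

        data = inject_dif(grouped_cohort, 17, shift=0.5, group_label="depressed", seed=3)
        th = np.array([full_test_estimate(bank, r).theta for r in data])
        group = (grouped_cohort.group_labels == "depressed").astype(int)
        df, flags = scr.dif_ordinal(data, th, group)
        j = grouped_cohort.spec.bank.item_ids.index(17)
        assert df.delta_r2.idxmax() == j
        assert any(f.items == (17,) for f in flags)

    def test_two_level_requirement(self, small_cohort, theta_hats):
        with pytest.raises(scr.ScreeningError, match="2 levels"):
            scr.dif_ordinal(small_cohort.responses[:, :3], theta_hats, np.zeros(400))


def test_battery_report_serializes(tmp_path, bank, small_cohort, theta_hats):
    report = scr.run_battery(
        small_cohort.responses[:, :8].copy(),
        bank.subset(bank.item_ids[:8]),
        theta_hats,
        polychoric=False,
    )
    path = tmp_path / "report.json"
    report.to_json(path)
    import json

    payload = json.loads(path.read_text())
    assert "q3" in payload and "flags" in payload
    assert isinstance(report.flags_frame().shape[0], int)
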