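import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grmcat.grm import (
    bank_information,
    category_probabilities,
    cumulative_prob,
    information_curve,
    item_information,
    item_log_likelihood,
)
from grmcat.grm import test_information as total_information  # avoid pytest collection
from grmcat.item_bank import GRMItem, ItemBank


class TestCumulativeProb:
    def test_equals_half_at_threshold(self, bank):
        item1 = bank.item_by_id(1)
        assert cumulative_prob(item1, 1, -2.50) == pytest.approx(0.5)

    def test_logistic_limits(self, bank):
        item = bank.item_by_id(4)
        assert cumulative_prob(item, 1, 50.0) == pytest.approx(1.0)
        assert cumulative_prob(item, 1, -50.0) == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_logistic_evaluation(self, bank):
        # frozen value: 1/(1+exp(-2.75*(0-(-1.51)))) computed externally
        assert cumulative_prob(bank.item_by_id(5), 2, 0.0) == pytest.approx(
            0.9845183944275346, abs=1e-12
        )

    def test_strictly_increasing_in_theta(self, bank):
        grid = np.linspace(-4, 4, 81)
        for item in bank:
            vals = cumulative_prob(item, 2, grid)
            assert np.all(np.diff(vals) > 0)

    def test_out_of_range_boundary_raises(self, bank):
        with pytest.raises(IndexError):
            cumulative_prob(bank.item_by_id(1), 5, 0.0)


class TestCategoryProbabilities:
    def test_item1_at_zero_matches_hand_computed_differences(self, bank):
        # frozen: cumulative differences evaluated independently
        expected = [0.002411721, 0.066546713, 0.382990320, 0.415639398, 0.132411848]
        probs = category_probabilities(bank.item_by_id(1), 0.0)
        np.testing.assert_allclose(probs, expected, atol=1e-9)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    @given(theta=st.floats(-6, 6), item_idx=st.integers(0, 21))
    @settings(max_examples=60, deadline=None)
    def test_proper_distribution_everywhere(self, bank, theta, item_idx):
        probs = category_probabilities(bank[item_idx], theta)
        assert np.all(probs >= 0)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_mass_concentrates_on_lowest_category_far_below(self):
        item = GRMItem(item_id=1, a=8.0, b=(-1.0, 0.0, 0.5, 1.0))
        probs = category_probabilities(item, -5.0)
        assert probs[0] > 0.999


class TestLogLikelihood:
    def test_matches_log_of_category_probabilities(self, bank):
        item = bank.item_by_id(9)
        for k in range(5):
            assert item_log_likelihood(item, k, 0.3) == pytest.approx(
                np.log(category_probabilities(item, 0.3)[k])
            )

    def test_sums_to_joint_under_local_independence(self, bank):
        responses = [0, 1, 2, 3, 4]
        items = [bank.item_by_id(i) for i in (1, 2, 3, 4, 5)]
        joint = sum(item_log_likelihood(it, r, -0.7) for it, r in zip(items, responses))
        manual = sum(np.log(category_probabilities(it, -0.7)[r]) for it, r in zip(items, responses))
        assert joint == pytest.approx(manual)

    def test_out_of_range_response_raises(self, bank):
        with pytest.raises(ValueError, match="out of range"):
            item_log_likelihood(bank.item_by_id(1), 5, 0.0)


def _fisher_information_oracle(item, theta, h=1e-2):
    """Finite-difference expected information: -E[d2/dtheta2 log P_k].

    Five-point stencil (O(h^4) truncation) keeps the oracle accurate to
    well below 1e-6 relative error.
    """
    total = 0.0
    probs = category_probabilities(item, theta)
    for k in range(item.n_categories):
        f = [item_log_likelihood(item, k, theta + i * h) for i in (-2, -1, 0, 1, 2)]
        d2 = (-f[0] + 16 * f[1] - 30 * f[2] + 16 * f[3] - f[4]) / (12 * h**2)
        total += probs[k] * -d2
    return total


class TestInformation:
    def test_information_decays_in_the_tails(self, bank):
        # decay rate scales with a, so the flattest items need the widest tail
        for item in bank:
            peak = max(item_information(item, t) for t in np.linspace(-4, 4, 81))
            assert item_information(item, 10.0) < 0.02 * peak
            assert item_information(item, -10.0) < 0.02 * peak
            assert item_information(item, 15.0) < 1e-3
            assert item_information(item, -15.0) < 1e-3

    def test_item5_most_informative_at_start(self, bank):
        info = [item_information(item, 0.0) for item in bank]
        assert bank.item_ids[int(np.argmax(info))] == 5

    @pytest.mark.parametrize("item_id", [1, 4, 9, 17, 22])
    def test_matches_finite_difference_fisher_oracle(self, bank, item_id):
        item = bank.item_by_id(item_id)
        grid = np.linspace(-4, 4, 41)
        ours = np.array([item_information(item, t) for t in grid])
        oracle = np.array([_fisher_information_oracle(item, t) for t in grid])
        np.testing.assert_allclose(ours, oracle, rtol=1e-6, atol=1e-9)

    def test_nonnegative_with_monotone_tails(self, bank):
        # polytomous information can ripple between spread thresholds, but it
        # is non-negative everywhere and decays monotonically outside them
        grid = np.linspace(-8, 8, 321)
        for item in bank:
            vals = np.array([item_information(item, t) for t in grid])
            assert np.all(vals >= 0)
            left = grid < min(item.b) - 1
            right = grid > max(item.b) + 1
            assert np.all(np.diff(vals[left]) >= 0)
            assert np.all(np.diff(vals[right]) <= 0)

    def test_test_information_is_additive(self, bank):
        single = ItemBank((bank.item_by_id(5),))
        assert total_information(single, 0.4) == pytest.approx(
            item_information(bank.item_by_id(5), 0.4)
        )
        total = sum(item_information(it, 0.4) for it in bank)
        assert total_information(bank, 0.4) == pytest.approx(total)

    def test_bank_information_peak_near_minus_half(self, bank):
        grid = np.arange(-4, 4 + 1e-9, 0.01)
        vals = total_information(bank, grid)
        assert grid[int(np.argmax(vals))] == pytest.approx(-0.50, abs=0.05)

    def test_about_sixty_percent_of_information_in_central_interval(self, bank):
        grid = np.linspace(-8, 8, 3201)
        vals = total_information(bank, grid)
        total = np.trapezoid(vals, grid)
        sel = (grid > -2) & (grid < 1)
        share = 100 * np.trapezoid(vals[sel], grid[sel]) / total
        assert share == pytest.approx(60.0, abs=3.0)


def test_information_curve_export_round_trips(tmp_path, bank):
    curve = information_curve(bank)
    assert len(curve.grid) == 161
    assert curve.peak_theta == pytest.approx(-0.5, abs=0.1)
    path = tmp_path / "curve.csv"
    curve.to_csv(path)
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    np.testing.assert_allclose(arr[:, 1], curve.values)
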