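"""Group summaries and the Mann-Whitney U comparison."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from rrmarkov import (
    AlphaBand,
    EmptySeriesWarning,
    MarkovEmissionConfig,
    Transition,
    ValidationError,
    WindowConfig,
    compare_groups,
    comparison_frame,
    mann_whitney_u,
    simulate_markov_rr,
    summarize,
    window_probability_series,
)

sample_values = st.lists(
    st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]), min_size=1, max_size=8
)


def enumeration_oracle(x, y):
    """Independent exact oracle: U computed by direct pairwise comparison
    (wins + half-ties) over every assignment of pooled values to groups."""
    pooled = list(x) + list(y)
    n_x, n_y = len(x), len(y)

    def u_of(xs, ys):
        return sum(
            (1.0 if a > b else 0.5 if a == b else 0.0) for a in xs for b in ys
        )

    mu = n_x * n_y / 2.0
    dev_obs = abs(u_of(x, y) - mu)
    hits = total = 0
    for combo in itertools.combinations(range(n_x + n_y), n_x):
        chosen = set(combo)
        xs = [pooled[i] for i in range(len(pooled)) if i in chosen]
        ys = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        if abs(u_of(xs, ys) - mu) >= dev_obs - 1e-9:
            hits += 1
        total += 1
    return hits / total


class TestSummarize:
    def test_hand_arithmetic(self):
        s = summarize([0, 1, 1, 1])
        assert s.mean == pytest.approx(0.75)
        assert s.sd == pytest.approx(0.5)
        assert s.n == 4

    def test_empty_sample_is_undefined_with_warning(self):
        with pytest.warns(EmptySeriesWarning):
            s = summarize([])
        assert s.n == 0 and math.isnan(s.mean) and math.isnan(s.sd)

    def test_single_observation_has_no_sd(self):
        s = summarize([0.5])
        assert s.mean == 0.5 and math.isnan(s.sd) and s.n == 1


class TestMannWhitneyU:
    def test_fully_separated_small_samples(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    def test_identical_samples_give_p_one(self):
        for mode in ("exact", "approx"):
            res = mann_whitney_u([1, 2, 2, 3], [1, 2, 2, 3], mode=mode)
            assert res.p_value == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])

    @given(sample_values, sample_values)
    def test_u_statistics_sum_to_product(self, x, y):
        u_x = mann_whitney_u(x, y).u_statistic
        u_y = mann_whitney_u(y, x).u_statistic
        assert u_x + u_y == pytest.approx(len(x) * len(y))

    @given(sample_values, sample_values)
    def test_invariance_under_decreasing_transform(self, x, y):
        """A rank test with a two-sided alternative is unchanged by
        v -> 1 - v applied to both samples."""
        direct = mann_whitney_u(x, y)
        flipped = mann_whitney_u([1 - v for v in x], [1 - v for v in y])
        assert direct.p_value == flipped.p_value
        assert direct.u_statistic + flipped.u_statistic == pytest.approx(
            len(x) * len(y)
        )

    @settings(max_examples=30)
    @given(sample_values, sample_values)
    def test_exact_mode_matches_enumeration_oracle(self, x, y):
        res = mann_whitney_u(x, y, mode="exact")
        assert res.p_value == pytest.approx(enumeration_oracle(x, y), abs=1e-12)

    def test_approx_matches_scipy_on_tied_data(self, rng):
        for _ in range(5):
            x = rng.choice([0.0, 0.5, 1.0], 60)
            y = rng.choice([0.0, 0.5, 1.0], 80)
            mine = mann_whitney_u(x, y, mode="approx")
            ref = mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            )
            assert mine.u_statistic == pytest.approx(float(ref.statistic))
            assert mine.p_value == pytest.approx(float(ref.pvalue), rel=1e-12)

    def test_auto_mode_switches_to_approximation_for_large_samples(self, rng):
        x = rng.random(50)
        y = rng.random(60)
        assert mann_whitney_u(x, y).method == "normal_approximation"
        assert mann_whitney_u(x[:5], y[:5]).method == "exact"


def _group(p_true, seeds, band, n=300):
    estimates = []
    for seed in seeds:
        cfg = MarkovEmissionConfig(
            p_true=np.asarray(p_true), band=band, n_intervals=n, seed=int(seed)
        )
        rr, _ = simulate_markov_rr(cfg)
        estimates.append(window_probability_series(rr, band, WindowConfig(10, 1)))
    return estimates


@pytest.fixture(scope="module")
def comparison():
    band = AlphaBand(800, 1000)
    group_a = _group([[0.8, 0.2], [0.3, 0.7]], [1, 2, 3], band)
    group_b = _group([[0.5, 0.5], [0.5, 0.5]], [4, 5, 6], band)
    return compare_groups(group_a, group_b)


class TestCompareGroups:
    band = AlphaBand(800, 1000)

    def test_row_order_matches_report_shape(self, comparison):
        assert [c.transition for c in comparison] == [
            Transition.AN,
            Transition.AA,
            Transition.NA,
            Transition.NN,
        ]

    def test_complementary_rows_share_p_and_mirror_means(self, comparison):
        rows = {c.transition: c for c in comparison}
        for first, second in [
            (Transition.AA, Transition.AN),
            (Transition.NN, Transition.NA),
        ]:
            assert rows[first].p_value == rows[second].p_value
            for a, b in [
                (rows[first].summary_a, rows[second].summary_a),
                (rows[first].summary_b, rows[second].summary_b),
            ]:
                assert a.mean + b.mean == pytest.approx(1.0, abs=1e-12)
                assert a.sd == pytest.approx(b.sd, abs=1e-12)
                assert a.n == b.n

    def test_frame_columns(self, comparison):
        frame = comparison_frame(comparison)
        assert list(frame.columns) == [
            "transition", "p_value", "mean_a", "mean_b", "sd_a", "sd_b",
            "n_a", "n_b", "u_statistic", "method",
        ]
        assert list(frame["transition"]) == ["A to N", "A to A", "N to A", "N to N"]

    def test_empty_pooled_sample_marks_row_not_computable(self):
        # all intervals in band: the A row never has outgoing transitions
        from rrmarkov import RRSeries

        all_n = [
            window_probability_series(
                RRSeries(np.full(40, 900.0), source="synthetic"),
                self.band,
                WindowConfig(10, 1),
            )
        ]
        mixed = _group([[0.5, 0.5], [0.5, 0.5]], [7], self.band)
        with pytest.warns(EmptySeriesWarning):
            rows = compare_groups(all_n, mixed)
        by_t = {c.transition: c for c in rows}
        assert not by_t[Transition.AA].computable
        assert math.isnan(by_t[Transition.AA].p_value)
        assert by_t[Transition.NN].computable
        assert by_t[Transition.NN].p_value <= 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups([], _group([[0.5, 0.5], [0.5, 0.5]], [1], self.band))
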