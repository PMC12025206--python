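"""RGBscore and brute-force weight calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rgbelisa as rg

LEVELS = np.array([0.0, 17.6, 44.0, 132.0, 352.0, 880.0])


def const_roi(r, g, b, shape=(4, 4)):
    return (np.full(shape, float(r)), np.full(shape, float(g)), np.full(shape, float(b)))


class TestRgbScore:
    def test_published_linear_weights_on_constant_channels(self):
        # 0.2*100 - 0.3*50 + 0.15*25 = 8.75
        score = rg.rgbscore(const_roi(100, 50, 25), (0.200, -0.300, 0.150))
        assert score == pytest.approx(8.75)

    def test_zero_weights_zero_score(self):
        assert rg.rgbscore(const_roi(17, 211, 3), (0.0, 0.0, 0.0)) == 0.0

    def test_pixel_mean_of_single_channel(self):
        R = np.array([[10.0], [30.0]])
        G = np.array([[20.0], [20.0]])
        B = np.array([[30.0], [10.0]])
        assert rg.rgbscore((R, G, B), (1.0, 0.0, 0.0)) == pytest.approx(20.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rg.rgbscore((np.zeros((2, 2)), np.zeros((2, 3)), np.zeros((2, 2))), (1, 1, 1))

    @settings(deadline=None, max_examples=25)
    @given(
        w1=st.tuples(*[st.floats(-1, 1) for _ in range(3)]),
        w2=st.tuples(*[st.floats(-1, 1) for _ in range(3)]),
        seed=st.integers(0, 2**16),
    )
    def test_linearity_in_weights(self, w1, w2, seed):
        rng = np.random.default_rng(seed)
        roi = tuple(rng.uniform(0, 255, (5, 5)) for _ in range(3))
        w_sum = tuple(a + b for a, b in zip(w1, w2))
        assert rg.rgbscore(roi, w_sum) == pytest.approx(
            rg.rgbscore(roi, w1) + rg.rgbscore(roi, w2), rel=1e-9, abs=1e-9
        )


class TestWeightGrid:
    def test_default_grid_size(self):
        W = rg.weight_grid(0.05)
        assert W.shape == (41**3 - 1, 3)

    def test_zero_triple_excluded_and_lex_order(self):
        W = rg.weight_grid(0.5)
        assert W.shape == (5**3 - 1, 3)
        assert not any(np.all(row == 0.0) for row in W)
        keys = [tuple(row) for row in W]
        assert keys == sorted(keys)

    def test_values_are_integer_step_multiples(self):
        W = rg.weight_grid(0.05)
        assert np.all(W == np.round(W / 0.05) * 0.05)

    def test_uneven_step_rejected(self):
        with pytest.raises(ValueError):
            rg.weight_grid(0.3)


class TestGridSearch:
    def test_exact_linear_combination_recovered(self):
        # R - G is exactly linear in concentration; every other direction
        # is contaminated by the shared nonlinearity h or by B
        h = 10.0 * np.sqrt(LEVELS)
        pairs = []
        for conc, hi, bi in zip(LEVELS, h, 5.0 * np.log1p(LEVELS)):
            pairs.append((conc, (50.0 + 0.1 * conc + hi, 50.0 + hi, 30.0 + bi)))
        series = rg.ConcentrationSeries.from_means(pairs)
        res = rg.coefficient_grid_search(series, models=("linear",), step=0.25)
        m = res.per_model["linear"]
        assert m.fit.r_squared == pytest.approx(1.0, abs=1e-9)
        w = m.weights.as_array()
        direction = w / np.linalg.norm(w)
        target = np.array([0.5, -0.5, 0.0]) / np.linalg.norm([0.5, -0.5, 0.0])
        assert min(np.linalg.norm(direction - target), np.linalg.norm(direction + target)) < 1e-9

    def test_identical_levels_forced_tiebreak(self):
        roi = const_roi(120, 80, 60)
        series = rg.ConcentrationSeries.from_means([(c, (120.0, 80.0, 60.0)) for c in LEVELS])
        res = rg.coefficient_grid_search(series, models=("linear",), step=0.5)
        m = res.per_model["linear"]
        assert m.fit.r_squared == 0.0
        assert (m.weights.alpha, m.weights.beta, m.weights.gamma) == (-1.0, -1.0, -1.0)

    def test_weight_scaling_leaves_r2_invariant(self):
        rng = np.random.default_rng(7)
        means = np.column_stack([
            200 - 0.1 * LEVELS + rng.normal(0, 1, 6),
            180 - 0.05 * LEVELS + rng.normal(0, 1, 6),
            150 - 0.2 * LEVELS + rng.normal(0, 1, 6),
        ])
        for kind in rg.MODEL_KINDS:
            y1 = means @ np.array([0.3, -0.2, 0.1])
            y2 = means @ (4.0 * np.array([0.3, -0.2, 0.1]))
            r2_1 = rg.fit_model(kind, LEVELS, y1).r_squared
            r2_2 = rg.fit_model(kind, LEVELS, y2).r_squared
            assert r2_2 == pytest.approx(r2_1, abs=1e-6)

    def test_stored_r2_consistent_with_scores(self):
        rng = np.random.default_rng(11)
        means = np.column_stack([
            230 - 20 * np.log1p(LEVELS) / 7 + rng.normal(0, 0.5, 6),
            220 - 40 * np.log1p(LEVELS) / 7 + rng.normal(0, 0.5, 6),
            210 - 90 * np.log1p(LEVELS) / 7 + rng.normal(0, 0.5, 6),
        ])
        series = rg.ConcentrationSeries.from_means(list(zip(LEVELS, means)))
        res = rg.coefficient_grid_search(series, step=0.25)
        for m in res.per_model.values():
            concs = np.array([c for c, _ in m.scores])
            scores = np.array([s for _, s in m.scores])
            assert m.fit.r_squared == pytest.approx(
                rg.r_squared(scores, m.fit.predict(concs)), abs=1e-9
            )

    def test_requires_three_distinct_levels(self):
        series = rg.ConcentrationSeries.from_means(
            [(0.0, (1, 2, 3)), (0.0, (2, 3, 4)), (10.0, (3, 4, 5))]
        )
        with pytest.raises(ValueError):
            rg.coefficient_grid_search(series, step=0.5)

    def test_empty_model_set_rejected(self):
        series = rg.ConcentrationSeries.from_means([(c, (c, c, c)) for c in (0.0, 1.0, 2.0)])
        with pytest.raises(ValueError):
            rg.coefficient_grid_search(series, models=(), step=0.5)
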