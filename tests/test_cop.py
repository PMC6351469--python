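import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oculopost.cop import (
    compute_postural_score,
    fit_quiet_unquiet_model,
    postural_score_from_fractions,
    swarii_resample,
    window_descriptors,
)
from oculopost.types import InvalidInputError, RawCoPRecording, UniformCoPSignal


def _rec(t, x, y=None, cond="EO"):
    x = np.asarray(x, dtype=float)
    return RawCoPRecording("s", cond, np.asarray(t, dtype=float), x, x if y is None else y)


class TestSwarii:
    def test_constant_preserved_exactly(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 10, 200))
        t[0], t[-1] = 0.0, 10.0
        sig = swarii_resample(_rec(t, np.full(200, 5.0)), rate=25.0)
        assert np.all(sig.x == 5.0)
        assert np.all(sig.y == 5.0)

    def test_symmetric_linear_samples_average_to_grid_value(self):
        # x(t) = t sampled symmetrically around the grid point 0.2
        t = np.array([0.0, 0.19, 0.21, 0.4])
        sig = swarii_resample(_rec(t, t), rate=25.0, window=0.04)
        g = sig.t0 + np.arange(len(sig.x)) / 25.0
        k = int(np.argmin(np.abs(g - 0.2)))
        assert g[k] == pytest.approx(0.2)
        assert sig.x[k] == pytest.approx(0.2, abs=1e-12)

    def test_interpolation_fallback_exact(self):
        # rate chosen so t=0.5 is a grid node with an empty 0.04 s window
        sig = swarii_resample(_rec([0.0, 1.0], [0.0, 10.0]), rate=2.0, window=0.04)
        assert sig.t[1] == pytest.approx(0.5)
        assert sig.x[1] == pytest.approx(5.0, abs=1e-12)

    def test_interpolation_fallback_on_25hz_grid(self):
        sig = swarii_resample(_rec([0.0, 1.0], [0.0, 10.0]), rate=25.0, window=0.04)
        k = 12  # grid node at 0.48 s, empty window
        assert sig.t[k] == pytest.approx(0.48)
        assert sig.x[k] == pytest.approx(4.8, abs=1e-12)

    def test_grid_spans_record(self):
        sig = swarii_resample(_rec([0.0, 2.0], [1.0, 1.0]), rate=25.0)
        assert sig.t0 == 0.0
        assert len(sig.x) == 51

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidInputError):
            _rec([0.0], [1.0])

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_output_within_raw_envelope(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 80)
        t = np.sort(rng.uniform(0, 5, n))
        t += np.arange(n) * 1e-6  # ensure strict increase
        v = rng.normal(size=n)
        sig = swarii_resample(_rec(t, v), rate=25.0, window=0.08)
        assert sig.x.min() >= v.min() - 1e-9
        assert sig.x.max() <= v.max() + 1e-9


class TestWindowDescriptors:
    def test_25s_gives_25_windows(self):
        sig = UniformCoPSignal(rate=25.0, x=np.zeros(625), y=np.zeros(625))
        assert len(window_descriptors(sig, 1.0, 25.0)) == 25

    def test_stationary_signal_all_zero(self):
        sig = UniformCoPSignal(rate=25.0, x=np.full(625, 2.0), y=np.full(625, -1.0))
        d = window_descriptors(sig).descriptors
        assert np.all(d == 0.0)

    def test_short_signal_rejected(self):
        sig = UniformCoPSignal(rate=25.0, x=np.zeros(100), y=np.zeros(100))
        with pytest.raises(InvalidInputError):
            window_descriptors(sig, 1.0, 25.0)

    def test_planted_quiet_burst_split_is_bimodal(self):
        # 12 quiet and 13 burst one-second windows, amplitude ratio 4x
        rng = np.random.default_rng(3)
        parts, labels = [], []
        for k in range(25):
            sd = 1.2 if k % 2 else 0.3
            labels.append(k % 2)
            parts.append(rng.normal(0, sd, 25))
        x = np.concatenate(parts)
        sig = UniformCoPSignal(rate=25.0, x=x, y=np.zeros_like(x))
        d = window_descriptors(sig)
        norms = np.linalg.norm(d.descriptors, axis=1)
        thr = (norms.min() + norms.max()) / 2
        assert np.array_equal(norms > thr, np.array(labels, dtype=bool))


class TestQuietUnquietModel:
    @staticmethod
    def _two_clouds(seed=0, n=1000, w=0.7):
        rng = np.random.default_rng(seed)
        n1 = int(round(n * w))
        a = rng.normal(0.0, 1.0, (n1, 3))
        b = rng.normal(10.0, 1.0, (n - n1, 3))  # > 6 pooled SDs apart
        return np.vstack([a, b])

    def test_planted_mixture_recovery(self):
        model = fit_quiet_unquiet_model(self._two_clouds(), seed=0)
        w = np.sort(model.weights)
        assert w[0] == pytest.approx(0.3, abs=0.05)
        assert w[1] == pytest.approx(0.7, abs=0.05)
        assert np.linalg.norm(model.means[model.unquiet_component]) > np.linalg.norm(
            model.means[1 - model.unquiet_component]
        )

    def test_degenerate_all_identical(self):
        X = np.ones((50, 3))
        model = fit_quiet_unquiet_model(X, seed=0)
        assert model.degenerate
        assert not model.label_unquiet(X).any()

    def test_deterministic_given_seed(self):
        X = self._two_clouds(seed=5)
        m1 = fit_quiet_unquiet_model(X, seed=11)
        m2 = fit_quiet_unquiet_model(X, seed=11)
        np.testing.assert_array_equal(m1.means, m2.means)
        np.testing.assert_array_equal(m1.weights, m2.weights)

    def test_too_few_windows_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_quiet_unquiet_model(np.zeros((10, 3)), seed=0)


class TestPosturalScore:
    def test_formula_oracle(self):
        assert postural_score_from_fractions(0.4, 0.6) == pytest.approx(50.0)
        assert postural_score_from_fractions(0.0, 0.0) == pytest.approx(100.0)
        assert postural_score_from_fractions(1.0, 1.0) == pytest.approx(0.0)

    @given(
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0.001, max_value=0.2),
    )
    def test_bounded_and_strictly_decreasing(self, f_eo, f_ec, eps):
        s = postural_score_from_fractions(f_eo, f_ec)
        assert 0.0 <= s <= 100.0
        if f_eo + eps <= 1.0:
            assert postural_score_from_fractions(f_eo + eps, f_ec) < s
        if f_ec + eps <= 1.0:
            assert postural_score_from_fractions(f_eo, f_ec + eps) < s

    def test_missing_condition_rejected(self):
        model = fit_quiet_unquiet_model(TestQuietUnquietModel._two_clouds(), seed=0)
        sig = UniformCoPSignal(rate=25.0, x=np.zeros(625), y=np.zeros(625))
        d = window_descriptors(sig)
        with pytest.raises(InvalidInputError):
            compute_postural_score(model, d, None)

    def test_labelled_scoring_on_separated_clouds(self):
        model = fit_quiet_unquiet_model(TestQuietUnquietModel._two_clouds(), seed=0)
        quiet = np.random.default_rng(1).normal(0.0, 1.0, (25, 3))
        loud = np.random.default_rng(2).normal(10.0, 1.0, (25, 3))
        from oculopost.cop import WindowDescriptorSet

        d_eo = WindowDescriptorSet(1.0, np.abs(quiet), np.arange(25.0))
        d_ec = WindowDescriptorSet(1.0, np.abs(loud), np.arange(25.0))
        ps = compute_postural_score(model, d_eo, d_ec, "s")
        assert ps.f_eo < 0.1 and ps.f_ec > 0.9
        assert ps.score == pytest.approx(100 * ((1 - ps.f_eo) + (1 - ps.f_ec)) / 2)
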