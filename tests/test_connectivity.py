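import numpy as np
import pytest

from fcmst import (
    DegeneratePhaseError,
    InvalidParameterError,
    Recording,
    broadband_filter,
    connectivity_matrix,
    instantaneous_phase,
    pli,
    plv,
    wrap_phase,
)

from _oracles import dft_analytic_signal

FS = 512.0


def cosine_channels(lags, freq=10.0, duration=4.0, fs=FS):
    """(channels, samples) cosines sharing a carrier with constant lags."""
    t = np.arange(0, duration, 1 / fs)
    return np.vstack([np.cos(2 * np.pi * freq * t - lag) for lag in lags])


class TestWrapPhase:
    def test_interval_convention(self):
        assert wrap_phase(np.pi) == pytest.approx(np.pi)
        assert wrap_phase(-np.pi) == pytest.approx(np.pi)
        assert wrap_phase(3 * np.pi) == pytest.approx(np.pi)
        assert wrap_phase(0.3) == pytest.approx(0.3)
        assert wrap_phase(2 * np.pi + 0.1) == pytest.approx(0.1)


class TestInstantaneousPhase:
    def test_cosine_phase_slope(self):
        x = cosine_channels([0.0, 0.0])
        ph = instantaneous_phase(x, fs=FS)
        unwrapped = np.unwrap(ph.interior_phases()[0])
        slope = np.polyfit(
            np.arange(unwrapped.size) / FS, unwrapped, 1
        )[0]
        assert slope == pytest.approx(2 * np.pi * 10, rel=1e-3)

    def test_constant_lag_delta_phase(self):
        x = cosine_channels([0.0, np.pi / 3])
        ph = instantaneous_phase(x, fs=FS).interior_phases()
        dphi = wrap_phase(ph[0] - ph[1])
        assert np.abs(dphi - np.pi / 3).max() < 0.01

    def test_matches_dft_analytic_signal_oracle(self, rng):
        x = rng.normal(size=(2, 1024))
        x = broadband_filter(Recording(x.T, FS), 4, 30).data.T
        ph = instantaneous_phase(x, fs=FS)
        for c in range(2):
            oracle = np.angle(dft_analytic_signal(x[c]))
            assert np.allclose(ph.phases[c], oracle, atol=1e-9)

    def test_edge_exclusion_default(self):
        ph = instantaneous_phase(cosine_channels([0.0, 0.1]), fs=FS)
        n = ph.phases.shape[1]
        assert ph.interior_phases().shape[1] == n - 2 * int(round(0.05 * n))

    def test_all_zero_channel_rejected(self):
        x = cosine_channels([0.0, 0.0])
        x[1] = 0.0
        with pytest.raises(DegeneratePhaseError, match="1"):
            instantaneous_phase(x, fs=FS)

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidParameterError):
            instantaneous_phase(np.ones((2, 32)), fs=FS)


class TestPliPlv:
    def test_pli_constant_nonzero_lag_is_one(self):
        assert pli(np.full(100, np.pi / 2)) == 1.0

    def test_pli_zero_lag_is_zero(self):
        assert pli(np.zeros(100)) == 0.0

    def test_pli_hand_example(self):
        assert pli([0.3, 0.5, -0.2, 0.4]) == pytest.approx(0.5)

    def test_plv_constant_lag_is_one(self):
        for value in (0.0, 1.2, np.pi):
            assert plv(np.full(64, value)) == pytest.approx(1.0)

    def test_plv_antipodal_cancels(self):
        assert plv([0.0, np.pi]) == pytest.approx(0.0, abs=1e-12)

    def test_plv_hand_example(self):
        assert plv([0.0, np.pi / 2]) == pytest.approx(np.sqrt(2) / 2)

    @pytest.mark.parametrize("fn", [pli, plv])
    def test_empty_series_rejected(self, fn):
        with pytest.raises(InvalidParameterError):
            fn([])

    def test_measures_bounded_and_agree_on_extremes(self, rng):
        """Range and extreme-case behaviour over 1000 random series.

        Both measures live in [0, 1].  PLI does NOT generally stay below
        PLV: any series confined to one half of the circle but scattered
        there has PLI = 1 and PLV < 1 (see the explicit counterexample
        below), so no ordering between the two is asserted.  What does
        hold: a series symmetric under negation has PLI = 0, and a
        constant series maximises both.
        """
        for _ in range(1000):
            kind = rng.integers(3)
            n = int(rng.integers(5, 200))
            if kind == 0:
                d = rng.uniform(-np.pi, np.pi, n)
            elif kind == 1:
                d = rng.normal(rng.uniform(-3, 3), rng.uniform(0.01, 2), n)
            else:
                d = np.full(n, rng.uniform(-np.pi, np.pi)) + rng.normal(
                    0, 0.2, n
                )
            assert 0.0 <= pli(d) <= 1.0
            assert 0.0 <= plv(d) <= 1.0 + 1e-12
            sym = np.concatenate([d, -d])
            assert pli(sym) == pytest.approx(0.0, abs=1e-12)

    def test_one_sided_scatter_puts_pli_above_plv(self):
        # all-negative but scattered: perfect sign asymmetry, imperfect
        # phasor concentration
        d = np.array([-1.4, -1.0, -1.2, -0.8])
        assert pli(d) == 1.0
        assert plv(d) < 1.0


class TestConnectivityMatrix:
    def test_identical_channels(self):
        x = cosine_channels([0.0, 0.0])
        ph = instantaneous_phase(x, fs=FS)
        assert connectivity_matrix(ph, "PLV").weights[0, 1] == pytest.approx(1.0)
        assert connectivity_matrix(ph, "PLI").weights[0, 1] == 0.0

    def test_three_channel_constant_lags_match_pairwise_oracle(self):
        lags = [0.0, np.pi / 4, 3 * np.pi / 4]  # pairwise {pi/4, pi/2, pi/4}
        x = cosine_channels(lags)
        ph = instantaneous_phase(x, fs=FS)
        for measure, fn in (("PLI", pli), ("PLV", plv)):
            mat = connectivity_matrix(ph, measure).weights
            assert np.allclose(mat, mat.T)
            inner = ph.interior_phases()
            for i in range(3):
                for j in range(i + 1, 3):
                    expected = fn(wrap_phase(inner[i] - inner[j]))
                    assert mat[i, j] == pytest.approx(expected, abs=1e-9)
                    if measure == "PLI":
                        assert mat[i, j] > 0.99
        assert connectivity_matrix(ph, "PLI").weights.diagonal().max() == 0.0
        assert connectivity_matrix(ph, "PLV").weights.diagonal().min() == 1.0

    def test_zero_lag_mixing_fools_plv_not_pli(self, rng):
        """Two channels a*s(t), b*s(t): the shared-source analogue.

        PLI must stay at the floor while PLV registers near-perfect
        synchrony.
        """
        s = broadband_filter(
            Recording(rng.normal(size=(4096, 2)), FS), 8, 12
        ).data[:, 0]
        x = np.vstack([2.0 * s, 0.5 * s])
        ph = instantaneous_phase(x, fs=FS)
        assert connectivity_matrix(ph, "PLI").weights[0, 1] <= 0.05
        assert connectivity_matrix(ph, "PLV").weights[0, 1] >= 0.95

    def test_epoch_averaging_is_arithmetic_mean(self, rng):
        eps = []
        for _ in range(2):
            x = broadband_filter(
                Recording(rng.normal(size=(512, 3)), FS), 6, 20
            ).data.T
            eps.append(instantaneous_phase(x, fs=FS))
        for measure in ("PLI", "PLV"):
            combined = connectivity_matrix(eps, measure).weights
            singles = [connectivity_matrix(e, measure).weights for e in eps]
            assert np.allclose(combined, np.mean(singles, axis=0), atol=1e-12)

    def test_channel_count_mismatch_rejected(self, rng):
        a = instantaneous_phase(np.cos(rng.normal(size=(2, 128))), fs=FS)
        b = instantaneous_phase(np.cos(rng.normal(size=(3, 128))), fs=FS)
        with pytest.raises(InvalidParameterError):
            connectivity_matrix([a, b], "PLI")

    def test_unknown_measure_rejected(self):
        ph = instantaneous_phase(cosine_channels([0.0, 0.2]), fs=FS)
        with pytest.raises(InvalidParameterError):
            connectivity_matrix(ph, "wpli")
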