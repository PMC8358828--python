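"""Field autocorrelation, coherence factor, Siegert mapping and noise."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tddcs.correlation import (
    NoiseModelParams,
    WavelengthContext,
    beta_from_pathlengths,
    coherence_length_gaussian,
    fit_gamma,
    g1_from_histories,
    g2_noise_sigma,
    multitau_grid,
    noisy_g2_series,
    siegert,
)
from tddcs.gating import DiscreteDistribution, TimeGate, allocate_gate, build_tpsf
from tddcs.media import two_layer_slab
from tddcs.transport import C0_MM_PS, HistoryEnsemble, PhotonHistory

CTX = WavelengthContext(765)


def _gated(histories, medium):
    ens = HistoryEnsemble.from_histories(histories, medium)
    mua = medium.mua_cm()
    tpsf = build_tpsf(ens, mua)
    return allocate_gate(ens, ens.tof_ps, tpsf, TimeGate(-1e6, 2e6), mua)


def _hand_histories(medium):
    n = medium.layers[0].n
    rows = [
        (np.array([40.0, 10.0]), np.array([35.0, 8.0])),
        (np.array([80.0, 30.0]), np.array([70.0, 25.0])),
        (np.array([25.0, 0.0]), np.array([20.0, 0.0])),
    ]
    return [
        PhotonHistory(L, Y, n * L.sum() / C0_MM_PS) for L, Y in rows
    ]


class TestG1:
    def test_static_medium_gives_unity(self):
        medium = two_layer_slab()
        g = _gated(_hand_histories(medium), medium)
        tau = np.array([0.0, 1e-6, 1e-4])
        np.testing.assert_allclose(
            g1_from_histories(g, np.zeros(2), medium.mua_cm(), CTX, tau), 1.0
        )

    def test_normalized_at_tau_zero(self):
        medium = two_layer_slab()
        g = _gated(_hand_histories(medium), medium)
        g1 = g1_from_histories(
            g, np.array([1e-6, 6e-6]), medium.mua_cm(), CTX, np.array([0.0])
        )
        assert g1[0] == pytest.approx(1.0, rel=1e-15)

    def test_three_histories_match_brute_force_sum(self):
        """Direct evaluation of the momentum-transfer sum, term by term."""
        medium = two_layer_slab()
        hist = _hand_histories(medium)
        g = _gated(hist, medium)
        D = np.array([1e-6, 6e-6])
        mua_mm = medium.mua_cm() / 10.0
        tau = np.array([0.0, 1e-6, 1e-5, 1e-4])
        k0 = CTX.k0_per_mm
        num = np.zeros_like(tau)
        den = 0.0
        for h in hist:
            w = math.exp(-float(mua_mm @ h.L_mm))
            den += w
            for i, t in enumerate(tau):
                num[i] += w * math.exp(-2.0 * k0**2 * t * float(h.Y @ D))
        expected = num / den
        got = g1_from_histories(g, D, medium.mua_cm(), CTX, tau)
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_monotone_decay_and_negative_D_rejected(self):
        medium = two_layer_slab()
        g = _gated(_hand_histories(medium), medium)
        tau = multitau_grid()
        g1 = g1_from_histories(g, np.array([1e-6, 6e-6]), medium.mua_cm(), CTX, tau)
        assert np.all(np.diff(g1) <= 1e-15)
        with pytest.raises(ValueError):
            g1_from_histories(g, np.array([-1e-6, 6e-6]), medium.mua_cm(), CTX, tau)


class TestBeta:
    def test_atomic_distribution_gives_unity(self):
        atom = DiscreteDistribution(np.array([100.0]), np.array([1.0]))
        for lc in (0.5, 5.0, math.inf):
            assert beta_from_pathlengths(atom, lc) == pytest.approx(1.0)

    def test_infinite_coherence_gives_unity(self):
        d = DiscreteDistribution(
            np.array([50.0, 150.0, 400.0]), np.array([0.2, 0.5, 0.3])
        )
        assert beta_from_pathlengths(d, math.inf) == pytest.approx(1.0)

    def test_two_point_closed_form(self):
        lc_cm = 5.0
        dl_mm = lc_cm * 10.0  # separation of one coherence length
        d = DiscreteDistribution(
            np.array([100.0, 100.0 + dl_mm]), np.array([0.5, 0.5])
        )
        expected = 0.5 + 0.5 * math.exp(-2.0)
        assert beta_from_pathlengths(d, lc_cm) == pytest.approx(expected, rel=1e-12)

    def test_unnormalized_distribution_rejected(self):
        d = DiscreteDistribution(np.array([1.0, 2.0]), np.array([0.5, 0.4]))
        with pytest.raises(ValueError, match="normalized"):
            beta_from_pathlengths(d, 5.0)

    @given(lc=st.floats(1.0, 50.0), factor=st.floats(1.01, 3.0))
    def test_beta_increases_with_coherence_length(self, lc, factor):
        d = DiscreteDistribution(
            np.array([80.0, 120.0, 200.0, 350.0]),
            np.array([0.3, 0.3, 0.25, 0.15]),
        )
        assert beta_from_pathlengths(d, lc * factor) >= beta_from_pathlengths(d, lc)

    @given(delta=st.floats(1.0, 40.0))
    def test_mean_preserving_spread_lowers_beta(self, delta):
        base = DiscreteDistribution(
            np.array([100.0, 200.0]), np.array([0.5, 0.5])
        )
        spread = DiscreteDistribution(
            np.array([100.0 - delta, 100.0 + delta, 200.0]),
            np.array([0.25, 0.25, 0.5]),
        )
        assert beta_from_pathlengths(spread, 5.0) <= beta_from_pathlengths(base, 5.0)


class TestCoherenceLength:
    def test_printed_300ps_value(self):
        assert round(coherence_length_gaussian(300.0, 1.4), 1) == 4.6

    def test_linear_in_fwhm(self):
        a = coherence_length_gaussian(200.0)
        b = coherence_length_gaussian(400.0)
        assert b == pytest.approx(2.0 * a, rel=1e-12)

    def test_detector_deconvolved_variant(self):
        fwhm = math.sqrt(300.0**2 - 90.0**2)  # 286.2 ps
        assert coherence_length_gaussian(fwhm, 1.4) == pytest.approx(4.42, abs=0.01)


class TestSiegert:
    @pytest.mark.parametrize(
        "g1,beta,expected", [(1.0, 0.5, 1.5), (0.0, 0.9, 1.0), (0.6, 0.5, 1.18)]
    )
    def test_values(self, g1, beta, expected):
        assert siegert(np.array([g1]), beta)[0] == pytest.approx(expected)

    def test_beta_bounds(self):
        with pytest.raises(ValueError):
            siegert(np.array([1.0]), 0.0)
        with pytest.raises(ValueError):
            siegert(np.array([1.0]), 1.5)


class TestNoiseModel:
    PARAMS = dict(T_s=1e-6, gamma_hz=2e4, n_avg=0.5, beta=0.5)

    def test_sigma_scales_as_inverse_sqrt_averaging_time(self):
        tau = multitau_grid()
        s1 = g2_noise_sigma(NoiseModelParams(t_s=1.0, **self.PARAMS), tau)
        s4 = g2_noise_sigma(NoiseModelParams(t_s=4.0, **self.PARAMS), tau)
        np.testing.assert_allclose(s4, s1 / 2.0, rtol=1e-12)

    def test_high_count_limit_keeps_only_speckle_term(self):
        tau = np.array([3e-6])
        p = NoiseModelParams(t_s=1.0, T_s=1e-6, gamma_hz=2e4, n_avg=1e12, beta=0.5)
        sig = g2_noise_sigma(p, tau)
        # hand-evaluated speckle bracket at m = 3
        G, T, beta, m = 2e4, 1e-6, 0.5, 3.0
        bracket = beta**2 * (
            (1 + math.exp(-2 * G * T)) * (1 + math.exp(-2 * G * m * T))
            + 2 * m * (1 - math.exp(-2 * G * T)) * math.exp(-2 * G * m * T)
        ) / (1 - math.exp(-2 * G * T))
        assert sig[0] == pytest.approx(math.sqrt(T / 1.0) * math.sqrt(bracket),
                                       rel=1e-9)

    def test_full_form_pinned_value(self):
        # freezes the chosen reading of the noise formula at one point
        tau = np.array([2e-6])
        p = NoiseModelParams(t_s=1.0, T_s=1e-6, gamma_hz=3e4, n_avg=0.4, beta=0.6)
        G, T, n, beta, m = 3e4, 1e-6, 0.4, 0.6, 2.0
        e2gt = math.exp(-2 * G * T)
        e2gtau = math.exp(-2 * G * m * T)
        egtau = math.exp(-G * m * T)
        bracket = (
            beta**2 * ((1 + e2gt) * (1 + e2gtau) + 2 * m * (1 - e2gt) * e2gtau)
            / (1 - e2gt)
            + 2 / n * beta * (1 + e2gtau)
            + 1 / n**2 * (1 + beta * egtau)
        )
        assert g2_noise_sigma(p, tau)[0] == pytest.approx(
            math.sqrt(T) * math.sqrt(bracket), rel=1e-12
        )

    @given(
        gamma=st.floats(1e2, 1e7),
        n_avg=st.floats(1e-3, 1e3),
        beta=st.floats(0.01, 1.0),
    )
    def test_sigma_positive_everywhere(self, gamma, n_avg, beta):
        p = NoiseModelParams(t_s=1.0, T_s=1e-6, gamma_hz=gamma, n_avg=n_avg,
                             beta=beta)
        assert np.all(g2_noise_sigma(p, multitau_grid()) > 0)

    def test_extreme_gamma_guarded(self):
        tau = multitau_grid()
        for gamma in (1e-3, 1e12):
            p = NoiseModelParams(t_s=1.0, T_s=1e-6, gamma_hz=gamma, n_avg=0.5,
                                 beta=0.5)
            assert np.all(np.isfinite(g2_noise_sigma(p, tau)))


class TestNoisyRealizations:
    def test_zero_sigma_reproduces_curve(self):
        g2 = 1.0 + 0.5 * np.exp(-np.arange(10.0))
        out = noisy_g2_series(g2, np.zeros(10), 5, seed=1)
        assert out.shape == (5, 10)
        np.testing.assert_array_equal(out, np.tile(g2, (5, 1)))

    def test_sample_std_matches_sigma(self):
        g2 = np.full(6, 1.3)
        sigma = np.array([0.1, 0.05, 0.02, 0.01, 0.005, 0.002])
        out = noisy_g2_series(g2, sigma, 10_000, seed=2)
        np.testing.assert_allclose(out.std(axis=0, ddof=1), sigma, rtol=0.03)

    def test_default_realization_count_is_120(self):
        out = noisy_g2_series(np.ones(3), np.full(3, 0.01))
        assert out.shape[0] == 120


def test_correlation_curve_csv_round_trip(tmp_path):
    from tddcs.correlation import CorrelationCurve

    tau = multitau_grid()
    g1 = np.exp(-2e4 * tau)
    curve = CorrelationCurve(tau, g1, 1 + 0.5 * g1**2, beta=0.5,
                             sigma=np.full(len(tau), 0.01))
    path = tmp_path / "curve.csv"
    curve.save(path, sidecar={"Lc_cm": 4.6, "count_rate_cps": 1e5})
    back = CorrelationCurve.load(path)
    np.testing.assert_allclose(back.g2, curve.g2)
    np.testing.assert_allclose(back.sigma, curve.sigma)
    assert back.beta == 0.5


def test_fit_gamma_recovers_exponential_rate():
    tau = multitau_grid()
    g1 = np.exp(-2.5e4 * tau)
    assert fit_gamma(tau, g1) == pytest.approx(2.5e4, rel=1e-6)
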