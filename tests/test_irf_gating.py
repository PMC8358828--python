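"""IRF sampling, TPSF construction, gate allocation and count rates."""

import numpy as np
import pytest
from scipy import stats

from tddcs.gating import (
    EmptyGateError,
    TimeGate,
    allocate_gate,
    apparent_tofs,
    build_tpsf,
    gate_count_rate,
)
from tddcs.irf import (
    DeltaIRF,
    ExGaussianIRF,
    GaussianIRF,
    HistogramIRF,
    load_histogram_irf,
    parse_irf,
    sample_jitter,
)
from tddcs.media import two_layer_slab
from tddcs.transport import C0_MM_PS, HistoryEnsemble, PhotonHistory


def _toy_ensemble(tofs_ps, medium=None, L_frac_deep=0.3):
    """Hand-built two-layer ensemble with prescribed tissue ToFs."""
    medium = medium or two_layer_slab()
    n = medium.layers[0].n
    hist = []
    for t in tofs_ps:
        L = t * C0_MM_PS / n
        Ld = L * L_frac_deep
        hist.append(
            PhotonHistory(np.array([L - Ld, Ld]), np.array([L - Ld, Ld]) * 0.968, t)
        )
    return HistoryEnsemble.from_histories(hist, medium, n_launched=10 * len(hist))


class TestJitterSampling:
    def test_delta_irf_draws_are_zero(self):
        j = sample_jitter(DeltaIRF(), 1000, seed=0)
        assert np.all(j == 0.0)

    def test_gaussian_sample_std_matches_fwhm(self):
        j = sample_jitter(GaussianIRF(300.0), 1_000_000, seed=1)
        expected = 300.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 127.4 ps
        assert j.std() == pytest.approx(expected, rel=0.01)
        assert abs(j.mean()) < 1.0

    def test_histogram_sampling_passes_ks(self):
        t = np.linspace(0.0, 2000.0, 400)
        counts = np.exp(-0.5 * ((t - 500.0) / 120.0) ** 2) + 0.3 * np.exp(
            -np.maximum(t - 500.0, 0.0) / 400.0
        )
        irf = HistogramIRF(t, counts)
        j = sample_jitter(irf, 1_000_000, seed=2)
        ks = stats.kstest(j, irf.cdf).statistic
        assert ks < 1.63 / np.sqrt(1e6)  # 1% critical value

    def test_jitter_is_deterministic(self):
        irf = GaussianIRF(250.0)
        np.testing.assert_array_equal(
            sample_jitter(irf, 2, seed=7), sample_jitter(irf, 2, seed=7)
        )

    def test_irf_pdfs_are_normalized_with_mode_at_zero(self):
        t = np.linspace(-4000, 12000, 160001)
        for irf in (
            GaussianIRF(300.0),
            ExGaussianIRF(300.0, 800.0, 0.3),
            HistogramIRF(np.linspace(0, 3000, 300),
                         np.exp(-((np.linspace(0, 3000, 300) - 900) / 200) ** 2)),
        ):
            pdf = irf.pdf(t)
            assert np.all(pdf >= 0)
            assert np.trapezoid(pdf, t) == pytest.approx(1.0, abs=1e-3)
            assert abs(t[np.argmax(pdf)]) < 5.0
            cdf = irf.cdf(t)
            assert np.all(np.diff(cdf) >= -1e-12)
            assert cdf[0] < 1e-6 and cdf[-1] > 1 - 1e-6

    def test_parse_irf_specs(self, tmp_path):
        assert isinstance(parse_irf("delta"), DeltaIRF)
        assert parse_irf("gaussian:300").fwhm_ps == 300.0
        x = parse_irf("exgauss:300,800,0.3")
        assert (x.fwhm_ps, x.tail_tau_ps, x.tail_fraction) == (300.0, 800.0, 0.3)
        t = np.linspace(0, 1000, 100)
        np.savetxt(tmp_path / "irf.txt",
                   np.column_stack([t, np.exp(-((t - 300) / 80) ** 2)]))
        assert isinstance(parse_irf(str(tmp_path / "irf.txt")), HistogramIRF)


class TestApparentTof:
    def test_delta_irf_is_identity(self):
        ens = _toy_ensemble([100.0, 500.0, 900.0])
        np.testing.assert_array_equal(
            apparent_tofs(ens, DeltaIRF(), 0), ens.tof_ps
        )

    def test_apparent_histogram_matches_convolution(self):
        # apparent-ToF density must equal tissue density (x) IRF pdf
        rng = np.random.default_rng(5)
        tofs = rng.gamma(4.0, 150.0, size=200_000)
        ens = _toy_ensemble(tofs)
        irf = GaussianIRF(300.0)
        app = apparent_tofs(ens, irf, 6)
        bin_ps = 50.0
        edges = np.arange(-1500.0, 4500.0, bin_ps)
        h_app, _ = np.histogram(app, bins=edges, density=True)
        h_tis, _ = np.histogram(ens.tof_ps, bins=edges, density=True)
        kernel = irf.pdf(np.arange(-1000, 1000.1, bin_ps))
        conv = np.convolve(h_tis, kernel / kernel.sum(), mode="same")
        # compare where the convolved density carries real mass
        sel = conv > 0.2 * conv.max()
        assert np.sqrt(np.mean((h_app[sel] - conv[sel]) ** 2)) < 0.05 * conv.max()


class TestTpsf:
    def test_single_photon_single_bin(self):
        ens = _toy_ensemble([333.0])
        tpsf = build_tpsf(ens, ens.medium.mua_cm(), bin_ps=10.0)
        assert np.count_nonzero(tpsf.fluence) == 1
        assert tpsf.peak_time_ps == pytest.approx(333.0, abs=5.0)

    def test_zero_absorption_equals_raw_histogram(self):
        ens = _toy_ensemble([100.0, 100.0, 400.0, 800.0])
        tpsf = build_tpsf(ens, np.zeros(2), bin_ps=10.0)
        raw, _ = np.histogram(ens.tof_ps, bins=tpsf.bin_edges_ps)
        np.testing.assert_allclose(tpsf.fluence * tpsf.bin_width_ps, raw)

    def test_absorption_reweighting_matches_direct_recomputation(self):
        ens = _toy_ensemble([150.0, 420.0, 770.0, 1200.0])
        mua = ens.medium.mua_cm()
        mua2 = mua.copy()
        mua2[1] *= 2.0
        t1 = build_tpsf(ens, mua, bin_ps=10.0)
        t2 = build_tpsf(ens, mua2, bin_ps=10.0)
        # doubling layer-1 mua multiplies each photon by exp(-mua1 * L1)
        extra = np.exp(-(mua[1] / 10.0) * ens.L_mm[:, 1])
        direct, _ = np.histogram(
            ens.tof_ps, bins=t1.bin_edges_ps, weights=ens.weights(mua) * extra
        )
        np.testing.assert_allclose(t2.fluence * t2.bin_width_ps, direct, rtol=1e-12)

    def test_peak_and_membership_shift_invariance(self):
        ens = _toy_ensemble(list(np.linspace(100, 1500, 300)))
        mua = ens.medium.mua_cm()
        app = apparent_tofs(ens, GaussianIRF(200.0), 3)
        shift = 120.0  # a multiple of the bin width
        t1 = build_tpsf(ens, mua, apparent_ps=app, bin_ps=10.0)
        t2 = build_tpsf(ens, mua, apparent_ps=app + shift, bin_ps=10.0)
        assert t2.peak_time_ps - t1.peak_time_ps == pytest.approx(shift)
        gate = TimeGate(100.0, 300.0)
        g1 = allocate_gate(ens, app, t1, gate, mua)
        g2 = allocate_gate(ens, app + shift, t2, gate, mua)
        np.testing.assert_array_equal(g1.indices, g2.indices)


class TestGateAllocation:
    def test_full_window_holds_everything(self):
        ens = _toy_ensemble(list(np.linspace(50, 900, 40)))
        mua = ens.medium.mua_cm()
        tpsf = build_tpsf(ens, mua)
        gate = TimeGate(-5000.0, 10000.0)
        g = allocate_gate(ens, ens.tof_ps, tpsf, gate, mua)
        assert len(g) == len(ens)
        assert g.P_L.probs.sum() == pytest.approx(1.0)
        assert g.P_ToF.probs.sum() == pytest.approx(1.0)

    def test_late_empty_gate_raises(self):
        ens = _toy_ensemble([100.0, 200.0])
        tpsf = build_tpsf(ens, ens.medium.mua_cm())
        with pytest.raises(EmptyGateError):
            allocate_gate(
                ens, ens.tof_ps, tpsf, TimeGate(5000.0, 100.0),
                ens.medium.mua_cm(),
            )

    def test_delta_irf_membership_matches_brute_force(self):
        rng = np.random.default_rng(11)
        ens = _toy_ensemble(list(rng.gamma(4.0, 150.0, size=500)))
        mua = ens.medium.mua_cm()
        tpsf = build_tpsf(ens, mua, bin_ps=10.0)
        gate = TimeGate(150.0, 400.0)
        g = allocate_gate(ens, ens.tof_ps, tpsf, gate, mua)
        lo = tpsf.peak_time_ps + gate.start_ps
        brute = np.flatnonzero(
            (ens.tof_ps >= lo) & (ens.tof_ps < lo + gate.width_ps)
        )
        np.testing.assert_array_equal(g.indices, brute)

    def test_min_members_threshold(self):
        ens = _toy_ensemble(list(np.linspace(50, 900, 40)))
        tpsf = build_tpsf(ens, ens.medium.mua_cm())
        with pytest.raises(EmptyGateError):
            allocate_gate(
                ens, ens.tof_ps, tpsf, TimeGate(-5000.0, 10000.0),
                ens.medium.mua_cm(), min_members=1000,
            )


class TestGateCountRate:
    def test_full_support_gets_total_rate(self):
        ens = _toy_ensemble(list(np.linspace(50, 900, 60)))
        tpsf = build_tpsf(ens, ens.medium.mua_cm())
        full = TimeGate(-5000.0, 20000.0)
        for total in (600_000.0, 4_000_000.0):
            assert gate_count_rate(tpsf, full, total) == pytest.approx(total)

    def test_half_mass_gate_gets_half_rate(self):
        # two equal-weight atoms; a gate around one holds half the mass
        ens = _toy_ensemble([200.0, 800.0])
        tpsf = build_tpsf(ens, np.zeros(2))
        # window [100, 400) in absolute time captures only the 200-ps atom
        gate = TimeGate(100.0 - tpsf.peak_time_ps, 300.0)
        rate = gate_count_rate(tpsf, gate, 1000.0)
        assert rate == pytest.approx(500.0)

    def test_partition_additivity(self):
        rng = np.random.default_rng(13)
        ens = _toy_ensemble(list(rng.gamma(4.0, 150.0, size=400)))
        mua = ens.medium.mua_cm()
        tpsf = build_tpsf(ens, mua)
        total = 600_000.0
        edges = np.linspace(-2000.0, 8000.0, 11) - tpsf.peak_time_ps
        rates = [
            gate_count_rate(tpsf, TimeGate(lo, hi - lo), total)
            for lo, hi in zip(edges[:-1], edges[1:])
        ]
        assert sum(rates) == pytest.approx(total, rel=1e-12)


def test_tailed_irf_leaks_early_photons_into_late_gates(two_layer_base):
    """A diffusion-tailed IRF sends early tissue photons into late gates."""
    ens = two_layer_base
    mua = ens.medium.mua_cm()
    gate = TimeGate(600.0, 300.0)
    leak = {}
    for name, irf in [("delta", DeltaIRF()),
                      ("exgauss", ExGaussianIRF(300.0, 800.0, 0.3))]:
        app = apparent_tofs(ens, irf, 5)
        tpsf = build_tpsf(ens, mua, apparent_ps=app)
        g = allocate_gate(ens, app, tpsf, gate, mua)
        lo, _ = gate.window(tpsf.peak_time_ps)
        leak[name] = g.P_ToF.probs[g.P_ToF.values < lo].sum()
    assert leak["delta"] == pytest.approx(0.0, abs=1e-12)
    assert leak["exgauss"] > leak["delta"]
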