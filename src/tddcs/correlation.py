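"""Field/intensity autocorrelations, coherence factor and measurement noise.

The field autocorrelation of a gated photon set follows from the
recorded momentum transfers: for photon n with per-layer momentum
transfer Y_{n,i}, per-layer path L_{n,i} and layer diffusion
coefficients D_i (the blood flow indices),

    G1(tau) = sum_n w_n exp(-2 k0^2 tau sum_i Y_{n,i} D_i),
    w_n     = exp(-sum_i mua_i L_{n,i}),

using <dr^2(tau)> = 6 D tau for Brownian scatterer motion, so that
(1/3) k0^2 Y 6 D tau = 2 k0^2 Y D tau.  g1 = G1/G1(0); the Siegert
relation g2 = 1 + beta |g1|^2 maps to the intensity autocorrelation.

The coherence factor beta of a gate accounts for the finite coherence
length Lc of a pulsed laser: paths differing by more than Lc no longer
interfere, so a gate with a broad path-length distribution P(L) loses
contrast:

    beta = sum_i sum_j P(L_i) P(L_j) exp(-2 ((L_i - L_j)/Lc)^2).

Measurement noise follows the photon-correlation noise model (Koppel
form): the per-lag standard deviation of g2 estimated over averaging
time t with correlator bin width T, count rate I (<n> = I T), g1 decay
rate Gamma and coherence factor beta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._kernel import C0_MM_PS
from .gating import DiscreteDistribution, GatedEnsemble

__all__ = [
    "WavelengthContext",
    "CoherenceSpec",
    "CorrelationCurve",
    "NoiseModelParams",
    "g1_from_histories",
    "decay_rates",
    "beta_from_pathlengths",
    "coherence_length_gaussian",
    "siegert",
    "g2_noise_sigma",
    "noisy_g2_series",
    "fit_gamma",
    "multitau_grid",
]


@dataclass(frozen=True)
class WavelengthContext:
    """Wavelength-dependent constants of the optical field in tissue."""

    wavelength_nm: float
    n_medium: float = 1.4

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0 or self.n_medium <= 0:
            raise ValueError("wavelength and refractive index must be > 0")

    @property
    def k0_per_mm(self) -> float:
        """Wavenumber in the medium, 2 pi n / lambda (1/mm)."""
        return 2.0 * math.pi * self.n_medium / (self.wavelength_nm * 1e-6)

    @property
    def c_tissue_mm_ps(self) -> float:
        return C0_MM_PS / self.n_medium


@dataclass(frozen=True)
class CoherenceSpec:
    """Laser coherence length in cm (math.inf = full-coherence limit)."""

    Lc_cm: float

    def __post_init__(self) -> None:
        if not self.Lc_cm > 0:
            raise ValueError("Lc must be > 0 (inf allowed)")


@dataclass
class CorrelationCurve:
    """g1/g2 on a delay grid with the per-lag noise model sigma."""

    tau_s: np.ndarray
    g1: np.ndarray
    g2: np.ndarray
    beta: float
    sigma: np.ndarray | None = None

    def to_frame(self):
        import pandas as pd

        d = {"tau_s": self.tau_s, "g1": self.g1, "g2": self.g2}
        if self.sigma is not None:
            d["sigma"] = self.sigma
        return pd.DataFrame(d)

    def save(self, csv_path, sidecar: dict | None = None) -> None:
        """Write the curve as CSV plus a JSON sidecar (<csv>.json).

        The sidecar records beta and any measurement context passed in
        (coherence length, gate, count rate, Gamma, ...).
        """
        import json
        import pathlib

        self.to_frame().to_csv(csv_path, index=False)
        meta = {"beta": float(self.beta)}
        if sidecar:
            meta.update(sidecar)
        pathlib.Path(str(csv_path) + ".json").write_text(
            json.dumps(meta, indent=2, sort_keys=True)
        )

    @classmethod
    def load(cls, csv_path) -> "CorrelationCurve":
        import json
        import pathlib

        import pandas as pd

        df = pd.read_csv(csv_path)
        meta = json.loads(pathlib.Path(str(csv_path) + ".json").read_text())
        return cls(
            tau_s=df["tau_s"].to_numpy(),
            g1=df["g1"].to_numpy(),
            g2=df["g2"].to_numpy(),
            beta=float(meta["beta"]),
            sigma=df["sigma"].to_numpy() if "sigma" in df else None,
        )


@dataclass(frozen=True)
class NoiseModelParams:
    """Inputs of the correlation noise model."""

    t_s: float          # averaging (integration) time
    T_s: float          # correlator bin width
    gamma_hz: float     # decay rate of g1
    n_avg: float        # mean photons per bin, <n> = I*T
    beta: float

    def __post_init__(self) -> None:
        if min(self.t_s, self.T_s, self.gamma_hz, self.n_avg) <= 0:
            raise ValueError("t, T, Gamma and <n> must all be > 0")
        if not 0 < self.beta <= 1:
            raise ValueError("beta must lie in (0, 1]")


def decay_rates(
    gated: GatedEnsemble, D_mm2s: np.ndarray, ctx: WavelengthContext
) -> np.ndarray:
    """Per-photon g1 decay rate 2 k0^2 sum_i Y_i D_i (1/s)."""
    D = np.asarray(D_mm2s, dtype=float)
    if np.any(D < 0):
        raise ValueError("negative diffusion coefficient")
    return 2.0 * ctx.k0_per_mm**2 * (gated.Y @ D)


def g1_from_histories(
    gated: GatedEnsemble,
    D_mm2s: np.ndarray,
    mua_cm: np.ndarray | None,
    ctx: WavelengthContext,
    tau_s: np.ndarray,
) -> np.ndarray:
    """Normalized field autocorrelation g1(tau) of a gated photon set."""
    if len(gated) == 0:
        raise ValueError("empty gate")
    rates = decay_rates(gated, D_mm2s, ctx)
    if mua_cm is None:
        w = gated.weights
    else:
        mua_mm = np.asarray(mua_cm, dtype=float) / 10.0
        w = np.exp(-gated.L_mm @ mua_mm)
    tau = np.asarray(tau_s, dtype=float)
    G1 = np.exp(-np.outer(tau, rates)) @ w
    return G1 / w.sum()


def beta_from_pathlengths(P_L: DiscreteDistribution, Lc_cm: float) -> float:
    """Coherence factor of a gate from its path-length distribution.

    ``P_L.values`` are path lengths in mm; ``Lc_cm`` the coherence
    length in cm (inf = fully coherent source).
    """
    if not Lc_cm > 0:
        raise ValueError("Lc must be > 0")
    p = np.asarray(P_L.probs, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("P_L is not normalized")
    L = np.asarray(P_L.values, dtype=float)
    if math.isinf(Lc_cm):
        return float(p.sum() ** 2)
    Lc_mm = Lc_cm * 10.0
    diff = (L[:, None] - L[None, :]) / Lc_mm
    return float(p @ np.exp(-2.0 * diff**2) @ p)


def coherence_length_gaussian(
    pulse_fwhm_ps: float, n_medium: float = 1.4
) -> float:
    """Coherence length (cm) of a transform-limited Gaussian pulse.

    Bandwidth dnu = 0.441/FWHM, and Lc = (c0/n)/(pi dnu) with the speed
    of light in tissue.
    """
    if pulse_fwhm_ps <= 0:
        raise ValueError("pulse_fwhm_ps must be > 0")
    dnu_hz = 0.441 / (pulse_fwhm_ps * 1e-12)
    c_tissue_cm_s = 2.99792458e10 / n_medium
    return c_tissue_cm_s / (math.pi * dnu_hz)


def siegert(g1: np.ndarray, beta: float) -> np.ndarray:
    """Intensity autocorrelation g2 = 1 + beta |g1|^2."""
    if not 0 < beta <= 1:
        raise ValueError("beta must lie in (0, 1]")
    g1 = np.asarray(g1, dtype=float)
    return 1.0 + beta * g1**2


def g2_noise_sigma(params: NoiseModelParams, tau_s: np.ndarray) -> np.ndarray:
    """Per-lag standard deviation of the g2 estimate.

    Koppel-form photon-correlation noise: with G = Gamma, T the bin
    width, tau = m T,

        sigma(tau) = sqrt(T/t) * [ beta^2 ((1+e^{-2GT})(1+e^{-2Gtau})
                     + 2m(1-e^{-2GT}) e^{-2Gtau}) / (1-e^{-2GT})
                     + 2 <n>^-1 beta (1+e^{-2Gtau})
                     + <n>^-2 (1 + beta e^{-Gtau}) ]^{1/2}.
    """
    tau = np.asarray(tau_s, dtype=float)
    G = params.gamma_hz
    T = params.T_s
    beta = params.beta
    n = params.n_avg
    m = np.maximum(np.rint(tau / T), 1.0)
    # guard the Gamma*T exponentials against over/underflow
    gt = min(G * T, 350.0)
    e2gt = math.exp(-2.0 * gt)
    one_minus = -math.expm1(-2.0 * gt)  # 1 - e^{-2GT}, accurate for small GT
    e2gtau = np.exp(-np.minimum(2.0 * G * tau, 700.0))
    egtau = np.exp(-np.minimum(G * tau, 700.0))
    speckle = beta**2 * (
        (1.0 + e2gt) * (1.0 + e2gtau) + 2.0 * m * one_minus * e2gtau
    ) / one_minus
    shot_cross = 2.0 / n * beta * (1.0 + e2gtau)
    shot = 1.0 / n**2 * (1.0 + beta * egtau)
    return np.sqrt(T / params.t_s) * np.sqrt(speckle + shot_cross + shot)


def noisy_g2_series(
    g2: np.ndarray,
    sigma: np.ndarray,
    n_realizations: int = 120,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Stack of noisy g2 realizations, one row each.

    Each realization adds independent zero-mean Gaussian noise with the
    per-lag standard deviation ``sigma``; the default of 120 one-second
    curves emulates a two-minute measurement.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    g2 = np.asarray(g2, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if g2.shape != sigma.shape:
        raise ValueError("g2 and sigma grids must match")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    return g2[None, :] + rng.standard_normal((n_realizations, len(g2))) * sigma


def fit_gamma(tau_s: np.ndarray, g1: np.ndarray, floor: float = 0.3) -> float:
    """Effective exponential decay rate of g1 (1/s).

    Straight-line fit of ln g1 against tau over the lags where
    g1 > ``floor`` (the noise model needs a single rate even though the
    multi-path g1 is not purely exponential).
    """
    tau = np.asarray(tau_s, dtype=float)
    g1 = np.asarray(g1, dtype=float)
    mask = (g1 > floor) & (tau > 0)
    if mask.sum() < 2:
        mask = tau > 0
        g1 = np.maximum(g1, 1e-12)
    slope = np.polyfit(tau[mask], np.log(g1[mask]), 1)[0]
    return float(max(-slope, 1e-12))


def multitau_grid(
    T_s: float = 1e-6, max_s: float = 1e-3, per_octave: int = 8
) -> np.ndarray:
    """Pseudo-logarithmic delay grid of integer multiples of ``T_s``.

    Dense linear spacing for the first 16 bins, then ``per_octave``
    lags per octave, multi-tau style.
    """
    m = set(range(1, 17))
    top = max_s / T_s
    k = 16.0
    while k < top:
        k *= 2.0
        step = k / per_octave / 2.0
        m.update(
            int(round(v)) for v in np.arange(k / 2.0, min(k, top) + 0.5 * step, step)
        )
    ms = np.array(sorted(v for v in m if 1 <= v <= top), dtype=float)
    return ms * T_s
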