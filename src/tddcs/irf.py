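"""Instrument response function (IRF) models and arrival-time jitter.

An IRF is the system's temporal response to an instantaneous input —
the laser pulse shape convolved with detector and timing-electronics
jitter.  Each model exposes ``pdf``/``cdf``/``ppf`` over time in ps and
is shifted so its mode sits at 0 ps, making the apparent time of flight
"tissue ToF + spread" without a systematic offset; gate placement is
referenced to the overall-TPSF peak anyway, so this is bookkeeping only.

Available shapes:

* ``DeltaIRF`` — ideal instantaneous response.
* ``GaussianIRF(fwhm_ps)`` — shaped quasi-Gaussian pulses (200-450 ps
  FWHM is the regime of interest).
* ``ExGaussianIRF(fwhm_ps, tail_tau_ps, tail_fraction)`` — a Gaussian
  core mixed with an exponentially-modified-Gaussian diffusion tail,
  standing in for red-enhanced detectors whose impulse response decays
  slowly.
* ``HistogramIRF(t_ps, counts)`` — a measured two-column histogram.

Jitter is drawn by inverse-transform sampling: u ~ U(0,1), t = cdf^-1(u).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "IRFModel",
    "DeltaIRF",
    "GaussianIRF",
    "ExGaussianIRF",
    "HistogramIRF",
    "sample_jitter",
    "parse_irf",
    "load_histogram_irf",
    "FWHM_TO_SIGMA",
]

#: sigma = FWHM / (2 sqrt(2 ln 2))
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


class IRFModel:
    """Base class; subclasses implement pdf/cdf/ppf in ps."""

    is_delta = False

    def pdf(self, t_ps):
        raise NotImplementedError

    def cdf(self, t_ps):
        raise NotImplementedError

    def ppf(self, u):
        raise NotImplementedError

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.random(n)
        return self.ppf(u)


class DeltaIRF(IRFModel):
    """Ideal delta-function response: no jitter."""

    is_delta = True

    def pdf(self, t_ps):
        raise ValueError("delta IRF has no density")

    def cdf(self, t_ps):
        return (np.asarray(t_ps, dtype=float) >= 0).astype(float)

    def ppf(self, u):
        return np.zeros_like(np.asarray(u, dtype=float))


@dataclass(frozen=True)
class GaussianIRF(IRFModel):
    fwhm_ps: float

    def __post_init__(self):
        if self.fwhm_ps <= 0:
            raise ValueError("fwhm_ps must be > 0")

    @property
    def sigma_ps(self) -> float:
        return self.fwhm_ps * FWHM_TO_SIGMA

    def pdf(self, t_ps):
        return stats.norm.pdf(t_ps, scale=self.sigma_ps)

    def cdf(self, t_ps):
        return stats.norm.cdf(t_ps, scale=self.sigma_ps)

    def ppf(self, u):
        return stats.norm.ppf(u, scale=self.sigma_ps)


class _GridPPF:
    """Numeric inverse cdf via a dense monotone (t, cdf) table."""

    def _build_grid(self, t_lo: float, t_hi: float, n: int = 4097) -> None:
        t = np.linspace(t_lo, t_hi, n)
        c = self.cdf(t)
        # strictly increasing cdf needed for interpolation
        keep = np.concatenate(([True], np.diff(c) > 1e-15))
        self._grid_t = t[keep]
        self._grid_c = c[keep]
        if len(self._grid_t) < 2:
            raise ValueError("degenerate IRF: cdf is not invertible")

    def ppf(self, u):
        u = np.asarray(u, dtype=float)
        return np.interp(u, self._grid_c, self._grid_t)


class ExGaussianIRF(_GridPPF, IRFModel):
    """Gaussian core plus exponential diffusion tail.

    pdf = (1 - f) N(0, sigma) + f EMG(0, sigma, tau), shifted so the
    mixture mode is at 0 ps.  ``tail_fraction`` f is the photon fraction
    in the tail component and ``tail_tau_ps`` its time constant.
    """

    def __init__(self, fwhm_ps: float, tail_tau_ps: float, tail_fraction: float):
        if fwhm_ps <= 0 or tail_tau_ps <= 0:
            raise ValueError("fwhm_ps and tail_tau_ps must be > 0")
        if not 0 <= tail_fraction < 1:
            raise ValueError("tail_fraction must lie in [0, 1)")
        self.fwhm_ps = fwhm_ps
        self.tail_tau_ps = tail_tau_ps
        self.tail_fraction = tail_fraction
        self.sigma_ps = fwhm_ps * FWHM_TO_SIGMA
        self._emg = stats.exponnorm(K=tail_tau_ps / self.sigma_ps,
                                    loc=0.0, scale=self.sigma_ps)
        # locate the mixture mode numerically, then shift it to 0
        self._shift = 0.0
        span = 6 * self.sigma_ps + 8 * tail_tau_ps
        t = np.linspace(-6 * self.sigma_ps, span, 8001)
        self._shift = t[np.argmax(self._pdf_raw(t))]
        self._build_grid(-8 * self.sigma_ps - self._shift,
                         8 * self.sigma_ps + 12 * tail_tau_ps - self._shift)

    def _pdf_raw(self, t):
        f = self.tail_fraction
        return (1 - f) * stats.norm.pdf(t, scale=self.sigma_ps) + f * self._emg.pdf(t)

    def pdf(self, t_ps):
        return self._pdf_raw(np.asarray(t_ps, dtype=float) + self._shift)

    def cdf(self, t_ps):
        t = np.asarray(t_ps, dtype=float) + self._shift
        f = self.tail_fraction
        return (1 - f) * stats.norm.cdf(t, scale=self.sigma_ps) + f * self._emg.cdf(t)


class HistogramIRF(_GridPPF, IRFModel):
    """IRF from a measured (time_ps, counts) histogram.

    Counts are normalized to a piecewise-linear density; the time axis
    is shifted so the density mode sits at 0 ps.
    """

    def __init__(self, t_ps: np.ndarray, counts: np.ndarray):
        t = np.asarray(t_ps, dtype=float)
        c = np.asarray(counts, dtype=float)
        if t.ndim != 1 or t.shape != c.shape or len(t) < 2:
            raise ValueError("need matching 1-D time and count arrays (>= 2 points)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time column must be strictly increasing")
        if np.any(c < 0) or not np.any(c > 0):
            raise ValueError("counts must be >= 0 with positive mass")
        area = np.trapezoid(c, t)
        if area <= 0:
            raise ValueError("degenerate histogram: zero area")
        dens = c / area
        mode = t[np.argmax(dens)]
        self._t = t - mode
        self._dens = dens
        cum = np.concatenate(
            ([0.0], np.cumsum(np.diff(self._t) * 0.5 * (dens[1:] + dens[:-1])))
        )
        self._cum = cum / cum[-1]
        self._grid_t = self._t[np.concatenate(([True], np.diff(self._cum) > 1e-15))]
        self._grid_c = self._cum[np.concatenate(([True], np.diff(self._cum) > 1e-15))]
        if len(self._grid_t) < 2:
            raise ValueError("degenerate histogram: cdf is not invertible")

    def pdf(self, t_ps):
        return np.interp(np.asarray(t_ps, dtype=float), self._t, self._dens,
                         left=0.0, right=0.0)

    def cdf(self, t_ps):
        return np.interp(np.asarray(t_ps, dtype=float), self._t, self._cum,
                         left=0.0, right=1.0)


def sample_jitter(irf: IRFModel, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw ``n`` jitter times (ps) from the IRF by inverse-transform sampling."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    return irf.sample(n, rng)


def parse_irf(spec: str) -> IRFModel:
    """Build an IRF from a compact string.

    ``"delta"``, ``"gaussian:300"`` (FWHM ps) or
    ``"exgauss:300,800,0.3"`` (FWHM ps, tail tau ps, tail fraction);
    anything else is treated as a path to a two-column histogram file.
    """
    s = spec.strip()
    if s == "delta":
        return DeltaIRF()
    if s.startswith("gaussian:"):
        return GaussianIRF(float(s.split(":", 1)[1]))
    if s.startswith("exgauss:"):
        parts = [float(x) for x in s.split(":", 1)[1].split(",")]
        if len(parts) != 3:
            raise ValueError("exgauss spec needs fwhm,tail_tau,tail_fraction")
        return ExGaussianIRF(*parts)
    return load_histogram_irf(s)


def load_histogram_irf(path) -> HistogramIRF:
    """Read a two-column ASCII (time_ps, counts) histogram file."""
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("histogram IRF file must have two columns")
    return HistogramIRF(data[:, 0], data[:, 1])
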