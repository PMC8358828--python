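"""TPSF construction, time-gate definition and photon-to-gate allocation.

The temporal point spread function (TPSF) is the histogram of detected
photon arrival times after a pulse, weighted by the analytic absorption
factor exp(-sum_j mua_j L_j) of each packet (fluence weighting: short
paths are attenuated less and contribute disproportionately).  Jittering
tissue times of flight with IRF draws before binning yields the
overall-TPSF, i.e. the convolution of the tissue response with the IRF.

A time gate is an interval of *apparent* time of flight specified by a
start (relative to the TPSF peak, possibly negative) and a width; the
membership interval is half-open, [peak + start, peak + start + width).
Gated photons keep their *tissue* path lengths and momentum-transfer
histories for the correlation model; the gate's path-length distribution
P(L) uses the total tissue path L = tissue ToF * c0/n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from ._kernel import C0_MM_PS
from .irf import IRFModel, sample_jitter
from .transport import HistoryEnsemble

__all__ = [
    "TPSF",
    "TimeGate",
    "DiscreteDistribution",
    "GatedEnsemble",
    "EmptyGateError",
    "apparent_tofs",
    "build_tpsf",
    "allocate_gate",
    "gate_count_rate",
]


class EmptyGateError(RuntimeError):
    """Raised when a gate holds fewer members than the configured minimum."""


class DiscreteDistribution(NamedTuple):
    """Normalized discrete distribution over scalar values."""

    values: np.ndarray
    probs: np.ndarray

    def mean(self) -> float:
        return float(np.sum(self.values * self.probs))

    def std(self) -> float:
        m = self.mean()
        return float(np.sqrt(np.sum(self.probs * (self.values - m) ** 2)))


@dataclass
class TPSF:
    """Fluence-weighted time-of-flight histogram with identified peak."""

    bin_edges_ps: np.ndarray
    fluence: np.ndarray
    peak_time_ps: float
    normalized: bool = False

    def __post_init__(self) -> None:
        self.bin_edges_ps = np.asarray(self.bin_edges_ps, dtype=float)
        self.fluence = np.asarray(self.fluence, dtype=float)
        if len(self.bin_edges_ps) != len(self.fluence) + 1:
            raise ValueError("need len(bin_edges) == len(fluence) + 1")
        if np.any(self.fluence < 0):
            raise ValueError("fluence must be >= 0")

    @property
    def bin_centers_ps(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_ps[:-1] + self.bin_edges_ps[1:])

    @property
    def bin_width_ps(self) -> float:
        return float(self.bin_edges_ps[1] - self.bin_edges_ps[0])

    def mass(self) -> float:
        """Total fluence mass (sum of per-bin fluence times bin width)."""
        return float(np.sum(self.fluence) * self.bin_width_ps)

    def mass_in(self, t_lo_ps: float, t_hi_ps: float) -> float:
        """Fluence mass inside [t_lo, t_hi), split bins fractionally."""
        edges = self.bin_edges_ps
        lo = np.clip(edges[:-1], t_lo_ps, t_hi_ps)
        hi = np.clip(edges[1:], t_lo_ps, t_hi_ps)
        return float(np.sum(self.fluence * np.maximum(hi - lo, 0.0)))

    def normalize(self) -> "TPSF":
        m = self.mass()
        if m <= 0:
            raise ValueError("cannot normalize an empty TPSF")
        return TPSF(self.bin_edges_ps, self.fluence / m, self.peak_time_ps, True)


@dataclass(frozen=True)
class TimeGate:
    """Gate start (ps, relative to the TPSF peak; may be negative) and width."""

    start_ps: float
    width_ps: float

    def __post_init__(self) -> None:
        if self.width_ps <= 0:
            raise ValueError("gate width must be > 0")

    def window(self, peak_time_ps: float) -> tuple[float, float]:
        lo = peak_time_ps + self.start_ps
        return lo, lo + self.width_ps


@dataclass
class GatedEnsemble:
    """Photons allocated to one time gate, with gate-level distributions."""

    ensemble: HistoryEnsemble
    gate: TimeGate
    indices: np.ndarray
    apparent_tof_ps: np.ndarray
    weights: np.ndarray
    P_L: DiscreteDistribution      # tissue path length, mm
    P_ToF: DiscreteDistribution    # tissue time of flight, ps
    count_rate_cps: float | None = None

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def L_mm(self) -> np.ndarray:
        return self.ensemble.L_mm[self.indices]

    @property
    def Y(self) -> np.ndarray:
        return self.ensemble.Y[self.indices]

    @property
    def tof_tissue_ps(self) -> np.ndarray:
        return self.ensemble.tof_ps[self.indices]


def apparent_tofs(
    ensemble: HistoryEnsemble, irf: IRFModel, seed: int | np.random.Generator
) -> np.ndarray:
    """Apparent ToF per photon: tissue ToF plus one independent IRF draw."""
    if irf.is_delta:
        return ensemble.tof_ps.copy()
    return ensemble.tof_ps + sample_jitter(irf, len(ensemble), seed)


def _find_peak(fluence: np.ndarray, centers: np.ndarray, smooth: int = 3) -> float:
    """Argmax of the histogram after a short moving average (noise guard)."""
    if smooth > 1 and len(fluence) >= smooth:
        kernel = np.ones(smooth) / smooth
        sm = np.convolve(fluence, kernel, mode="same")
    else:
        sm = fluence
    return float(centers[int(np.argmax(sm))])


def build_tpsf(
    ensemble: HistoryEnsemble,
    mua_cm: np.ndarray | None = None,
    irf: IRFModel | None = None,
    bin_ps: float = 10.0,
    seed: int | np.random.Generator = 0,
    apparent_ps: np.ndarray | None = None,
    normalized: bool = False,
    peak_smooth_bins: int = 3,
) -> TPSF:
    """Bin (apparent) ToFs into an absorption-weighted TPSF.

    Either pass ``irf`` (+ ``seed``) to jitter internally, or supply
    precomputed ``apparent_ps`` so the same draws serve TPSF building
    and gate allocation.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    if bin_ps <= 0:
        raise ValueError("bin_ps must be > 0")
    if apparent_ps is None:
        if irf is None:
            apparent_ps = ensemble.tof_ps
        else:
            apparent_ps = apparent_tofs(ensemble, irf, seed)
    w = ensemble.weights(mua_cm)
    lo = np.floor(apparent_ps.min() / bin_ps) * bin_ps
    hi = np.ceil(apparent_ps.max() / bin_ps) * bin_ps
    if hi <= lo:
        hi = lo + bin_ps
    edges = np.arange(lo, hi + 0.5 * bin_ps, bin_ps)
    counts, _ = np.histogram(apparent_ps, bins=edges, weights=w)
    fluence = counts / bin_ps  # per-unit-time fluence convention
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = _find_peak(fluence, centers, peak_smooth_bins)
    tpsf = TPSF(edges, fluence, peak)
    return tpsf.normalize() if normalized else tpsf


def _weighted_hist_distribution(
    x: np.ndarray, w: np.ndarray, bin_width: float
) -> DiscreteDistribution:
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    h, _ = np.histogram(x, bins=edges, weights=w)
    keep = h > 0
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = h[keep] / h[keep].sum()
    return DiscreteDistribution(centers[keep], p)


def allocate_gate(
    ensemble: HistoryEnsemble,
    apparent_ps: np.ndarray,
    tpsf: TPSF,
    gate: TimeGate,
    mua_cm: np.ndarray | None = None,
    min_members: int = 1,
    tof_bin_ps: float = 10.0,
) -> GatedEnsemble:
    """Select the photons whose apparent ToF falls inside the gate window.

    The gate's fluence-weighted tissue-ToF distribution P(ToF) and
    path-length distribution P(L) (L = tissue ToF * c0/n) are binned at
    ``tof_bin_ps`` resolution.  Raises :class:`EmptyGateError` when the
    gate holds fewer than ``min_members`` photons.
    """
    lo, hi = gate.window(tpsf.peak_time_ps)
    mask = (apparent_ps >= lo) & (apparent_ps < hi)
    idx = np.flatnonzero(mask)
    if len(idx) < max(min_members, 1):
        raise EmptyGateError(
            f"gate start={gate.start_ps} width={gate.width_ps} holds "
            f"{len(idx)} photons (< {max(min_members, 1)})"
        )
    w = ensemble.weights(mua_cm)[idx]
    tof_tissue = ensemble.tof_ps[idx]
    n_med = ensemble.medium.layers[0].n
    p_tof = _weighted_hist_distribution(tof_tissue, w, tof_bin_ps)
    p_l = DiscreteDistribution(p_tof.values * C0_MM_PS / n_med, p_tof.probs)
    return GatedEnsemble(
        ensemble=ensemble,
        gate=gate,
        indices=idx,
        apparent_tof_ps=apparent_ps[idx],
        weights=w,
        P_L=p_l,
        P_ToF=p_tof,
    )


def gate_count_rate(tpsf: TPSF, gate: TimeGate, total_rate_cps: float) -> float:
    """Detected count rate assigned to the gate.

    The total area under the overall-TPSF corresponds to the full
    detected rate; the gate receives the fraction of fluence mass inside
    its window.
    """
    if total_rate_cps <= 0:
        raise ValueError("total_rate_cps must be > 0")
    total = tpsf.mass()
    if total <= 0:
        raise ValueError("empty TPSF")
    lo, hi = gate.window(tpsf.peak_time_ps)
    return total_rate_cps * tpsf.mass_in(lo, hi) / total
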