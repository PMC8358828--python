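"""Monte Carlo photon transport with momentum-transfer recording.

For every detected photon packet the per-layer path length L_i (mm) and
the per-layer dimensionless momentum transfer Y_i = sum(1 - cos theta)
over its scattering events are recorded.  These two vectors are all the
field autocorrelation model needs: dynamic dephasing is driven by Y and
the layer diffusion coefficients, absorption enters analytically as
exp(-sum mua_i L_i), so one transport run serves every absorption and
flow scenario.

The source is a pencil beam at the origin, normally incident; the
detector sits on the surface at the source-detector separation, either
as a circular disk (the physical probe) or as an annulus of the same
radial extent ("ring"), which exploits the lateral symmetry of the slab
to collect ~2*pi*sd/diameter more photons with identical path-length
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel
from ._kernel import C0_MM_PS
from .media import LayeredMedium

__all__ = [
    "ProbeSpec",
    "PhotonHistory",
    "HistoryEnsemble",
    "TransportError",
    "momentum_increment",
    "simulate_histories",
    "sample_hg_mean_transfer",
]


class TransportError(RuntimeError):
    """Raised when transport cannot produce a usable ensemble."""


@dataclass(frozen=True)
class ProbeSpec:
    """Source-detector arrangement on the slab surface.

    ``geometry`` is "disk" (circular detector at distance
    ``sd_separation_mm`` from the source) or "ring" (annulus
    ``|r - sd| <= radius``).
    """

    sd_separation_mm: float = 10.0
    detector_radius_mm: float = 0.5
    geometry: str = "disk"

    def __post_init__(self) -> None:
        if self.sd_separation_mm <= 0:
            raise ValueError("sd_separation_mm must be > 0")
        if self.detector_radius_mm <= 0:
            raise ValueError("detector_radius_mm must be > 0")
        if self.geometry not in ("disk", "ring"):
            raise ValueError("geometry must be 'disk' or 'ring'")


@dataclass(frozen=True)
class PhotonHistory:
    """Per-layer path length and momentum transfer of one detected packet."""

    L_mm: np.ndarray
    Y: np.ndarray
    tof_ps: float
    detector_id: int = 0

    def __post_init__(self) -> None:
        L = np.asarray(self.L_mm, dtype=float)
        Y = np.asarray(self.Y, dtype=float)
        if L.shape != Y.shape:
            raise ValueError("L and Y must have the same shape")
        if np.any(L < 0) or np.any(Y < 0):
            raise ValueError("path lengths and momentum transfers must be >= 0")
        if np.any((L == 0) & (Y > 0)):
            raise ValueError("momentum transfer in a layer with zero path length")
        object.__setattr__(self, "L_mm", L)
        object.__setattr__(self, "Y", Y)


@dataclass
class HistoryEnsemble:
    """Detected photon histories from one transport run.

    Arrays are row-per-photon: ``L_mm``/``Y`` are (n_detected, n_layers),
    ``tof_ps`` and ``detector_id`` are 1-D.
    """

    L_mm: np.ndarray
    Y: np.ndarray
    tof_ps: np.ndarray
    detector_id: np.ndarray
    n_launched: int
    medium: LayeredMedium
    probe: ProbeSpec
    seed: int = 0

    def __post_init__(self) -> None:
        self.L_mm = np.ascontiguousarray(self.L_mm, dtype=float)
        self.Y = np.ascontiguousarray(self.Y, dtype=float)
        self.tof_ps = np.asarray(self.tof_ps, dtype=float)
        self.detector_id = np.asarray(self.detector_id, dtype=np.int32)
        n, k = self.L_mm.shape
        if self.Y.shape != (n, k) or self.tof_ps.shape != (n,):
            raise ValueError("inconsistent ensemble array shapes")
        if k != len(self.medium):
            raise ValueError("layer-count mismatch between arrays and medium")
        if self.n_launched < n:
            raise ValueError("n_launched must be >= number of detected photons")

    def __len__(self) -> int:
        return self.L_mm.shape[0]

    @property
    def n_layers(self) -> int:
        return self.L_mm.shape[1]

    def weights(self, mua_cm: np.ndarray | None = None) -> np.ndarray:
        """Absorption weights exp(-sum_i mua_i L_i) per photon."""
        if mua_cm is None:
            mua_cm = self.medium.mua_cm()
        mua_mm = np.asarray(mua_cm, dtype=float) / 10.0
        return np.exp(-self.L_mm @ mua_mm)

    def subset(self, idx: np.ndarray) -> "HistoryEnsemble":
        return HistoryEnsemble(
            L_mm=self.L_mm[idx],
            Y=self.Y[idx],
            tof_ps=self.tof_ps[idx],
            detector_id=self.detector_id[idx],
            n_launched=self.n_launched,
            medium=self.medium,
            probe=self.probe,
            seed=self.seed,
        )

    def histories(self) -> list[PhotonHistory]:
        return [
            PhotonHistory(self.L_mm[i], self.Y[i], float(self.tof_ps[i]),
                          int(self.detector_id[i]))
            for i in range(len(self))
        ]

    @classmethod
    def from_histories(
        cls,
        histories: list[PhotonHistory],
        medium: LayeredMedium,
        probe: ProbeSpec | None = None,
        n_launched: int | None = None,
        seed: int = 0,
    ) -> "HistoryEnsemble":
        if not histories:
            raise ValueError("empty history list")
        return cls(
            L_mm=np.stack([h.L_mm for h in histories]),
            Y=np.stack([h.Y for h in histories]),
            tof_ps=np.array([h.tof_ps for h in histories]),
            detector_id=np.array([h.detector_id for h in histories]),
            n_launched=n_launched if n_launched is not None else len(histories),
            medium=medium,
            probe=probe if probe is not None else ProbeSpec(),
            seed=seed,
        )


def momentum_increment(cos_theta: float) -> float:
    """Dimensionless momentum transfer q^2/(2 k0^2) = 1 - cos(theta)."""
    c = np.asarray(cos_theta, dtype=float)
    if np.any(c < -1) or np.any(c > 1):
        raise ValueError("cos_theta must lie in [-1, 1]")
    out = 1.0 - c
    return float(out) if np.isscalar(cos_theta) else out


def sample_hg_mean_transfer(g: float, n: int, seed: int = 0) -> float:
    """Monte Carlo estimate of E[1 - cos theta] for Henyey-Greenstein."""
    return float(_kernel.sample_hg_mean_transfer(g, n, seed))


def simulate_histories(
    medium: LayeredMedium,
    probe: ProbeSpec,
    n_photons: int,
    seed: int,
    max_tof_ps: float = 5000.0,
    chunk: int = 200_000,
) -> HistoryEnsemble:
    """Trace ``n_photons`` packets through the slab; return detected histories.

    Packets are launched as a pencil beam at the origin.  Step lengths
    follow exp(mus) per layer with mus = musp/(1-g); deflections are
    Henyey-Greenstein; only the exterior surface reflects (internal
    refractive indices must match).  Packets exceeding ``max_tof_ps``
    are dropped.  Deterministic given ``seed``, independent of ``chunk``.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    mus_cm = np.array([layer.mus_cm for layer in medium.layers])
    if np.any(mus_cm <= 0):
        raise TransportError("non-positive scattering coefficient in a layer")
    n_arr = medium.n()
    if not np.allclose(n_arr, n_arr[0]):
        raise TransportError(
            "internal refractive indices must be equal across layers"
        )
    mus_mm = mus_cm / 10.0
    g_arr = medium.g()
    tops = medium.tops_mm
    geometry = (
        _kernel.GEOM_RING if probe.geometry == "ring" else _kernel.GEOM_DISK
    )

    L_parts, Y_parts, tof_parts = [], [], []
    L_buf = np.empty((chunk, len(medium)))
    Y_buf = np.empty((chunk, len(medium)))
    tof_buf = np.empty(chunk)
    done = 0
    while done < n_photons:
        m = min(chunk, n_photons - done)
        cnt = _kernel.run_chunk(
            np.uint64(seed),
            done,
            m,
            mus_mm,
            g_arr,
            n_arr,
            tops,
            medium.exterior_index,
            probe.sd_separation_mm,
            probe.detector_radius_mm,
            geometry,
            max_tof_ps,
            L_buf,
            Y_buf,
            tof_buf,
        )
        if cnt:
            L_parts.append(L_buf[:cnt].copy())
            Y_parts.append(Y_buf[:cnt].copy())
            tof_parts.append(tof_buf[:cnt].copy())
        done += m
    if not L_parts:
        raise TransportError(
            "no photons detected; increase the photon budget or check the probe"
        )
    L = np.concatenate(L_parts)
    return HistoryEnsemble(
        L_mm=L,
        Y=np.concatenate(Y_parts),
        tof_ps=np.concatenate(tof_parts),
        detector_id=np.zeros(L.shape[0], dtype=np.int32),
        n_launched=n_photons,
        medium=medium,
        probe=probe,
        seed=seed,
    )
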