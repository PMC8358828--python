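"""Inverse problem: optical properties from the TPSF, then BFi and beta
from gated intensity autocorrelations.

The fitting forward model is deliberately homogeneous: photon histories
are simulated in a semi-infinite medium whose (mua, musp') come from
fitting the measured/simulated TPSF to the time-resolved diffusion
reflectance.  Gated g2 data are then fitted to

    g2(tau) = 1 + beta * g1(tau; BFi)^2,

where g1 pools all momentum transfer of the homogeneous histories in
the matching gate.  Levenberg-Marquardt least squares in log-parameter
space is started from a small grid of initial guesses (two BFi x two
beta) and the start with the least residual norm wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .correlation import WavelengthContext, decay_rates
from .diffusion import semi_infinite_reflectance, semi_infinite_reflectance_ring
from .gating import GatedEnsemble, TPSF, TimeGate

__all__ = [
    "FitResult",
    "HomogeneousModel",
    "FitError",
    "fit_tpsf_optical_props",
    "fit_g2",
    "fit_series",
    "select_fit_window",
    "DEFAULT_INIT_BFI",
    "DEFAULT_INIT_BETA",
]

DEFAULT_INIT_BFI = (1e-6, 1e-5)
DEFAULT_INIT_BETA = (0.3, 0.6)

_BFI_LO, _BFI_HI = 1e-9, 1e-3  # plausibility bounds, mm^2/s


class FitError(RuntimeError):
    """Raised when a fit cannot converge from any start."""


@dataclass
class FitResult:
    """Recovered flow index and coherence factor for one g2 curve."""

    BFi_mm2s: float
    beta: float
    residual_norm: float
    init_used: tuple[float, float]
    converged: bool

    @classmethod
    def failed(cls) -> "FitResult":
        return cls(float("nan"), float("nan"), float("inf"), (float("nan"),) * 2,
                   False)


def fit_tpsf_optical_props(
    tpsf: TPSF,
    sd_mm: float,
    n_medium: float = 1.4,
    init: tuple[float, float] = (0.1, 5.0),
    ring_halfwidth_mm: float | None = None,
) -> tuple[float, float]:
    """Recover homogeneous-equivalent (mua, musp') in 1/cm from a TPSF.

    Least-squares fit of log fluence (log residuals weight the decades
    of the decay evenly instead of letting the peak dominate) to the
    semi-infinite time-resolved diffusion reflectance with free
    amplitude, over the window from the 50% rising edge to the 1%
    falling tail.  Pass ``ring_halfwidth_mm`` when the histories came
    from an annular detector so the model integrates over the same
    annulus.
    """
    t = tpsf.bin_centers_ps
    y = tpsf.fluence.astype(float)
    if y.max() <= 0:
        raise FitError("empty TPSF")
    y = y / y.max()
    ipk = int(np.argmax(y))
    rising = np.flatnonzero(y[: ipk + 1] >= 0.5)
    lo = int(rising[0]) if len(rising) else 0
    falling = np.flatnonzero(y[ipk:] < 0.01)
    hi = ipk + int(falling[0]) if len(falling) else len(y)
    if hi - lo < 20:
        raise FitError("TPSF has fewer than 20 informative bins in the fit window")
    sel = np.arange(lo, hi)
    sel = sel[y[sel] > 0]
    tw, yw = t[sel], y[sel]

    if ring_halfwidth_mm is not None:
        def model(tt, mua, musp):
            return semi_infinite_reflectance_ring(
                tt, sd_mm - ring_halfwidth_mm, sd_mm + ring_halfwidth_mm,
                mua, musp, n_medium)
    else:
        def model(tt, mua, musp):
            return semi_infinite_reflectance(tt, sd_mm, mua, musp, n_medium)

    def resid(p):
        amp, mua, musp = np.exp(p)
        m = amp * model(tw, mua, musp)
        return np.log(np.maximum(m, 1e-300)) - np.log(yw)

    m0 = model(tw, init[0], init[1])
    if m0.max() <= 0:
        raise FitError("diffusion model vanishes over the fit window")
    p0 = np.log([yw.max() / m0.max(), init[0], init[1]])
    sol = least_squares(resid, p0, method="lm", xtol=1e-12, ftol=1e-12)
    mua, musp = np.exp(sol.x[1]), np.exp(sol.x[2])
    if not sol.success or not np.isfinite([mua, musp]).all():
        raise FitError("TPSF optical-property fit did not converge")
    if not (1e-4 < mua < 10 and 0.01 < musp < 1000):
        raise FitError(f"unphysical recovered properties mua={mua}, musp={musp}")
    return float(mua), float(musp)


@dataclass
class HomogeneousModel:
    """Gated homogeneous histories compressed for fast g1 evaluation.

    ``rate_atoms`` are per-photon decay-rate coefficients 2 k0^2 Y
    (units 1/s per (mm^2/s) of BFi) binned into weighted atoms, so
    g1(tau; BFi) = sum_a w_a exp(-rate_a * BFi * tau) / sum_a w_a.
    """

    mua_cm: float
    musp_cm: float
    gate: TimeGate
    rate_atoms: np.ndarray
    weight_atoms: np.ndarray
    n_members: int

    @classmethod
    def from_gated(
        cls,
        gated: GatedEnsemble,
        ctx: WavelengthContext,
        mua_cm: float | None = None,
        musp_cm: float | None = None,
        n_atoms: int = 128,
    ) -> "HomogeneousModel":
        ens = gated.ensemble
        if ens.n_layers != 1:
            raise ValueError("homogeneous model needs a single-layer ensemble")
        layer = ens.medium.layers[0]
        base = decay_rates(gated, np.array([1.0]), ctx)  # rate per unit BFi
        w = gated.weights
        atoms_r, atoms_w = _compress(base, w, n_atoms)
        return cls(
            mua_cm=mua_cm if mua_cm is not None else layer.mua_cm,
            musp_cm=musp_cm if musp_cm is not None else layer.musp_cm,
            gate=gated.gate,
            rate_atoms=atoms_r,
            weight_atoms=atoms_w,
            n_members=len(gated),
        )

    def g1(self, tau_s: np.ndarray, bfi: float) -> np.ndarray:
        ex = np.exp(-np.outer(np.asarray(tau_s, float), self.rate_atoms * bfi))
        return ex @ self.weight_atoms

    def g1_and_grad(self, tau_s: np.ndarray, bfi: float):
        tau = np.asarray(tau_s, float)
        arg = np.outer(tau, self.rate_atoms * bfi)
        ex = np.exp(-arg)
        g1 = ex @ self.weight_atoms
        # d g1 / d ln BFi = -sum w * arg * exp(-arg)
        dg1 = -(ex * arg) @ self.weight_atoms
        return g1, dg1

    def g2(self, tau_s: np.ndarray, bfi: float, beta: float) -> np.ndarray:
        return 1.0 + beta * self.g1(tau_s, bfi) ** 2


def _compress(values: np.ndarray, weights: np.ndarray, n_atoms: int):
    """Weighted binning of per-photon decay coefficients into atoms."""
    if len(values) <= n_atoms:
        return values.astype(float), weights / weights.sum()
    lo, hi = values.min(), values.max()
    if hi <= lo:
        return np.array([lo]), np.array([1.0])
    edges = np.linspace(lo, hi, n_atoms + 1)
    idx = np.clip(np.searchsorted(edges, values, side="right") - 1, 0, n_atoms - 1)
    wsum = np.bincount(idx, weights=weights, minlength=n_atoms)
    vsum = np.bincount(idx, weights=weights * values, minlength=n_atoms)
    keep = wsum > 0
    return vsum[keep] / wsum[keep], wsum[keep] / wsum.sum()


def select_fit_window(
    tau_s: np.ndarray, g2_ref: np.ndarray, beta_ref: float,
    cap_s: float = 1e-3, min_lags: int = 5
) -> np.ndarray:
    """Lag mask: where the noiseless g2 retains >= 1% of its contrast.

    ``g2_ref`` is a noiseless reference curve; lags beyond ``cap_s`` are
    dropped.  Falls back to the capped grid when too few lags qualify.
    """
    tau = np.asarray(tau_s, float)
    mask = (np.asarray(g2_ref, float) - 1.0 >= 0.01 * beta_ref) & (tau <= cap_s)
    if mask.sum() < min_lags:
        mask = tau <= cap_s
    return mask


def fit_g2(
    g2_data: np.ndarray,
    tau_s: np.ndarray,
    model: HomogeneousModel,
    init_bfi: Sequence[float] = DEFAULT_INIT_BFI,
    init_beta: Sequence[float] = DEFAULT_INIT_BETA,
) -> FitResult:
    """Fit one g2 curve for (BFi, beta) by multi-start least squares."""
    g2_data = np.asarray(g2_data, float)
    tau = np.asarray(tau_s, float)
    if g2_data.shape != tau.shape:
        raise ValueError("g2 and tau grids must match")

    def resid(p):
        bfi, beta = np.exp(p)
        return 1.0 + beta * model.g1(tau, bfi) ** 2 - g2_data

    def jac(p):
        bfi, beta = np.exp(p)
        g1, dg1 = model.g1_and_grad(tau, bfi)
        J = np.empty((len(tau), 2))
        J[:, 0] = beta * 2.0 * g1 * dg1       # d/d ln BFi
        J[:, 1] = beta * g1**2                # d/d ln beta
        return J

    best: FitResult | None = None
    for b0 in init_bfi:
        for beta0 in init_beta:
            try:
                sol = least_squares(
                    resid, np.log([b0, beta0]), jac=jac, method="lm",
                    xtol=1e-12, ftol=1e-12, max_nfev=400,
                )
            except Exception:
                continue
            bfi, beta = np.exp(sol.x)
            ok = (
                sol.success
                and np.isfinite(bfi)
                and np.isfinite(beta)
                and _BFI_LO < bfi < _BFI_HI
                and 0 < beta <= 1.2
            )
            res = FitResult(
                BFi_mm2s=float(bfi),
                beta=float(beta),
                residual_norm=float(np.linalg.norm(sol.fun)),
                init_used=(b0, beta0),
                converged=bool(ok),
            )
            if ok and (best is None or res.residual_norm < best.residual_norm):
                best = res
    if best is None:
        raise FitError("all initial guesses failed to converge")
    return best


def fit_series(
    g2_list: Sequence[np.ndarray],
    tau_s: np.ndarray,
    model: HomogeneousModel,
    init_bfi: Sequence[float] = DEFAULT_INIT_BFI,
    init_beta: Sequence[float] = DEFAULT_INIT_BETA,
) -> list[FitResult]:
    """Elementwise :func:`fit_g2`; failures are flagged, not fatal."""
    if len(g2_list) == 0:
        raise ValueError("empty g2 series")
    out = []
    for g2 in g2_list:
        try:
            out.append(fit_g2(g2, tau_s, model, init_bfi, init_beta))
        except (FitError, ValueError):
            out.append(FitResult.failed())
    return out
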