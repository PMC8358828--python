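"""Gate-quality metrics and the gate-parameter sweep.

For every time gate (start x width) the sweep evaluates:

* beta — coherence factor from the gate's path-length spread;
* count rate — the share of the overall-TPSF area inside the gate;
* intrinsic sensitivity — fractional BFi response to a fractional
  brain-flow change, from noiseless fits;
* superficial sensitivity — the same for a scalp-flow change
  (crosstalk, to be minimized);
* CNR — BFi contrast of the brain perturbation divided by the standard
  deviation of the recovered BFi series over noisy realizations, with a
  coefficient-of-variation floor emulating physiological noise;
* FoM — CNR divided by the fractional superficial sensitivity, the
  single ranking criterion.

Sensitivities use noiseless g2; CNR/FoM use noisy series — the two
halves of the evaluation are deliberately split that way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correlation import (
    NoiseModelParams,
    WavelengthContext,
    beta_from_pathlengths,
    fit_gamma,
    g1_from_histories,
    g2_noise_sigma,
    multitau_grid,
    noisy_g2_series,
    siegert,
)
from .gating import (
    EmptyGateError,
    TimeGate,
    allocate_gate,
    apparent_tofs,
    build_tpsf,
    gate_count_rate,
)
from .inversion import (
    FitError,
    HomogeneousModel,
    fit_g2,
    fit_series,
    fit_tpsf_optical_props,
    select_fit_window,
)
from .irf import IRFModel
from .media import FlowScenario, homogeneous_slab, make_flow_scenario
from .transport import HistoryEnsemble, simulate_histories

__all__ = [
    "BFiSeries",
    "NoiseConfig",
    "GateGrid",
    "MetricsGrid",
    "intrinsic_sensitivity",
    "superficial_sensitivity",
    "cnr",
    "fom",
    "sweep_gates",
]


@dataclass
class BFiSeries:
    """Recovered BFi time series with summary statistics."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) < 2:
            raise ValueError("series needs at least 2 values")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def std(self) -> float:
        return float(np.std(self.values, ddof=1))

    @property
    def cov(self) -> float:
        return self.std / self.mean


@dataclass(frozen=True)
class NoiseConfig:
    """Measurement assumptions behind the noise model."""

    total_cps: float
    integration_s: float = 1.0
    realizations: int = 120
    T_s: float = 1e-6
    cov_floor: float = 0.1
    superficial_floor_pct: float = 1.0

    def __post_init__(self) -> None:
        if self.total_cps <= 0:
            raise ValueError("total_cps must be > 0")
        if self.realizations < 2:
            raise ValueError("need at least 2 realizations")


@dataclass(frozen=True)
class GateGrid:
    starts_ps: tuple[float, ...] = tuple(np.arange(-200.0, 1001.0, 100.0))
    widths_ps: tuple[float, ...] = tuple(np.arange(100.0, 1001.0, 100.0))


@dataclass
class MetricsGrid:
    """Per-gate metric matrices (gate start x gate width)."""

    gate_starts_ps: np.ndarray
    gate_widths_ps: np.ndarray
    beta: np.ndarray
    count_rate_cps: np.ndarray
    intrinsic_sensitivity_pct: np.ndarray
    superficial_sensitivity_pct: np.ndarray
    cnr: np.ndarray
    fom: np.ndarray
    mask: np.ndarray  # True where the cell is empty/failed
    fom_flagged: np.ndarray = field(default=None)

    def _best(self, mat: np.ndarray):
        m = np.where(self.mask, -np.inf, mat)
        if not np.isfinite(m).any():
            return None
        i, j = np.unravel_index(np.nanargmax(m), m.shape)
        return {
            "start_ps": float(self.gate_starts_ps[i]),
            "width_ps": float(self.gate_widths_ps[j]),
            "value": float(mat[i, j]),
        }

    def _top_cells(self, mat: np.ndarray, frac: float = 0.2):
        vals = mat[~self.mask]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            return []
        thr = np.quantile(vals, 1.0 - frac)
        out = []
        for i, s in enumerate(self.gate_starts_ps):
            for j, w in enumerate(self.gate_widths_ps):
                if not self.mask[i, j] and np.isfinite(mat[i, j]) and mat[i, j] >= thr:
                    out.append(
                        {"start_ps": float(s), "width_ps": float(w),
                         "value": float(mat[i, j])}
                    )
        return out

    def summary(self) -> dict:
        return {
            "argmax_fom": self._best(self.fom),
            "argmax_cnr": self._best(self.cnr),
            "top20pct_fom": self._top_cells(self.fom),
            "top20pct_cnr": self._top_cells(self.cnr),
        }

    def save_csv(self, outdir) -> None:
        import pathlib

        import pandas as pd

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        names = {
            "beta": self.beta,
            "count_rate_cps": self.count_rate_cps,
            "intrinsic_sensitivity_pct": self.intrinsic_sensitivity_pct,
            "superficial_sensitivity_pct": self.superficial_sensitivity_pct,
            "cnr": self.cnr,
            "fom": self.fom,
        }
        for name, mat in names.items():
            pd.DataFrame(
                mat,
                index=pd.Index(self.gate_starts_ps, name="gate_start_ps"),
                columns=pd.Index(self.gate_widths_ps, name="gate_width_ps"),
            ).to_csv(outdir / f"{name}.csv")

    def save_heatmaps(self, outdir) -> None:
        import pathlib

        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("beta", "intrinsic_sensitivity_pct",
                     "superficial_sensitivity_pct", "cnr", "fom"):
            mat = getattr(self, name)
            fig, ax = plt.subplots()
            im = ax.imshow(
                np.where(self.mask, np.nan, mat),
                origin="lower",
                aspect="auto",
                extent=[
                    self.gate_widths_ps[0], self.gate_widths_ps[-1],
                    self.gate_starts_ps[0], self.gate_starts_ps[-1],
                ],
            )
            ax.set_xlabel("gate width (ps)")
            ax.set_ylabel("gate start after TPSF peak (ps)")
            ax.set_title(name)
            fig.colorbar(im, ax=ax)
            fig.savefig(outdir / f"{name}.png", dpi=120)
            plt.close(fig)


def intrinsic_sensitivity(
    bfi_perturbed: float, bfi_baseline: float, cbf_ratio: float
) -> float:
    """Percent response of recovered BFi to a deep-flow change.

    100 * [(BFi_p/BFi_b) - 1] / [CBF_p/CBF_b - 1]; 100% means the gate
    fully expresses the brain perturbation.
    """
    if bfi_baseline <= 0:
        raise ValueError("bfi_baseline must be > 0")
    if cbf_ratio == 1:
        raise ValueError("cbf_ratio must differ from 1")
    return 100.0 * (bfi_perturbed / bfi_baseline - 1.0) / (cbf_ratio - 1.0)


def superficial_sensitivity(
    bfi_perturbed: float, bfi_baseline: float, superficial_ratio: float
) -> float:
    """Percent response of recovered BFi to a scalp-flow change."""
    return intrinsic_sensitivity(bfi_perturbed, bfi_baseline, superficial_ratio)


def cnr(
    series_baseline: BFiSeries, bfi_perturbed_mean: float, cov_floor: float = 0.1
) -> float:
    """Contrast-to-noise ratio with a physiological-noise CoV floor.

    Denominator = max(std(baseline series), cov_floor * mean(baseline)).
    """
    if cov_floor < 0:
        raise ValueError("cov_floor must be >= 0")
    mean = series_baseline.mean
    if mean == 0:
        raise ValueError("zero-mean baseline series")
    denom = max(series_baseline.std, cov_floor * abs(mean))
    return (bfi_perturbed_mean - mean) / denom


def fom(
    cnr_value: float,
    superficial_sensitivity_pct: float,
    floor_pct: float = 1.0,
) -> float:
    """Figure of merit: CNR / (superficial sensitivity / 100).

    Superficial sensitivities below ``floor_pct`` are floored so
    noise-level crosstalk estimates cannot produce unbounded FoM.
    """
    denom_pct = max(superficial_sensitivity_pct, floor_pct)
    return cnr_value / (denom_pct / 100.0)


def _scenario_D(scenario: FlowScenario, names, which: str) -> np.ndarray:
    src = scenario.baseline if which == "baseline" else scenario.perturbed
    return np.array([src[n] for n in names])


def sweep_gates(
    ensemble: HistoryEnsemble,
    irf: IRFModel,
    flow_scenarios: dict[str, FlowScenario] | None,
    ctx: WavelengthContext,
    noise_cfg: NoiseConfig,
    grid: GateGrid,
    seed: int,
    Lc_cm: float = float("inf"),
    homogeneous_ensemble: HistoryEnsemble | None = None,
    homogeneous_photons: int = 2_000_000,
    min_members: int = 200,
    tpsf_bin_ps: float = 10.0,
) -> MetricsGrid:
    """Evaluate every gate of the grid end to end.

    ``flow_scenarios`` maps ``{"brain": ..., "superficial": ...}``; when
    None, the canonical 20% perturbations are built from the ensemble's
    medium.  ``homogeneous_ensemble`` may supply pre-simulated
    single-layer fitting histories (with optical properties close to
    the TPSF-fitted ones); otherwise they are simulated here.
    Per-cell noise uses independent substreams of ``seed`` so the grid
    is reproducible cell by cell.
    """
    medium = ensemble.medium
    names = medium.names
    if flow_scenarios is None:
        flow_scenarios = {
            "brain": make_flow_scenario(medium, "brain", 1.2),
            "superficial": make_flow_scenario(medium, "superficial", 1.2),
        }
    sc_brain = flow_scenarios["brain"]
    sc_sup = flow_scenarios["superficial"]
    D_base = _scenario_D(sc_brain, names, "baseline")
    D_brain = _scenario_D(sc_brain, names, "perturbed")
    D_sup = _scenario_D(sc_sup, names, "perturbed")
    mua = medium.mua_cm()

    ss = np.random.SeedSequence(seed)
    s_jit, s_hjit, s_htrans, s_cells = ss.spawn(4)

    apparent = apparent_tofs(ensemble, irf, np.random.default_rng(s_jit))
    tpsf = build_tpsf(ensemble, mua, apparent_ps=apparent, bin_ps=tpsf_bin_ps)

    if homogeneous_ensemble is None:
        mua_h, musp_h = fit_tpsf_optical_props(
            tpsf,
            ensemble.probe.sd_separation_mm,
            n_medium=medium.layers[0].n,
            ring_halfwidth_mm=(
                ensemble.probe.detector_radius_mm
                if ensemble.probe.geometry == "ring"
                else None
            ),
        )
        homog_medium = homogeneous_slab(
            mua_h, musp_h, g=medium.layers[0].g, n=medium.layers[0].n
        )
        homogeneous_ensemble = simulate_histories(
            homog_medium,
            ensemble.probe,
            homogeneous_photons,
            seed=int(s_htrans.generate_state(1)[0] % (2**31)),
        )
    else:
        layer0 = homogeneous_ensemble.medium.layers[0]
        mua_h, musp_h = layer0.mua_cm, layer0.musp_cm
    mua_homog = homogeneous_ensemble.medium.mua_cm()
    h_apparent = apparent_tofs(
        homogeneous_ensemble, irf, np.random.default_rng(s_hjit)
    )
    h_tpsf = build_tpsf(
        homogeneous_ensemble, mua_homog, apparent_ps=h_apparent, bin_ps=tpsf_bin_ps
    )

    starts = np.asarray(grid.starts_ps, dtype=float)
    widths = np.asarray(grid.widths_ps, dtype=float)
    shape = (len(starts), len(widths))
    mats = {
        k: np.full(shape, np.nan)
        for k in ("beta", "rate", "s_int", "s_sup", "cnr", "fom")
    }
    mask = np.ones(shape, dtype=bool)
    flagged = np.zeros(shape, dtype=bool)

    tau = multitau_grid(noise_cfg.T_s, 1e-3)
    cell_seeds = s_cells.spawn(len(starts) * len(widths))

    for i, start in enumerate(starts):
        for j, width in enumerate(widths):
            gate = TimeGate(start, width)
            try:
                gated = allocate_gate(
                    ensemble, apparent, tpsf, gate, mua,
                    min_members=min_members, tof_bin_ps=tpsf_bin_ps,
                )
                h_gated = allocate_gate(
                    homogeneous_ensemble, h_apparent, h_tpsf, gate, mua_homog,
                    min_members=min_members, tof_bin_ps=tpsf_bin_ps,
                )
            except EmptyGateError:
                continue

            beta = beta_from_pathlengths(gated.P_L, Lc_cm)
            rate = gate_count_rate(tpsf, gate, noise_cfg.total_cps)
            if rate <= 0:
                continue
            model = HomogeneousModel.from_gated(h_gated, ctx, mua_h, musp_h)

            g1_base = g1_from_histories(gated, D_base, mua, ctx, tau)
            g2_base = siegert(g1_base, beta)
            g2_brain = siegert(g1_from_histories(gated, D_brain, mua, ctx, tau), beta)
            g2_sup = siegert(g1_from_histories(gated, D_sup, mua, ctx, tau), beta)
            win = select_fit_window(tau, g2_base, beta)
            tw = tau[win]

            try:
                fit_b = fit_g2(g2_base[win], tw, model)
                fit_br = fit_g2(g2_brain[win], tw, model)
                fit_sp = fit_g2(g2_sup[win], tw, model)
            except FitError:
                continue

            s_int = intrinsic_sensitivity(
                fit_br.BFi_mm2s, fit_b.BFi_mm2s, sc_brain.ratio
            )
            s_sup = superficial_sensitivity(
                fit_sp.BFi_mm2s, fit_b.BFi_mm2s, sc_sup.ratio
            )

            gamma = fit_gamma(tau, g1_base)
            params = NoiseModelParams(
                t_s=noise_cfg.integration_s,
                T_s=noise_cfg.T_s,
                gamma_hz=gamma,
                n_avg=rate * noise_cfg.T_s,
                beta=min(beta, 1.0),
            )
            sigma = g2_noise_sigma(params, tau)
            rng = np.random.default_rng(cell_seeds[i * len(widths) + j])
            noisy_b = noisy_g2_series(
                g2_base[win], sigma[win], noise_cfg.realizations, rng
            )
            noisy_p = noisy_g2_series(
                g2_brain[win], sigma[win], noise_cfg.realizations, rng
            )
            fits_b = [f for f in fit_series(list(noisy_b), tw, model) if f.converged]
            fits_p = [f for f in fit_series(list(noisy_p), tw, model) if f.converged]
            if len(fits_b) < 2 or len(fits_p) < 2:
                continue
            series_b = BFiSeries(np.array([f.BFi_mm2s for f in fits_b]))
            mean_p = float(np.mean([f.BFi_mm2s for f in fits_p]))

            cell_cnr = cnr(series_b, mean_p, noise_cfg.cov_floor)
            cell_fom = fom(cell_cnr, s_sup, noise_cfg.superficial_floor_pct)
            flagged[i, j] = s_sup <= noise_cfg.superficial_floor_pct

            mats["beta"][i, j] = beta
            mats["rate"][i, j] = rate
            mats["s_int"][i, j] = s_int
            mats["s_sup"][i, j] = s_sup
            mats["cnr"][i, j] = cell_cnr
            mats["fom"][i, j] = cell_fom
            mask[i, j] = False

    return MetricsGrid(
        gate_starts_ps=starts,
        gate_widths_ps=widths,
        beta=mats["beta"],
        count_rate_cps=mats["rate"],
        intrinsic_sensitivity_pct=mats["s_int"],
        superficial_sensitivity_pct=mats["s_sup"],
        cnr=mats["cnr"],
        fom=mats["fom"],
        mask=mask,
        fom_flagged=flagged,
    )
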