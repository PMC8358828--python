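"""Reading and writing detected-photon history files.

The native container is HDF5 with datasets ``/L`` (mm, n_photons x
n_layers), ``/Y`` (same shape), ``/tof_ps`` and ``/detector_id``, plus
root attributes ``seed``, ``n_launched``, ``layer_names`` and YAML
snapshots of the medium and probe.

A tabular TSV dialect is also read for externally produced histories:
a header line ``detector_id  tof_ps  L1..Lk  Y1..Yk`` followed by one
row per photon (L in mm, Y dimensionless).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .media import LayeredMedium
from .transport import HistoryEnsemble, ProbeSpec

__all__ = ["write_histories", "read_histories", "read_histories_tsv",
           "write_histories_tsv"]


def write_histories(ensemble: HistoryEnsemble, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("L", data=ensemble.L_mm, compression="gzip")
        f.create_dataset("Y", data=ensemble.Y, compression="gzip")
        f.create_dataset("tof_ps", data=ensemble.tof_ps, compression="gzip")
        f.create_dataset("detector_id", data=ensemble.detector_id)
        f.attrs["seed"] = ensemble.seed
        f.attrs["n_launched"] = ensemble.n_launched
        f.attrs["layer_names"] = list(ensemble.medium.names)
        f.attrs["medium_yaml"] = yaml.safe_dump(ensemble.medium.to_dict())
        f.attrs["probe_yaml"] = yaml.safe_dump(
            {
                "sd_separation_mm": ensemble.probe.sd_separation_mm,
                "detector_radius_mm": ensemble.probe.detector_radius_mm,
                "geometry": ensemble.probe.geometry,
            }
        )


def read_histories(path, medium: LayeredMedium | None = None) -> HistoryEnsemble:
    """Load an HDF5 history container.

    If ``medium`` is given it overrides the stored snapshot and its
    layer count must match the stored arrays.
    """
    import h5py

    with h5py.File(path, "r") as f:
        L = f["L"][...]
        Y = f["Y"][...]
        tof = f["tof_ps"][...]
        det = f["detector_id"][...]
        stored_medium = LayeredMedium.from_dict(
            yaml.safe_load(f.attrs["medium_yaml"])
        )
        probe = ProbeSpec(**yaml.safe_load(f.attrs["probe_yaml"]))
        seed = int(f.attrs["seed"])
        n_launched = int(f.attrs["n_launched"])
    if medium is not None and len(medium) != L.shape[1]:
        raise ValueError(
            f"layer-count mismatch: file has {L.shape[1]} layers, "
            f"medium has {len(medium)}"
        )
    _validate(L, Y)
    return HistoryEnsemble(
        L_mm=L,
        Y=Y,
        tof_ps=tof,
        detector_id=det,
        n_launched=n_launched,
        medium=medium if medium is not None else stored_medium,
        probe=probe,
        seed=seed,
    )


def write_histories_tsv(ensemble: HistoryEnsemble, path) -> None:
    k = ensemble.n_layers
    cols = {"detector_id": ensemble.detector_id, "tof_ps": ensemble.tof_ps}
    for i in range(k):
        cols[f"L{i + 1}"] = ensemble.L_mm[:, i]
    for i in range(k):
        cols[f"Y{i + 1}"] = ensemble.Y[:, i]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_histories_tsv(
    path,
    medium: LayeredMedium,
    probe: ProbeSpec | None = None,
    n_launched: int | None = None,
) -> HistoryEnsemble:
    """Load externally produced tabular histories (see module docstring)."""
    df = pd.read_csv(path, sep="\t")
    k = len(medium)
    l_cols = [f"L{i + 1}" for i in range(k)]
    y_cols = [f"Y{i + 1}" for i in range(k)]
    missing = [c for c in ["detector_id", "tof_ps", *l_cols, *y_cols]
               if c not in df.columns]
    if missing:
        raise ValueError(
            f"malformed history TSV: missing columns {missing} "
            f"(layer-count mismatch with supplied medium?)"
        )
    L = df[l_cols].to_numpy(dtype=float)
    Y = df[y_cols].to_numpy(dtype=float)
    _validate(L, Y)
    return HistoryEnsemble(
        L_mm=L,
        Y=Y,
        tof_ps=df["tof_ps"].to_numpy(dtype=float),
        detector_id=df["detector_id"].to_numpy(),
        n_launched=n_launched if n_launched is not None else len(df),
        medium=medium,
        probe=probe if probe is not None else ProbeSpec(),
    )


def _validate(L: np.ndarray, Y: np.ndarray) -> None:
    if np.any(L < 0):
        raise ValueError("negative path length in history file")
    if np.any(Y < 0):
        raise ValueError("negative momentum transfer in history file")
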