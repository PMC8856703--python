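"""HDF5 persistence for trajectories and parameter-search stores."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .fitting import FitResult, PSEStore
from .params import DMFParams
from .simulate import NeuralTrajectory

__all__ = [
    "save_trajectory",
    "load_trajectory",
    "save_pse_store",
    "load_pse_store",
]


def save_trajectory(
    trajectory: NeuralTrajectory,
    path: str | Path,
    params: DMFParams | None = None,
) -> None:
    """Write S_E / r_E datasets plus a time axis and a parameter attribute block."""
    with h5py.File(path, "w") as f:
        f.create_dataset("S_E", data=trajectory.S_E)
        f.create_dataset("r_E", data=trajectory.r_E)
        t = (np.arange(trajectory.n_samples) + 1) * trajectory.sample_interval
        f.create_dataset("time", data=t)
        f.attrs["sample_interval_ms"] = trajectory.sample_interval
        f.attrs["seed"] = trajectory.seed
        if params is not None:
            for k, v in params.to_dict().items():
                f.attrs[f"param_{k}"] = v


def load_trajectory(path: str | Path) -> tuple[NeuralTrajectory, DMFParams | None]:
    with h5py.File(path, "r") as f:
        traj = NeuralTrajectory(
            S_E=f["S_E"][()],
            r_E=f["r_E"][()],
            sample_interval=float(f.attrs["sample_interval_ms"]),
            seed=int(f.attrs["seed"]),
        )
        pkeys = {k[6:]: float(v) for k, v in f.attrs.items() if k.startswith("param_")}
    params = DMFParams.from_dict(pkeys) if pkeys else None
    return traj, params


_FIT_FIELDS = ["g_value", "g_index", "iteration", "seed", "fc_fit", "fcd_ks", "converged", "mean_rate"]


def save_pse_store(store: PSEStore, path: str | Path) -> None:
    """Write the fit table and the per-(g, iteration) tuned J vectors."""
    with h5py.File(path, "w") as f:
        f.create_dataset("g_grid", data=store.g_grid)
        f.attrs["n_iterations"] = store.n_iterations
        tbl = f.create_group("fits")
        table = store.table()
        for col in _FIT_FIELDS:
            tbl.create_dataset(col, data=table[col].to_numpy())
        jg = f.create_group("J")
        for (gi, it), J in store.J_store.items():
            jg.create_dataset(f"g{gi:03d}_i{it:03d}", data=J)


def load_pse_store(path: str | Path) -> PSEStore:
    with h5py.File(path, "r") as f:
        store = PSEStore(
            g_grid=f["g_grid"][()], n_iterations=int(f.attrs["n_iterations"])
        )
        cols = {c: f["fits"][c][()] for c in _FIT_FIELDS}
        n_rows = len(cols["g_value"])
        for r in range(n_rows):
            store.results.append(
                FitResult(
                    g_value=float(cols["g_value"][r]),
                    g_index=int(cols["g_index"][r]),
                    iteration=int(cols["iteration"][r]),
                    seed=int(cols["seed"][r]),
                    fc_fit=float(cols["fc_fit"][r]),
                    fcd_ks=float(cols["fcd_ks"][r]),
                    converged=bool(cols["converged"][r]),
                    mean_rate=float(cols["mean_rate"][r]),
                )
            )
        for name, ds in f["J"].items():
            gi = int(name[1:4])
            it = int(name[6:9])
            store.J_store[(gi, it)] = ds[()]
    return store
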