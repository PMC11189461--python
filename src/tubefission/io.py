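"""Snapshot and time-series persistence (HDF5 fields, CSV observables)."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .energetics import ElasticParameters
from .fields import AxisymmetricGrid, MidplaneContour

__all__ = ["save_snapshot", "load_snapshot", "write_contour_csv"]


def save_snapshot(path: str | Path, grid: AxisymmetricGrid, phi: np.ndarray,
                  params: ElasticParameters, time: float = 0.0,
                  step: int = 0, extra_attrs: dict | None = None) -> None:
    """Write a self-describing field snapshot (phi + coordinates + parameters)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("phi", data=phi)
        fh.create_dataset("r_centers", data=grid.r_centers)
        fh.create_dataset("z_centers", data=grid.z_centers)
        fh.attrs["L_r_nm"] = grid.L_r
        fh.attrs["L_z_nm"] = grid.L_z
        fh.attrs["time_s"] = time
        fh.attrs["step"] = step
        for key, val in vars(params).items():
            fh.attrs[f"elastic_{key}"] = val
        for key, val in (extra_attrs or {}).items():
            fh.attrs[key] = val


def load_snapshot(path: str | Path):
    """Read a snapshot; returns (grid, phi, params, attrs)."""
    with h5py.File(path, "r") as fh:
        phi = fh["phi"][...]
        attrs = dict(fh.attrs)
    grid = AxisymmetricGrid(L_r=float(attrs["L_r_nm"]), L_z=float(attrs["L_z_nm"]),
                            N_r=phi.shape[0], N_z=phi.shape[1])
    ep_kwargs = {k.removeprefix("elastic_"): float(v)
                 for k, v in attrs.items() if k.startswith("elastic_")}
    params = ElasticParameters(**ep_kwargs)
    return grid, phi, params, attrs


def write_contour_csv(path: str | Path, contour: MidplaneContour) -> None:
    """Export a midplane contour as CSV (z_nm, r_mid_nm, closed_flag)."""
    contour.to_dataframe().to_csv(path, index=False)
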