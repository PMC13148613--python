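"""Readers and writers for the HDF5 scan container and CSV result tables.

HDF5 layout (one file per scan)::

    /scan/intensity      float  [ny, nx, n_seg, n_q]
    /scan/q              float  [n_q]        bin centers, nm^-1
    /scan/q_edges        float  [n_q + 1]    optional; derived if absent
    /scan/phi            float  [n_seg]      sector centers, degrees
    /scan/transmission   float  [ny, nx]
    /scan attrs: exposure_s, step_um, normalized

Row 0 of the intensity array is the top row of rendered maps; azimuth is
counterclockwise from the detector +x axis in degrees.
"""

from __future__ import annotations

import os

import h5py
import numpy as np
import pandas as pd

from .grids import QAzGrid
from .scan import RESULT_COLUMNS, ReducedScan, ResultTable

_REQUIRED = ("intensity", "q", "phi", "transmission")


class FormatError(ValueError):
    """The file does not follow the documented scan layout."""


def write_scan(scan: ReducedScan, path: str | os.PathLike,
               overwrite: bool = False, compress: bool = True) -> None:
    """Write a ReducedScan to the HDF5 container.

    Refuses to overwrite an existing file unless ``overwrite`` is set.
    """
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
    comp = {"compression": "gzip", "compression_opts": 4} if compress else {}
    with h5py.File(path, "w") as f:
        g = f.create_group("scan")
        g.create_dataset("intensity", data=scan.intensity, **comp)
        g.create_dataset("q", data=scan.grid.q_centers)
        g.create_dataset("q_edges", data=scan.grid.q_edges)
        g.create_dataset("phi", data=scan.grid.phi_centers)
        g.create_dataset("transmission", data=scan.transmission, **comp)
        g.attrs["exposure_s"] = scan.exposure_s
        g.attrs["step_um"] = scan.step_um
        g.attrs["normalized"] = scan.normalized


def read_scan(path: str | os.PathLike) -> ReducedScan:
    """Read and validate a ReducedScan from the HDF5 container."""
    with h5py.File(path, "r") as f:
        if "scan" not in f:
            raise FormatError("missing group /scan")
        g = f["scan"]
        for name in _REQUIRED:
            if name not in g:
                raise FormatError(f"missing dataset /scan/{name}")
        q = np.asarray(g["q"][()], dtype=float)
        if not np.all(np.isfinite(q)):
            raise FormatError("NaN or infinite value in /scan/q")
        if "q_edges" in g:
            q_edges = np.asarray(g["q_edges"][()], dtype=float)
        else:
            # reconstruct edges from midpoints, extrapolating the ends
            mid = 0.5 * (q[:-1] + q[1:])
            q_edges = np.concatenate([[2 * q[0] - mid[0]], mid, [2 * q[-1] - mid[-1]]])
        phi = np.asarray(g["phi"][()], dtype=float)
        intensity = np.asarray(g["intensity"][()], dtype=float)
        transmission = np.asarray(g["transmission"][()], dtype=float)
        attrs = dict(g.attrs)
    try:
        grid = QAzGrid(q_centers=q, q_edges=q_edges, phi_centers=phi)
        return ReducedScan(
            intensity=intensity,
            transmission=transmission,
            grid=grid,
            exposure_s=float(attrs.get("exposure_s", 0.1)),
            step_um=float(attrs.get("step_um", 25.0)),
            normalized=bool(attrs.get("normalized", False)),
        )
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


def write_result_table(table: ResultTable, path: str | os.PathLike) -> None:
    """Write a per-point result table as CSV.

    One header row, one row per scan point, columns in the documented
    stable order (see :data:`scansaxs.scan.RESULT_COLUMNS`).
    """
    table.data.to_csv(path, index=False, float_format="%.10g")


def read_result_table(path: str | os.PathLike) -> ResultTable:
    """Read a CSV written by :func:`write_result_table`."""
    df = pd.read_csv(path)
    missing = [c for c in ("row", "col", "region") if c not in df.columns]
    if missing:
        raise FormatError(f"result table missing columns: {missing}")
    return ResultTable(data=df)
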