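"""Azimuthal regrouping of raw detector frames and scan normalization.

A raw frame is regrouped onto a :class:`~scansaxs.grids.QAzGrid` by assigning
every unmasked pixel to the (sector, q) bin containing its (q, phi) and
taking the *mean* of pixel counts per bin.  The mean (rather than the sum)
makes bins comparable across unequal pixel populations; solid-angle and
polarization corrections are out of scope.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .grids import SENTINEL, QAzGrid
from .scan import DetectorGeometry, ReducedScan

log = logging.getLogger(__name__)


@dataclass
class DetectorFrame:
    """A single raw detector exposure with its geometry."""

    counts: np.ndarray
    geometry: DetectorGeometry

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2D")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


def reduce_frame(frame: DetectorFrame, grid: QAzGrid,
                 return_counts: bool = False) -> np.ndarray:
    """Regroup a detector frame into an ``[n_seg, n_q]`` intensity slab.

    Each populated bin holds the mean of the unmasked pixel counts whose
    (q, phi) fall in that bin; empty bins hold the missing-data sentinel.
    With ``return_counts`` the per-bin pixel counts are returned as well
    (useful for photon-conservation checks).
    """
    q, phi = frame.geometry.pixel_q_phi(frame.counts.shape)
    mask = frame.geometry.mask
    keep = np.ones(frame.counts.shape, dtype=bool) if mask is None else ~mask
    if not keep.any():
        raise ValueError("all detector pixels are masked")

    if grid.q_edges[-1] > q[keep].max() or grid.q_edges[0] < q[keep].min():
        warnings.warn(
            "q grid extends beyond the detector's accessible q range; "
            "out-of-range bins will be sentinel", stacklevel=2)

    q_idx = np.digitize(q[keep], grid.q_edges) - 1
    in_q = (q_idx >= 0) & (q_idx < grid.n_q)
    seg_w = grid.seg_width_deg
    # sector k spans [k*w, (k+1)*w); centers are (k+0.5)*w
    seg_idx = np.floor((phi[keep] % 360.0) / seg_w).astype(int) % grid.n_seg

    flat = seg_idx[in_q] * grid.n_q + q_idx[in_q]
    vals = frame.counts[keep][in_q].astype(float)
    nbins = grid.n_seg * grid.n_q
    sums = np.bincount(flat, weights=vals, minlength=nbins)
    counts = np.bincount(flat, minlength=nbins)
    slab = np.full(nbins, SENTINEL)
    np.divide(sums, counts, out=slab, where=counts > 0)
    slab = slab.reshape(grid.n_seg, grid.n_q)
    if return_counts:
        return slab, counts.reshape(grid.n_seg, grid.n_q)
    return slab


def estimate_transmission(frame: DetectorFrame, beamstop_roi: tuple[int, int, int, int],
                          empty_reference: float) -> float:
    """Transmission proxy from beamstop-scatter counts.

    ``beamstop_roi`` is ``(row0, row1, col0, col1)`` (half-open).  Returns
    (ROI count sum) / ``empty_reference`` clipped to (0, 1]; the scatter
    proxy can exceed the empty-beam reference through noise, in which case
    a warning is issued and 1.0 returned.
    """
    if empty_reference <= 0:
        raise ValueError("empty_reference must be > 0")
    r0, r1, c0, c1 = beamstop_roi
    roi_sum = float(frame.counts[r0:r1, c0:c1].sum())
    if roi_sum == 0:
        raise ValueError("beamstop ROI sum is zero (beam off?)")
    t = roi_sum / empty_reference
    if t > 1.0:
        warnings.warn(f"transmission {t:.3f} > 1 clipped to 1.0", stacklevel=2)
        t = 1.0
    return t


def normalize_scan(scan: ReducedScan) -> ReducedScan:
    """Divide intensities per point by (transmission x exposure time).

    Idempotent: a scan already carrying the ``normalized`` flag is returned
    unchanged.  Points with non-positive transmission are masked (all bins
    set to the sentinel) and logged.
    """
    if scan.normalized:
        return scan
    intensity = scan.intensity.copy()
    valid = scan.valid_mask()
    t = scan.transmission
    bad = t <= 0
    if bad.any():
        log.warning("masking %d scan points with non-positive transmission",
                    int(bad.sum()))
        intensity[bad] = SENTINEL
    ok = ~bad
    factor = np.ones_like(t)
    factor[ok] = t[ok] * scan.exposure_s
    intensity = np.where(valid & ok[:, :, None, None],
                         intensity / factor[:, :, None, None], intensity)
    return ReducedScan(
        intensity=intensity, transmission=scan.transmission, grid=scan.grid,
        exposure_s=scan.exposure_s, step_um=scan.step_um, normalized=True,
    )
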