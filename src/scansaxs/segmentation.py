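"""Region segmentation from the low-q intensity exponent.

Each scan point is classified as collagen, muscle, other connective
structure, or background from the power-law exponent (slope of log I vs
log q) of its azimuthally averaged profile in a fixed q window on the
rising edge of the first-order collagen peak (default 0.085-0.095 nm^-1).
Collagen shows a positive slope there; diffuse muscle scatter a moderately
negative one; a third connective-tissue component with broad peaks near
q = 0.075, 0.16 and 0.245 nm^-1 an even lower exponent.  Samples whose
first-order collagen peak is destroyed by processing are caught by an
enhanced sixth-order meridional reflection instead (OR-combined rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import QAzGrid
from .peakfit import fit_peak
from .scan import (REGION_BACKGROUND, REGION_COLLAGEN, REGION_MUSCLE,
                   REGION_OTHER, ReducedScan)

#: Exponent sentinel for points where the fit is impossible.
ALPHA_SENTINEL: float = float("nan")

DEFAULT_EXPONENT_WINDOW = (0.085, 0.095)


@dataclass
class SegmentationThresholds:
    """Exponent/transmission cuts; only the ordering is physically fixed
    (collagen has a positive slope), the numeric values are tunable."""

    t_collagen: float = 0.0    # alpha >= t_collagen -> collagen
    t_other: float = -4.0      # alpha < t_other -> other connective
    t_background: float = 0.99  # transmission >= t_background -> empty beam


@dataclass
class ExponentMap:
    alpha: np.ndarray                       # [ny, nx], NaN = not fittable
    fit_window: tuple[float, float] = DEFAULT_EXPONENT_WINDOW


@dataclass
class RegionMap:
    label: np.ndarray                       # [ny, nx] int codes
    thresholds: SegmentationThresholds = field(default_factory=SegmentationThresholds)


def compute_intensity_exponent(scan: ReducedScan,
                               window: tuple[float, float] = DEFAULT_EXPONENT_WINDOW,
                               ) -> ExponentMap:
    """Least-squares slope of log I vs log q over ``window`` per point.

    Uses the azimuthally averaged profile.  Points with fewer than 4
    positive valid bins in the window get the NaN sentinel (later labeled
    background).
    """
    q = scan.grid.q_centers
    sel = (q >= window[0]) & (q <= window[1])
    if not sel.any():
        raise ValueError(f"exponent window {window} outside q grid")
    prof = scan.azimuthal_mean()[:, :, sel]       # [ny, nx, m]
    logq = np.log(q[sel])
    ny, nx, m = prof.shape
    valid = prof > 0
    nv = valid.sum(axis=2)
    alpha = np.full((ny, nx), ALPHA_SENTINEL)
    ok = nv >= 4
    if ok.any():
        # per-point weighted least squares on the valid bins only
        logy = np.where(valid, np.log(np.where(valid, prof, 1.0)), 0.0)
        w = valid.astype(float)
        sw = w.sum(axis=2)
        sx = (w * logq).sum(axis=2)
        sy = (w * logy).sum(axis=2)
        sxx = (w * logq ** 2).sum(axis=2)
        sxy = (w * logq * logy).sum(axis=2)
        denom = sw * sxx - sx ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            slope = (sw * sxy - sx * sy) / denom
        alpha[ok] = slope[ok]
    return ExponentMap(alpha=alpha, fit_window=window)


def detect_sixth_order(scan: ReducedScan, d_ref: float = 67.0,
                       tol: float = 0.06, snr_min: float = 3.0) -> np.ndarray:
    """Boolean [ny, nx] map: sixth-order collagen reflection present.

    Fits a Gaussian in the window 2*pi*6/d_ref * (1 +- tol) of the
    azimuthal-mean profile; True where the amplitude clears ``snr_min``
    times the local residual RMS.  Ill-conditioned fits return False.
    """
    q6 = 2.0 * np.pi * 6.0 / d_ref
    window = (q6 * (1 - tol), q6 * (1 + tol))
    q = scan.grid.q_centers
    if window[0] < q[0] or window[1] > q[-1]:
        raise ValueError(f"sixth-order window {window} outside q grid")
    prof = scan.azimuthal_mean()
    ny, nx = prof.shape[:2]
    out = np.zeros((ny, nx), dtype=bool)
    for i in range(ny):
        for j in range(nx):
            fit = fit_peak(q, prof[i, j], window, order=6, snr_min=snr_min)
            out[i, j] = fit.visible
    return out


def segment_regions(expmap: ExponentMap, sixth: np.ndarray,
                    transmission: np.ndarray,
                    thresholds: SegmentationThresholds | None = None) -> RegionMap:
    """Assign each point one of {background, collagen, muscle, other}.

    Rules, in order: background where transmission >= t_background (empty
    beam) or the exponent is unfittable; collagen where alpha >=
    t_collagen OR the sixth-order reflection is present; other where
    alpha < t_other; muscle otherwise.  Deterministic given its inputs.
    """
    th = thresholds or SegmentationThresholds()
    alpha = expmap.alpha
    if not (alpha.shape == sixth.shape == transmission.shape):
        raise ValueError("maps must be congruent")
    label = np.full(alpha.shape, REGION_MUSCLE, dtype=int)
    label[alpha < th.t_other] = REGION_OTHER
    label[(alpha >= th.t_collagen) | sixth] = REGION_COLLAGEN
    label[(transmission >= th.t_background) | ~np.isfinite(alpha)] = REGION_BACKGROUND
    return RegionMap(label=label, thresholds=th)
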