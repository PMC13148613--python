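"""Gaussian peak fitting with local power-law background subtraction.

Shared by the collagen meridional and muscle equatorial analyses.  Within a
q window, a power law ``A * q**b`` is fitted to the outer 20% of bins on
each flank and subtracted, then a single Gaussian is fitted to the residual
by nonlinear least squares (lmfit).  A peak is *visible* when its amplitude
clears ``snr_min`` times the post-fit residual RMS and its center lies
strictly inside the window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from lmfit import Model

GAUSS_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class PeakFit:
    """A fitted Gaussian reflection and its local background."""

    order: int | None = None
    center: float = float("nan")      # nm^-1
    sigma: float = float("nan")       # nm^-1
    amplitude: float = float("nan")   # counts (peak height)
    visible: bool = False
    background: tuple[float, float] = (0.0, 0.0)  # (A, b) of A*q**b
    snr: float = float("nan")
    message: str = ""
    window: tuple[float, float] = (float("nan"), float("nan"))

    @property
    def fwhm(self) -> float:
        return GAUSS_FWHM * self.sigma

    @property
    def area(self) -> float:
        """Integrated intensity, amplitude * sigma * sqrt(2 pi)."""
        return self.amplitude * self.sigma * math.sqrt(2.0 * math.pi)


def _gauss(x, amplitude, center, sigma):
    return amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)


_GAUSS_MODEL = Model(_gauss)


def _fit_background(q: np.ndarray, y: np.ndarray, n_flank: int) -> tuple[float, float]:
    """Power law through the outer flank bins; log-log least squares.

    Falls back to a constant (median of flank values) when too few flank
    bins are positive for a log fit.
    """
    flank = np.zeros(q.size, dtype=bool)
    flank[:n_flank] = True
    flank[-n_flank:] = True
    qf, yf = q[flank], y[flank]
    pos = yf > 0
    if pos.sum() >= 4:
        b, lnA = np.polyfit(np.log(qf[pos]), np.log(yf[pos]), 1)
        return float(np.exp(lnA)), float(b)
    return float(max(np.median(yf), 0.0)), 0.0


def fit_peak(q: np.ndarray, intensity: np.ndarray, window: tuple[float, float],
             order: int | None = None, snr_min: float = 3.0,
             recentre: bool = True) -> PeakFit:
    """Fit one Gaussian reflection inside ``window`` (q interval, nm^-1).

    ``intensity`` may contain negative sentinel values; those bins are
    ignored.  Requires at least 8 valid bins in the window (including
    flanks); otherwise the peak is reported invisible with a diagnostic.

    When the fitted center lands inside a background flank (a reflection
    shifted by e.g. embedding shrinkage toward a window edge), the window
    is recentred on that estimate once and the fit repeated, so the
    background is estimated from flanks that actually exclude the peak.
    """
    fit = _fit_peak_once(q, intensity, window, order, snr_min)
    if recentre and np.isfinite(fit.center):
        lo, hi = window
        flank = 0.2 * (hi - lo)
        if not (lo + flank <= fit.center <= hi - flank):
            shifted = (fit.center - (hi - lo) / 2, fit.center + (hi - lo) / 2)
            refit = _fit_peak_once(q, intensity, shifted, order, snr_min)
            if refit.visible or not fit.visible:
                refit.message = (refit.message + " window recentred").strip()
                return refit
    return fit


def _fit_peak_once(q: np.ndarray, intensity: np.ndarray,
                   window: tuple[float, float], order: int | None,
                   snr_min: float) -> PeakFit:
    q = np.asarray(q, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    lo, hi = window
    sel = (q >= lo) & (q <= hi) & (intensity >= 0) & np.isfinite(intensity)
    qw, yw = q[sel], intensity[sel]
    fit = PeakFit(order=order, window=(lo, hi))
    if qw.size < 8:
        fit.message = f"only {qw.size} valid bins in window"
        return fit

    n_flank = max(2, int(math.ceil(0.2 * qw.size)))
    A, b = _fit_background(qw, yw, n_flank)
    bg = A * qw ** b
    resid = yw - bg

    amp0 = float(resid.max())
    if amp0 <= 0:
        amp0 = max(float(np.abs(resid).max()), 1e-12)
    c0 = float(qw[int(np.argmax(resid))])
    width = hi - lo
    dq = float(np.median(np.diff(qw)))
    params = _GAUSS_MODEL.make_params(amplitude=amp0, center=c0, sigma=width / 10.0)
    params["amplitude"].set(min=0.0)
    params["center"].set(min=lo, max=hi)
    params["sigma"].set(min=dq / 2.0, max=width)

    try:
        res = _GAUSS_MODEL.fit(resid, params, x=qw)
    except Exception as exc:  # pragma: no cover - lmfit failure path
        fit.background = (A, b)
        fit.message = f"fit failed: {exc}"
        return fit

    amp = float(res.params["amplitude"].value)
    center = float(res.params["center"].value)
    sigma = float(res.params["sigma"].value)
    rms = float(np.sqrt(np.mean(res.residual ** 2)))
    # absolute floor keeps a numerically-zero residual from promoting a
    # numerically-zero amplitude to "visible"
    floor = 1e-9 * max(1.0, float(np.abs(yw).max()))
    snr = amp / max(rms, floor / snr_min) if (rms > 0 or amp > 0) else 0.0

    fit.center, fit.sigma, fit.amplitude = center, sigma, amp
    fit.background = (A, b)
    fit.snr = amp / rms if rms > 0 else float("inf") if amp > 0 else 0.0
    fit.visible = bool(
        res.success
        and amp >= snr_min * max(rms, floor / snr_min)
        and lo < center < hi
        # q-binning resolution limit: a reflection narrower than ~1.5 bins
        # is indeterminate and indistinguishable from a noise spike
        and sigma >= 1.5 * dq
    )
    if not res.success:
        fit.message = res.message or "optimizer did not converge"
    return fit
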