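"""Azimuthal anisotropy analysis: the pi-periodic cosine model.

The azimuthal intensity of a fibrous scatterer in a q band follows

    I(phi) = a_sym + a_asym * cos(2 * (phi - theta_s))

where ``a_sym`` is the mean (symmetric) band intensity, ``a_asym`` the
anisotropic amplitude and ``theta_s`` the scattering-anisotropy direction.
The degree of orientation is ``a_asym / a_sym`` (0 isotropic, 1 fully
oriented).  With all sectors valid the parameters are the discrete 2-phi
Fourier component of the azimuthal vector (exact by orthogonality on a
uniform sector grid); with missing sectors an equivalent least-squares fit
on the cosine basis is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import SENTINEL

#: theta_s reported for isotropic points (a_asym == 0), where the direction
#: is undefined.
THETA_UNDEFINED: float = float("nan")


@dataclass
class OrientationResult:
    """Cosine-model parameters of one scan point in one q band."""

    a_sym: float
    a_asym: float
    theta_s: float          # degrees in [0, 180); NaN when undefined
    q_band: tuple[float, float] = (float("nan"), float("nan"))
    valid: bool = True

    @property
    def degree(self) -> float:
        """Degree of orientation, a_asym / a_sym."""
        if not self.valid or self.a_sym <= 0:
            return float("nan")
        return self.a_asym / self.a_sym


def band_profile(point_intensity: np.ndarray, q_centers: np.ndarray,
                 band: tuple[float, float]) -> np.ndarray:
    """Per-sector mean intensity over the valid q bins in ``band``.

    ``point_intensity`` is ``[n_seg, n_q]``.  Sectors with no valid bin in
    the band are set to the sentinel.  Raises if more than half of the
    sectors end up sentinel (the point cannot be fitted).
    """
    lo, hi = band
    sel = (q_centers >= lo) & (q_centers <= hi)
    if not sel.any():
        raise ValueError(f"band {band} contains no q bins")
    sub = point_intensity[:, sel]
    valid = sub >= 0
    n_valid = valid.sum(axis=1)
    out = np.full(sub.shape[0], SENTINEL)
    np.divide(np.where(valid, sub, 0.0).sum(axis=1), n_valid,
              out=out, where=n_valid > 0)
    if (out < 0).sum() > sub.shape[0] // 2:
        raise ValueError("more than half of the azimuth sectors have no data in band")
    return out


def fit_azimuthal_orientation(az: np.ndarray, phi_centers: np.ndarray,
                              q_band: tuple[float, float] = (float("nan"), float("nan")),
                              ) -> OrientationResult:
    """Fit the cosine model to one azimuthal vector.

    Sentinel (negative) entries are treated as missing.  Requires at least
    8 valid sectors.  Complete data uses the closed-form Fourier component;
    incomplete data a least-squares fit on the basis {1, cos 2phi, sin 2phi}
    — the two coincide when nothing is missing.
    """
    az = np.asarray(az, dtype=float)
    phi = np.radians(np.asarray(phi_centers, dtype=float))
    valid = az >= 0
    n = int(valid.sum())
    if n < 8:
        return OrientationResult(float("nan"), float("nan"), THETA_UNDEFINED,
                                 q_band, valid=False)
    if valid.all():
        a_sym = float(az.mean())
        c2 = (2.0 / az.size) * np.sum(az * np.exp(-2j * phi))
    else:
        basis = np.column_stack([np.ones(n), np.cos(2 * phi[valid]),
                                 np.sin(2 * phi[valid])])
        coef, *_ = np.linalg.lstsq(basis, az[valid], rcond=None)
        a_sym = float(coef[0])
        c2 = complex(coef[1], -coef[2])
    a_asym = float(abs(c2))
    if a_sym <= 0:
        return OrientationResult(a_sym, a_asym, THETA_UNDEFINED, q_band, valid=False)
    if a_asym <= 1e-12 * a_sym:   # isotropic to machine precision
        a_asym = 0.0
        theta = THETA_UNDEFINED
    else:
        theta = float(np.degrees(-np.angle(c2) / 2.0) % 180.0)
    return OrientationResult(a_sym, a_asym, theta, q_band, valid=True)


def fiber_axis(theta_s: float, mode: str) -> float:
    """Long-axis direction implied by the scattering anisotropy direction.

    ``meridional`` (collagen): the fiber axis lies along the meridional
    scattering direction, so theta_s is returned as-is.  ``equatorial``
    (myofibrils): the long axis is perpendicular to the equatorial
    scattering direction, so 90 degrees are added (mod 180).
    """
    if mode == "meridional":
        return float(theta_s % 180.0)
    if mode == "equatorial":
        return float((theta_s + 90.0) % 180.0)
    raise ValueError(f"unknown mode {mode!r}")
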