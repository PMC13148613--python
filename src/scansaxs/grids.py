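"""Scattering-vector and azimuth grids for azimuthally segmented scan data.

Every reduced scan point is a small image ``I[segment, q]``: the detector
pattern regrouped into ``n_seg`` azimuthal sectors (default 16) and ``n_q``
radial bins (default 1200) over the accessible momentum-transfer range.
``q`` is the magnitude of the scattering vector in nm^-1; azimuth ``phi`` is
measured counterclockwise from the detector +x axis, in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Value marking missing / invalid intensity bins.  Physical intensities are
#: non-negative, so any negative entry is treated as "no data" and excluded
#: from every fit.  Stored as-is on disk so masks survive serialization.
SENTINEL: float = -1.0

DEFAULT_N_Q = 1200
DEFAULT_N_SEG = 16
DEFAULT_Q_MIN = 0.05
DEFAULT_Q_MAX = 1.0


@dataclass(frozen=True)
class QAzGrid:
    """Radial (q) and azimuthal (phi) binning of a reduced scattering pattern.

    Parameters
    ----------
    q_centers
        Bin centers in nm^-1, strictly increasing, length ``n_q``.
    q_edges
        Bin edges, length ``n_q + 1``, monotone increasing.
    phi_centers
        Azimuth sector centers in degrees in ``[0, 360)``, uniformly spaced.
        ``n_seg`` must be even so that sectors come in opposite pairs
        (``k`` and ``k + n_seg/2`` face each other across the beam center).
    """

    q_centers: np.ndarray
    q_edges: np.ndarray
    phi_centers: np.ndarray = field(
        default_factory=lambda: make_phi_centers(DEFAULT_N_SEG)
    )

    def __post_init__(self) -> None:
        q_c = np.asarray(self.q_centers, dtype=float)
        q_e = np.asarray(self.q_edges, dtype=float)
        phi = np.asarray(self.phi_centers, dtype=float)
        object.__setattr__(self, "q_centers", q_c)
        object.__setattr__(self, "q_edges", q_e)
        object.__setattr__(self, "phi_centers", phi)
        if q_c.ndim != 1 or q_e.ndim != 1 or q_e.size != q_c.size + 1:
            raise ValueError("q_edges must have length n_q + 1")
        if not np.all(np.isfinite(q_c)) or not np.all(np.isfinite(q_e)):
            raise ValueError("q grid contains non-finite values")
        if np.any(np.diff(q_c) <= 0) or np.any(np.diff(q_e) <= 0):
            raise ValueError("q grid must be strictly increasing")
        if phi.ndim != 1 or phi.size < 2 or phi.size % 2 != 0:
            raise ValueError("phi_centers must be a 1D array of even length")
        spacing = np.diff(phi)
        if not np.allclose(spacing, spacing[0]):
            raise ValueError("phi sectors must be uniformly spaced")
        if not np.isclose(spacing[0] * phi.size, 360.0):
            raise ValueError("phi sectors must tile [0, 360)")

    @property
    def n_q(self) -> int:
        return self.q_centers.size

    @property
    def n_seg(self) -> int:
        return self.phi_centers.size

    @property
    def seg_width_deg(self) -> float:
        return 360.0 / self.n_seg

    def q_slice(self, q_lo: float, q_hi: float) -> slice:
        """Index slice of q bins whose centers fall in ``[q_lo, q_hi]``."""
        idx = np.nonzero((self.q_centers >= q_lo) & (self.q_centers <= q_hi))[0]
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)


def make_phi_centers(n_seg: int = DEFAULT_N_SEG) -> np.ndarray:
    """Uniform sector centers tiling [0, 360): first sector spans [0, w)."""
    w = 360.0 / n_seg
    return (np.arange(n_seg) + 0.5) * w


def default_grid(
    n_q: int = DEFAULT_N_Q,
    q_min: float = DEFAULT_Q_MIN,
    q_max: float = DEFAULT_Q_MAX,
    n_seg: int = DEFAULT_N_SEG,
) -> QAzGrid:
    """The package's default grid: 1200 q bins on 0.05-1.0 nm^-1, 16 sectors.

    The upper limit is set so that collagen meridional orders up to n = 10
    (D ~ 67 nm, q_10 ~ 0.94 nm^-1) remain on-grid for per-order prevalence
    tables.
    """
    q_edges = np.linspace(q_min, q_max, n_q + 1)
    q_centers = 0.5 * (q_edges[:-1] + q_edges[1:])
    return QAzGrid(q_centers=q_centers, q_edges=q_edges,
                   phi_centers=make_phi_centers(n_seg))


def angular_distance_mod180(a: float | np.ndarray, b: float | np.ndarray):
    """Smallest separation between two axial (pi-periodic) angles, degrees."""
    d = np.abs((np.asarray(a) - np.asarray(b)) % 180.0)
    return np.minimum(d, 180.0 - d)
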