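"""Scan-level containers: reduced scans, detector geometry, result tables."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import SENTINEL, QAzGrid

#: Fixed region vocabulary.  Integer codes are what lives in label arrays;
#: names are what lives in CSV exports.
REGION_BACKGROUND = 0
REGION_COLLAGEN = 1
REGION_MUSCLE = 2
REGION_OTHER = 3
REGION_NAMES = {
    REGION_BACKGROUND: "background",
    REGION_COLLAGEN: "collagen",
    REGION_MUSCLE: "muscle",
    REGION_OTHER: "other",
}
REGION_CODES = {v: k for k, v in REGION_NAMES.items()}


@dataclass
class DetectorGeometry:
    """Flat-detector geometry used to map pixels to (q, phi).

    Defaults describe a generic 2 m flight-tube setup with a photon-counting
    detector (172 um pixels) at 12.4 keV (wavelength 0.1 nm); they are
    consistent with the built-in simulator, not calibrated to any instrument.
    """

    sample_detector_distance_mm: float = 2000.0
    pixel_size_um: float = 172.0
    beam_center_px: tuple[float, float] = (128.0, 128.0)  # (row, col)
    wavelength_nm: float = 0.1
    mask: np.ndarray | None = None  # True = masked (excluded)

    def __post_init__(self) -> None:
        if self.sample_detector_distance_mm <= 0:
            raise ValueError("sample-detector distance must be > 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be > 0")

    def pixel_q_phi(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Per-pixel q (nm^-1) and azimuth phi (degrees in [0, 360)).

        Uses the exact flat-detector relation q = (4 pi / lambda) sin(0.5
        atan(r / L)); azimuth is counterclockwise from +x (columns increase
        along +x, rows increase downward, so row offsets are negated).
        """
        rows, cols = np.indices(shape)
        cr, cc = self.beam_center_px
        if not (0 <= cr < shape[0] and 0 <= cc < shape[1]):
            raise ValueError("beam center outside frame")
        dx = (cols - cc) * self.pixel_size_um * 1e-6  # m
        dy = -(rows - cr) * self.pixel_size_um * 1e-6
        r = np.hypot(dx, dy)
        L = self.sample_detector_distance_mm * 1e-3
        q = (4.0 * np.pi / self.wavelength_nm) * np.sin(0.5 * np.arctan2(r, L))
        phi = np.degrees(np.arctan2(dy, dx)) % 360.0
        return q, phi


@dataclass
class ReducedScan:
    """Azimuthally segmented scanning-SAXS data set.

    ``intensity`` has shape ``[ny, nx, n_seg, n_q]`` in counts per exposure.
    Missing bins carry the negative sentinel and are excluded from all fits.
    ``transmission`` is the per-point direct-beam transmission in (0, 1].
    """

    intensity: np.ndarray
    transmission: np.ndarray
    grid: QAzGrid
    exposure_s: float = 0.1
    step_um: float = 25.0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.transmission = np.asarray(self.transmission, dtype=float)
        if self.intensity.ndim != 4:
            raise ValueError("intensity must be [ny, nx, n_seg, n_q]")
        ny, nx, n_seg, n_q = self.intensity.shape
        if (n_seg, n_q) != (self.grid.n_seg, self.grid.n_q):
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match grid "
                f"({self.grid.n_seg} sectors, {self.grid.n_q} q bins)"
            )
        if self.transmission.shape != (ny, nx):
            raise ValueError("transmission must be [ny, nx]")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite (use the sentinel for gaps)")
        if self.exposure_s <= 0 or self.step_um <= 0:
            raise ValueError("exposure_s and step_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape[:2]

    def valid_mask(self) -> np.ndarray:
        """Boolean [ny, nx, n_seg, n_q]: True where a bin holds data."""
        return self.intensity >= 0

    def azimuthal_mean(self) -> np.ndarray:
        """Sentinel-aware mean over sectors -> [ny, nx, n_q] profile.

        Bins with no valid sector are set to the sentinel.
        """
        valid = self.valid_mask()
        num = np.where(valid, self.intensity, 0.0).sum(axis=2)
        den = valid.sum(axis=2)
        out = np.full(num.shape, SENTINEL)
        np.divide(num, den, out=out, where=den > 0)
        return out


#: Column order of the per-point result table, stable across releases.
RESULT_COLUMNS = [
    "row", "col", "region",
    "alpha", "transmission",
    # collagen orientation band
    "col_a_sym", "col_a_asym", "col_theta_s", "col_degree",
    # myofibril orientation band
    "mus_a_sym", "mus_a_asym", "mus_theta_s", "mus_degree",
    # collagen meridional results
    "D5", "D6", "fwhm5", "fwhm6", "i6_over_i5", "overlap_fraction",
    # muscle equatorial results
    "q10", "q11", "d10", "d11", "lattice_a",
    "fwhm10", "fwhm11", "i11_over_i10",
]


@dataclass
class ResultTable:
    """One record per scan point with all per-point analysis outputs.

    Backed by a pandas DataFrame with the documented stable column order;
    unknown values are NaN, region labels use the fixed name vocabulary.
    """

    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=RESULT_COLUMNS))

    def __post_init__(self) -> None:
        df = self.data
        for c in RESULT_COLUMNS:
            if c not in df.columns:
                df[c] = np.nan
        extra = [c for c in df.columns if c not in RESULT_COLUMNS]
        self.data = df[RESULT_COLUMNS + extra]
        if len(df) and df.duplicated(subset=["row", "col"]).any():
            raise ValueError("(row, col) pairs must be unique")
        if len(df):
            bad = set(df["region"].dropna()) - set(REGION_NAMES.values())
            if bad:
                raise ValueError(f"unknown region labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.data)
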