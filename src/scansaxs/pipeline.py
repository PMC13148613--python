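"""Pipeline orchestration: segment -> orient -> analyze -> summarize.

:func:`analyze_scan` runs the full per-point analysis of one reduced scan
and returns a :class:`~scansaxs.scan.ResultTable` plus the intermediate
maps; :func:`run_pipeline` adds file I/O (CSV tables, PNG maps, a config
log); :func:`compare_samples` builds the cross-sample comparison report
(distribution summaries, rank-sum tests, percent change of medians against
a declared reference sample).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .collagen import (D_NOMINAL_NM, HYDRATED_OVERLAP_REFERENCE,
                       analyze_collagen_point)
from .io import read_scan, write_result_table
from .muscle import DEFAULT_WINDOW_10, DEFAULT_WINDOW_11, analyze_muscle_point
from .orientation import band_profile, fit_azimuthal_orientation
from .reduction import normalize_scan
from .scan import (REGION_COLLAGEN, REGION_MUSCLE, REGION_NAMES, ReducedScan,
                   ResultTable)
from .segmentation import (DEFAULT_EXPONENT_WINDOW, SegmentationThresholds,
                           compute_intensity_exponent, detect_sixth_order,
                           segment_regions)
from .stats import compare_distributions, percent_change, summarize

log = logging.getLogger(__name__)

#: Parameters compared across samples, keyed by result-table column.
COMPARISON_PARAMETERS = ["D5", "D6", "fwhm5", "fwhm6", "i6_over_i5",
                         "overlap_fraction", "d10", "d11", "fwhm10",
                         "fwhm11", "i11_over_i10"]


@dataclass
class PipelineConfig:
    """All tunable q windows and thresholds, serializable to YAML.

    The three printed-analysis windows (segmentation 0.085-0.095, collagen
    band 0.085-0.11, myofibril band 0.231-0.367 nm^-1) are the defaults.
    """

    exponent_window: tuple[float, float] = DEFAULT_EXPONENT_WINDOW
    collagen_band: tuple[float, float] = (0.085, 0.11)
    myofibril_band: tuple[float, float] = (0.231, 0.367)
    window10: tuple[float, float] = DEFAULT_WINDOW_10
    window11: tuple[float, float] = DEFAULT_WINDOW_11
    d_nominal: float = D_NOMINAL_NM
    collagen_orders: tuple[int, ...] = (5, 6)
    overlap_reference: float = HYDRATED_OVERLAP_REFERENCE
    t_collagen: float = 0.0
    t_other: float = -4.0
    t_background: float = 0.99
    snr_min: float = 3.0
    render_percentiles: tuple[float, float] = (1.0, 99.0)
    seed: int = 0

    def thresholds(self) -> SegmentationThresholds:
        return SegmentationThresholds(t_collagen=self.t_collagen,
                                      t_other=self.t_other,
                                      t_background=self.t_background)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = {}
        for f_ in dataclasses.fields(cls):
            if f_.name in raw:
                v = raw[f_.name]
                kwargs[f_.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class AnalysisResult:
    """Everything :func:`analyze_scan` computes for one scan."""

    table: ResultTable
    alpha: np.ndarray
    region: np.ndarray
    theta_collagen: np.ndarray
    theta_muscle: np.ndarray


def analyze_scan(scan: ReducedScan, config: PipelineConfig | None = None,
                 ) -> AnalysisResult:
    """Run segmentation, orientation and peak analyses on every point."""
    config = config or PipelineConfig()
    scan = normalize_scan(scan)
    ny, nx = scan.shape
    expmap = compute_intensity_exponent(scan, config.exponent_window)
    th = config.thresholds()
    # sixth-order fallback is only consulted where the exponent rule did
    # not already decide collagen/background; restricting the (expensive)
    # per-point fit to those points changes nothing in the labels
    need_sixth = (np.isfinite(expmap.alpha)
                  & (expmap.alpha < th.t_collagen)
                  & (scan.transmission < th.t_background))
    sixth = detect_sixth_order_masked(scan, need_sixth, config)
    region = segment_regions(expmap, sixth, scan.transmission, th)

    theta_col = np.full((ny, nx), np.nan)
    theta_mus = np.full((ny, nx), np.nan)
    rows = []
    q = scan.grid.q_centers
    for i in range(ny):
        for j in range(nx):
            lab = region.label[i, j]
            rec: dict = {"row": i, "col": j, "region": REGION_NAMES[lab],
                         "alpha": expmap.alpha[i, j],
                         "transmission": scan.transmission[i, j]}
            point = scan.intensity[i, j]
            if lab == REGION_COLLAGEN:
                try:
                    az = band_profile(point, q, config.collagen_band)
                    o = fit_azimuthal_orientation(az, scan.grid.phi_centers,
                                                  config.collagen_band)
                except ValueError:
                    o = None
                if o is not None and o.valid:
                    rec.update(col_a_sym=o.a_sym, col_a_asym=o.a_asym,
                               col_theta_s=o.theta_s, col_degree=o.degree)
                    theta_col[i, j] = o.theta_s
                    theta_fit = o.theta_s if np.isfinite(o.theta_s) else 0.0
                    c = analyze_collagen_point(
                        point, theta_fit, scan.grid,
                        orders=config.collagen_orders,
                        d_nominal=config.d_nominal,
                        snr_min=config.snr_min,
                        overlap_reference=config.overlap_reference)
                    rec.update(D5=c.D5, D6=c.D6, fwhm5=c.fwhm5, fwhm6=c.fwhm6,
                               i6_over_i5=c.i6_over_i5,
                               overlap_fraction=c.overlap_fraction)
            elif lab == REGION_MUSCLE:
                try:
                    az = band_profile(point, q, config.myofibril_band)
                    o = fit_azimuthal_orientation(az, scan.grid.phi_centers,
                                                  config.myofibril_band)
                except ValueError:
                    o = None
                if o is not None and o.valid:
                    rec.update(mus_a_sym=o.a_sym, mus_a_asym=o.a_asym,
                               mus_theta_s=o.theta_s, mus_degree=o.degree)
                    theta_mus[i, j] = o.theta_s
                    theta_fit = o.theta_s if np.isfinite(o.theta_s) else 0.0
                    m = analyze_muscle_point(point, theta_fit, scan.grid,
                                             config.window10, config.window11,
                                             snr_min=config.snr_min)
                    if m is not None:
                        rec.update(q10=m.q10, q11=m.q11, d10=m.d10, d11=m.d11,
                                   lattice_a=m.lattice_a, fwhm10=m.fwhm10,
                                   fwhm11=m.fwhm11,
                                   i11_over_i10=m.i11_over_i10)
            rows.append(rec)
    table = ResultTable(data=pd.DataFrame(rows))
    return AnalysisResult(table=table, alpha=expmap.alpha,
                          region=region.label, theta_collagen=theta_col,
                          theta_muscle=theta_mus)


def detect_sixth_order_masked(scan: ReducedScan, mask: np.ndarray,
                              config: PipelineConfig) -> np.ndarray:
    """Sixth-order detection restricted to masked points (False elsewhere)."""
    from .peakfit import fit_peak

    q6 = 2.0 * np.pi * 6.0 / config.d_nominal
    window = (q6 * 0.94, q6 * 1.06)
    prof = scan.azimuthal_mean()
    out = np.zeros(scan.shape, dtype=bool)
    for i, j in zip(*np.nonzero(mask)):
        fit = fit_peak(scan.grid.q_centers, prof[i, j], window, order=6,
                       snr_min=config.snr_min)
        out[i, j] = fit.visible
    return out


def run_pipeline(scan_path: str | os.PathLike, out_dir: str | os.PathLike,
                 config: PipelineConfig | str | os.PathLike | None = None,
                 ) -> AnalysisResult:
    """Analyze one scan file and write the deterministic artifact set.

    Outputs under ``out_dir``: ``results.csv`` (per-point table),
    ``region_map.png``, ``orientation_*.png``, ratio maps, a summary CSV
    and ``config.yaml`` + ``log.json`` recording the configuration hash
    and package version.
    """
    from .render import (render_orientation_map, render_region_map,
                         render_value_map, save_png)

    if config is None:
        config = PipelineConfig()
        log.info("no config given; using documented defaults")
    elif not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    os.makedirs(out_dir, exist_ok=True)
    scan = read_scan(scan_path)
    result = analyze_scan(scan, config)

    write_result_table(result.table, os.path.join(out_dir, "results.csv"))
    config.to_yaml(os.path.join(out_dir, "config.yaml"))
    save_png(render_region_map(result.region),
             os.path.join(out_dir, "region_map.png"))
    df = result.table.data
    ny, nx = scan.shape
    for band, prefix in (("col", "collagen"), ("mus", "muscle")):
        theta = np.full((ny, nx), np.nan)
        asym = np.zeros((ny, nx))
        amean = np.zeros((ny, nx))
        sub = df.dropna(subset=[f"{band}_theta_s"])
        theta[sub["row"].astype(int), sub["col"].astype(int)] = sub[f"{band}_theta_s"]
        asym[sub["row"].astype(int), sub["col"].astype(int)] = sub[f"{band}_a_asym"]
        amean[sub["row"].astype(int), sub["col"].astype(int)] = sub[f"{band}_a_sym"]
        save_png(render_orientation_map(theta, asym, amean, mode="hue-value",
                                        percentiles=config.render_percentiles),
                 os.path.join(out_dir, f"orientation_{prefix}.png"))
    for colname, fname in (("i6_over_i5", "i6_over_i5.png"),
                           ("overlap_fraction", "overlap_fraction.png"),
                           ("i11_over_i10", "i11_over_i10.png")):
        vals = np.full((ny, nx), np.nan)
        sub = df.dropna(subset=[colname])
        if len(sub):
            vals[sub["row"].astype(int), sub["col"].astype(int)] = sub[colname]
        save_png(render_value_map(vals, percentiles=config.render_percentiles),
                 os.path.join(out_dir, fname))

    summary = summarize_table(result.table)
    summary.to_csv(os.path.join(out_dir, "summary.csv"), index=False)
    with open(os.path.join(out_dir, "log.json"), "w") as f:
        json.dump({"config_hash": config.config_hash(),
                   "scansaxs_version": __version__,
                   "scan": str(scan_path), "n_points": int(ny * nx)}, f, indent=1)
    return result


def summarize_table(table: ResultTable) -> pd.DataFrame:
    """Distribution summaries per parameter over the relevant region."""
    rows = []
    df = table.data
    for p in COMPARISON_PARAMETERS:
        vals = df[p].dropna().to_numpy()
        if vals.size == 0:
            continue
        s = summarize(vals)
        rows.append({"parameter": p, "n": s.n, "median": s.median,
                     "q1": s.q1, "q3": s.q3, "whisker_lo": s.whisker_lo,
                     "whisker_hi": s.whisker_hi, "n_outliers": s.n_outliers})
    return pd.DataFrame(rows)


def compare_samples(tables: dict[str, ResultTable], reference: str,
                    parameters: list[str] | None = None) -> pd.DataFrame:
    """Compare each sample against a declared reference, per parameter.

    Returns one row per (sample, parameter) with the rank-sum test result
    and the percent change of medians; every number is recomputable from
    the per-point tables alone.  Parameters absent from either sample are
    skipped with a note row.
    """
    if reference not in tables:
        raise ValueError(f"reference sample {reference!r} not among inputs")
    if len(tables) < 2:
        raise ValueError("need at least two samples to compare")
    parameters = parameters or COMPARISON_PARAMETERS
    ref_df = tables[reference].data
    rows = []
    for name, tab in tables.items():
        if name == reference:
            continue
        for p in parameters:
            a = tab.data[p].dropna().to_numpy() if p in tab.data else np.array([])
            b = ref_df[p].dropna().to_numpy() if p in ref_df else np.array([])
            if a.size < 2 or b.size < 2:
                rows.append({"sample": name, "reference": reference,
                             "parameter": p, "note": "skipped: insufficient data"})
                continue
            cmp = compare_distributions(a, b)
            rows.append({
                "sample": name, "reference": reference, "parameter": p,
                "n": cmp.n_a, "n_ref": cmp.n_b,
                "median": float(np.median(a)), "median_ref": float(np.median(b)),
                "percent_change": percent_change(float(np.median(a)),
                                                 float(np.median(b))),
                "U": cmp.statistic, "p_value": cmp.p_value, "stars": cmp.stars,
                "note": "",
            })
    return pd.DataFrame(rows)
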