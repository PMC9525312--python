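"""Localization post-processing: 2D Gaussian fitting, astigmatism
calibration, z lookup with the refractive-index rescale, and the
sigma band-pass filter.

File I/O speaks the ThunderSTORM CSV dialect (frame numbers 1-based on
disk, 0-based in memory; conversion happens only at the I/O boundary).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "GaussianFitError",
    "ZCalibration",
    "fit_gaussian2d",
    "calibrate_astigmatism",
    "lookup_z",
    "add_z",
    "bandpass_filter",
    "read_thunderstorm",
    "write_thunderstorm",
    "read_calibration",
    "write_calibration",
]

THUNDERSTORM_COLUMNS = ["frame", "x [nm]", "y [nm]", "sigma1 [nm]",
                        "sigma2 [nm]", "intensity [photon]"]
_INTERNAL = ["frame", "x", "y", "sigma1", "sigma2", "intensity"]


class GaussianFitError(RuntimeError):
    """Raised when an ROI cannot be fitted with an elliptical Gaussian."""


def _gauss2d(coords, amp, x0, y0, sx, sy, bg):
    x, y = coords
    return bg + amp * np.exp(-((x - x0) ** 2 / (2 * sx**2)
                               + (y - y0) ** 2 / (2 * sy**2)))


def fit_gaussian2d(roi: np.ndarray, px_size: float = 1.0):
    """Least-squares elliptical-Gaussian fit of a small image patch.

    Parameters
    ----------
    roi : 2D array, at least 4x4, finite values.
    px_size : nm per pixel; centers are returned in pixels, widths in
        pixels * px_size (so pass the camera pixel size to get nm).

    Returns
    -------
    dict with x, y (px, sub-pixel), sigma1, sigma2 (px * px_size, with
    sigma1 >= sigma2), intensity (integrated above background), background.

    Raises
    ------
    GaussianFitError on flat/degenerate patches or non-convergence.
    """
    roi = np.asarray(roi, dtype=float)
    if roi.ndim != 2 or min(roi.shape) < 4:
        raise GaussianFitError("patch must be 2D and at least 4x4")
    if not np.all(np.isfinite(roi)):
        raise GaussianFitError("patch contains non-finite values")
    rng_val = roi.max() - roi.min()
    if rng_val <= 1e-12 * max(1.0, abs(roi.max())):
        raise GaussianFitError("flat patch: no spot to fit")

    h, w = roi.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    bg0 = roi.min()
    net = roi - bg0
    tot = net.sum()
    x0 = float((net * xx).sum() / tot)
    y0 = float((net * yy).sum() / tot)
    sx0 = max(0.8, math_sqrt((net * (xx - x0) ** 2).sum() / tot))
    sy0 = max(0.8, math_sqrt((net * (yy - y0) ** 2).sum() / tot))
    p0 = [net.max(), x0, y0, sx0, sy0, bg0]
    bounds = ([0, -1, -1, 0.3, 0.3, -np.inf],
              [np.inf, w, h, 5 * w, 5 * h, np.inf])
    try:
        popt, _ = curve_fit(_gauss2d, (xx.ravel(), yy.ravel()), roi.ravel(),
                            p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise GaussianFitError(f"fit did not converge: {exc}") from exc
    amp, xc, yc, sx, sy, bg = popt
    s1, s2 = max(sx, sy) * px_size, min(sx, sy) * px_size
    return {"x": xc, "y": yc, "sigma1": s1, "sigma2": s2,
            "intensity": 2 * np.pi * amp * sx * sy, "background": bg}


def math_sqrt(v):
    return float(np.sqrt(max(v, 0.0)))


@dataclass
class ZCalibration:
    """Smooth sigma1(z)/sigma2(z) calibration with unique-lookup guarantee.

    sigma1(z) - sigma2(z) must be strictly monotone over the calibrated
    range; `rescale_factor` (default 0.75) corrects the refractive-index
    mismatch between the bead calibration path and the aqueous sample.
    """

    z_nodes: np.ndarray
    s1_nodes: np.ndarray
    s2_nodes: np.ndarray
    rescale_factor: float = 0.75
    _grid_n: int = 2001

    def __post_init__(self):
        order = np.argsort(self.z_nodes)
        self.z_nodes = np.asarray(self.z_nodes, float)[order]
        self.s1_nodes = np.asarray(self.s1_nodes, float)[order]
        self.s2_nodes = np.asarray(self.s2_nodes, float)[order]
        self._s1 = CubicSpline(self.z_nodes, self.s1_nodes)
        self._s2 = CubicSpline(self.z_nodes, self.s2_nodes)
        zg = np.linspace(self.z_nodes[0], self.z_nodes[-1], self._grid_n)
        diff = self._s1(zg) - self._s2(zg)
        d = np.diff(diff)
        span = diff[-1] - diff[0]
        # strictly monotone up to a small numerical tolerance near the
        # range edges (uniqueness of the lookup)
        tol = 1e-4 * abs(span)
        if span == 0 or not (np.all(d > -tol) or np.all(d < tol)):
            raise ValueError("sigma1 - sigma2 is not strictly monotone: "
                             "ambiguous z lookup")
        self._zg = zg
        self._rt_s1 = np.sqrt(np.clip(self._s1(zg), 0, None))
        self._rt_s2 = np.sqrt(np.clip(self._s2(zg), 0, None))

    def sigma1(self, z):
        return self._s1(z)

    def sigma2(self, z):
        return self._s2(z)

    @property
    def z_range(self):
        return float(self.z_nodes[0]), float(self.z_nodes[-1])


def calibrate_astigmatism(bead_table: pd.DataFrame,
                          rescale_factor: float = 0.75) -> ZCalibration:
    """Build a ZCalibration from a bead z-stack width table.

    The table needs columns z, sigma1, sigma2 and at least 7 z planes.
    Widths are represented by interpolating cubic splines; an error is
    raised if sigma1 - sigma2 is not strictly monotone (which would make
    the z lookup ambiguous).
    """
    for col in ("z", "sigma1", "sigma2"):
        if col not in bead_table.columns:
            raise ValueError(f"bead table missing column {col!r}")
    if len(bead_table) < 7:
        raise ValueError("need at least 7 z planes to calibrate")
    z = bead_table["z"].to_numpy(dtype=float)
    s1 = bead_table["sigma1"].to_numpy(dtype=float)
    s2 = bead_table["sigma2"].to_numpy(dtype=float)
    try:
        return ZCalibration(z, s1, s2, rescale_factor=rescale_factor)
    except ValueError:
        # width noise can make the interpolant wiggle; retry with light
        # spline smoothing before declaring the table ambiguous
        s1s, s2s = (_smooth_widths(z, s) for s in (s1, s2))
        return ZCalibration(z, s1s, s2s, rescale_factor=rescale_factor)


def _smooth_widths(z, sigma):
    from scipy.interpolate import UnivariateSpline

    order = np.argsort(z)
    resid = sigma[order] - np.polyval(np.polyfit(z[order], sigma[order], 4),
                                      z[order])
    spl = UnivariateSpline(z[order], sigma[order], k=3,
                           s=len(z) * float(np.mean(resid**2)))
    return spl(z)


def lookup_z(sigma1, sigma2, calib: ZCalibration, envelope_tol: float = 0.25):
    """Look up z from astigmatic widths.

    z* minimizes (sqrt(s1_obs) - sqrt(s1_cal(z)))^2 +
    (sqrt(s2_obs) - sqrt(s2_cal(z)))^2 over the calibrated range; the
    result is multiplied by the calibration's rescale factor (0.75 by
    default) to correct the refractive-index mismatch.

    Localizations whose widths fall outside the calibrated envelope by
    more than `envelope_tol` (relative) come back as NaN.

    Accepts scalars or arrays; returns matching shape.
    """
    s1 = np.atleast_1d(np.asarray(sigma1, dtype=float))
    s2 = np.atleast_1d(np.asarray(sigma2, dtype=float))
    rt1 = np.sqrt(np.clip(s1, 0, None))[:, None]
    rt2 = np.sqrt(np.clip(s2, 0, None))[:, None]
    dist = (rt1 - calib._rt_s1[None, :]) ** 2 + (rt2 - calib._rt_s2[None, :]) ** 2
    k = np.argmin(dist, axis=1)
    zg = calib._zg
    # parabolic refinement around the grid minimum
    z_raw = zg[k].astype(float)
    interior = (k > 0) & (k < zg.size - 1)
    if interior.any():
        ki = k[interior]
        rows = np.flatnonzero(interior)
        d0 = dist[rows, ki - 1]
        d1 = dist[rows, ki]
        d2 = dist[rows, ki + 1]
        denom = d0 - 2 * d1 + d2
        shift = np.where(np.abs(denom) > 1e-300,
                         0.5 * (d0 - d2) / np.where(denom == 0, 1, denom), 0.0)
        shift = np.clip(shift, -1.0, 1.0)
        z_raw[interior] = zg[ki] + shift * (zg[1] - zg[0])

    # envelope check: both widths must be near the calibration curves
    c1 = calib.sigma1(z_raw)
    c2 = calib.sigma2(z_raw)
    bad = ((np.abs(s1 - c1) > envelope_tol * c1)
           | (np.abs(s2 - c2) > envelope_tol * c2))
    z_out = z_raw * calib.rescale_factor
    z_out[bad] = np.nan
    if np.isscalar(sigma1) or np.asarray(sigma1).ndim == 0:
        return float(z_out[0])
    return z_out


def add_z(locs: pd.DataFrame, calib: ZCalibration,
          drop: bool = True) -> pd.DataFrame:
    """Attach a z column (nm) to a localization table via lookup_z.

    Rows whose widths fall outside the calibrated envelope are dropped
    (with a logged count) when drop=True, else kept with z = NaN.
    """
    out = locs.copy()
    out["z"] = lookup_z(out["sigma1"].to_numpy(), out["sigma2"].to_numpy(), calib)
    n_bad = int(out["z"].isna().sum())
    if n_bad:
        logger.info("lookup_z: dropped %d/%d localizations outside the "
                    "calibrated envelope", n_bad, len(out))
        if drop:
            out = out.dropna(subset=["z"]).reset_index(drop=True)
    return out


def bandpass_filter(locs: pd.DataFrame, lo: float = 60.0,
                    hi: float = 300.0) -> pd.DataFrame:
    """Keep localizations with lo <= sigma1 <= hi and lo <= sigma2 <= hi.

    Bounds are inclusive. Removes single-pixel noise (narrow widths) and
    out-of-focus molecules (wide widths).
    """
    keep = ((locs["sigma1"] >= lo) & (locs["sigma1"] <= hi)
            & (locs["sigma2"] >= lo) & (locs["sigma2"] <= hi))
    return locs.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------- I/O --

def write_thunderstorm(locs: pd.DataFrame, path) -> None:
    """Write a localization table as ThunderSTORM-dialect CSV (1-based frames)."""
    out = pd.DataFrame({
        "frame": locs["frame"].to_numpy() + 1,
        "x [nm]": locs["x"], "y [nm]": locs["y"],
        "sigma1 [nm]": locs["sigma1"], "sigma2 [nm]": locs["sigma2"],
        "intensity [photon]": locs["intensity"],
    })
    out.to_csv(path, index=False)


def read_thunderstorm(path) -> pd.DataFrame:
    """Read a ThunderSTORM-dialect CSV into the internal 0-based table."""
    raw = pd.read_csv(path)
    missing = [c for c in THUNDERSTORM_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"not a ThunderSTORM table, missing {missing}")
    out = pd.DataFrame({
        "frame": raw["frame"].astype(int) - 1,
        "x": raw["x [nm]"], "y": raw["y [nm]"],
        "sigma1": raw["sigma1 [nm]"], "sigma2": raw["sigma2 [nm]"],
        "intensity": raw["intensity [photon]"],
    })
    return out


def write_calibration(calib: ZCalibration, csv_path, json_path=None) -> None:
    """Store calibration as (z, sigma1, sigma2) CSV + JSON sidecar."""
    pd.DataFrame({"z": calib.z_nodes, "sigma1": calib.s1_nodes,
                  "sigma2": calib.s2_nodes}).to_csv(csv_path, index=False)
    side = Path(json_path) if json_path else Path(csv_path).with_suffix(".json")
    side.write_text(json.dumps({"rescale_factor": calib.rescale_factor}))


def read_calibration(csv_path, json_path=None) -> ZCalibration:
    tab = pd.read_csv(csv_path)
    side = Path(json_path) if json_path else Path(csv_path).with_suffix(".json")
    rescale = 0.75
    if side.exists():
        rescale = float(json.loads(side.read_text()).get("rescale_factor", 0.75))
    return calibrate_astigmatism(tab, rescale_factor=rescale)
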