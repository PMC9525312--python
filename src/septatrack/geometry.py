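"""Cell-geometry fitting and cylindrical trajectory unwrapping.

A dividing rod-shaped cell is modeled as a cylinder; a molecule moving
on its surface at midcell travels along the circumference, so its true
displacement is underestimated by the in-plane chord. Unwrapping maps
each 3D localization to (s, l): arc length along the circumference and
position along the cell's long axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CellGeometry", "fit_cell_geometry", "unwrap_track",
           "UnwrappedTrack"]


@dataclass
class CellGeometry:
    """Cylinder model of the cell: a point on the axis, the unit axis
    direction, the radius, and the axial position of the septum (all nm;
    axial positions are measured along axis_direction from axis_point)."""

    axis_point: np.ndarray
    axis_direction: np.ndarray
    radius: float
    septum_axial_pos: float

    def __post_init__(self):
        self.axis_point = np.asarray(self.axis_point, dtype=float)
        a = np.asarray(self.axis_direction, dtype=float)
        n = np.linalg.norm(a)
        if abs(n - 1.0) > 1e-9:
            a = a / n
        self.axis_direction = a
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass
class UnwrappedTrack:
    """1D decomposition of a septal trajectory.

    data columns: t (s), s (circumferential arc length, nm), l (axial,
    nm), radial_residual (distance from the fitted surface, nm).
    """

    track_id: int
    data: pd.DataFrame

    def __len__(self):
        return len(self.data)


def _ortho_basis(a: np.ndarray):
    """Right-handed in-plane basis (e1, e2) with e1 x e2 = a."""
    ref = np.zeros(3)
    ref[np.argmin(np.abs(a))] = 1.0
    e1 = ref - (ref @ a) * a
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    return e1, e2


def fit_cell_geometry(locs_or_geometry, septum: str | float = "density",
                      min_locs: int = 20) -> CellGeometry:
    """Fit a cylinder to a 3D localization cloud.

    If a CellGeometry is passed it is returned unchanged (explicit
    geometry from config). Otherwise `locs_or_geometry` must be a table
    with x, y, z columns: the axis is the principal direction of the
    cloud, the radius comes from an algebraic (Kasa) circle fit of the
    cross-sectional projection, and the septum sits at the axial density
    maximum (or at an explicit axial position passed via `septum`).

    Raises on degenerate clouds (too few points, or collinear in the
    cross-sectional plane) with advice to supply explicit geometry.
    """
    if isinstance(locs_or_geometry, CellGeometry):
        return locs_or_geometry
    locs = locs_or_geometry
    pts = np.column_stack([locs["x"], locs["y"], locs["z"]]).astype(float)
    if len(pts) < min_locs:
        raise ValueError(f"need at least {min_locs} localizations to fit "
                         "geometry; supply explicit CellGeometry instead")
    center = pts.mean(axis=0)
    u, sv, vt = np.linalg.svd(pts - center, full_matrices=False)
    a = vt[0]
    if a[np.argmax(np.abs(a))] < 0:  # deterministic orientation
        a = -a
    e1, e2 = _ortho_basis(a)
    rel = pts - center
    p = rel @ e1
    q = rel @ e2
    if np.std(p) < 1e-9 or np.std(q) < 1e-9:
        raise ValueError("cross-sectional cloud is collinear; supply "
                         "explicit CellGeometry")
    # Kasa algebraic circle fit: minimize ||A [a b c] - (p^2+q^2)||
    A = np.column_stack([2 * p, 2 * q, np.ones_like(p)])
    b = p**2 + q**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    pc, qc, c = sol
    radius = float(np.sqrt(max(c + pc**2 + qc**2, 1e-12)))

    # refine the PCA axis by nonlinear least squares on the radial
    # residuals (the principal direction alone carries an O(1/sqrt(n))
    # finite-sample tilt)
    from scipy.optimize import least_squares as _lsq

    def _resid(par):
        al, be, c1, c2, r = par
        ax = a + al * e1 + be * e2
        ax = ax / np.linalg.norm(ax)
        f1, f2 = _ortho_basis(ax)
        pp = rel @ f1
        qq = rel @ f2
        return np.hypot(pp - c1, qq - c2) - r

    fit = _lsq(_resid, [0.0, 0.0, pc, qc, radius], xtol=1e-14, ftol=1e-14)
    al, be, pc, qc, radius = fit.x
    a = a + al * e1 + be * e2
    a = a / np.linalg.norm(a)
    if a[np.argmax(np.abs(a))] < 0:
        a = -a
    e1, e2 = _ortho_basis(a)
    radius = float(abs(radius))
    axis_point = center + pc * e1 + qc * e2

    l = (pts - axis_point) @ a
    if septum == "density":
        nbins = max(10, int((l.max() - l.min()) / 100.0))
        hist, edges = np.histogram(l, bins=nbins)
        k = int(np.argmax(hist))
        septum_l = float(0.5 * (edges[k] + edges[k + 1]))
    else:
        septum_l = float(septum)
    return CellGeometry(axis_point=axis_point, axis_direction=a,
                        radius=radius, septum_axial_pos=septum_l)


def unwrap_track(track, geom: CellGeometry, frame_interval: float = 1.0,
                 min_radial_frac: float = 0.2) -> UnwrappedTrack:
    """Unwrap a 3D trajectory onto the cylinder surface.

    Each localization is projected onto the plane perpendicular to the
    cell axis; its angle theta about the axis (right-handed, fixed
    reference direction per cell) is computed from the radial vector —
    equivalently, the point is radially re-projected onto the fitted
    surface, so z noise is constrained to the tangent direction. Per-step
    angle increments are wrapped into (-pi, pi] (unambiguous for <=300
    nm/s at 1 frame/s on r >= 300 nm) and accumulated:

        s = radius * unwrap(theta),  l = axial coordinate.

    Localizations closer to the axis than min_radial_frac * radius are
    dropped (the angle is ill-defined there). The distance from the
    fitted surface is kept per point as radial_residual for QC.
    """
    data = track.data if hasattr(track, "data") else track
    track_id = getattr(track, "track_id", -1)
    cols = ["x", "y", "z"]
    pts = np.column_stack([data[c] for c in cols]).astype(float)
    frames = data["frame"].to_numpy()
    a = geom.axis_direction
    e1, e2 = _ortho_basis(a)
    rel = pts - geom.axis_point
    l = rel @ a
    p = rel @ e1
    q = rel @ e2
    rad = np.hypot(p, q)
    keep = rad >= min_radial_frac * geom.radius
    if not keep.all():
        frames, l, p, q, rad = (arr[keep] for arr in (frames, l, p, q, rad))
    theta = np.arctan2(q, p)
    dtheta = np.mod(np.diff(theta) + np.pi, 2 * np.pi) - np.pi
    # map boundary value -pi -> +pi so increments live in (-pi, pi]
    dtheta[dtheta == -np.pi] = np.pi
    theta_unwrapped = np.concatenate([[theta[0] if theta.size else 0.0],
                                      theta[:1] + np.cumsum(dtheta)]) \
        if theta.size else np.array([])
    s = geom.radius * theta_unwrapped
    t = frames * frame_interval
    out = pd.DataFrame({"t": t, "s": s, "l": l,
                        "radial_residual": rad - geom.radius})
    return UnwrappedTrack(track_id=track_id, data=out)
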