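"""Synthetic-data generator for septal single-molecule experiments.

Emulates the full observation chain of a septal single-molecule tracking
(SMT) experiment on a rod-shaped bacterium: molecules live on the surface
of a cylindrical cell, move along the circumference (processive) or stay
put (stationary), are observed through an astigmatic 3D localization
channel with Gaussian localization error, blinking and finite detection
probability, and are only visible on the bottom half of the cylinder
(the focal plane sits ~250 nm above the coverslip).

Also generates bead calibration z-stacks, circumferential ring profiles,
torus-shaped ring localization clouds, FRAP intensity traces and small
diffraction-limited cluster movies, so that every downstream analysis
stage can be tested against known ground truth.

Coordinate convention: the cell axis runs along x at height z = radius;
z is measured from the coverslip (bottom of the cell), theta from the
bottom of the cylinder (theta = 0 at z = 0), positive right-handed about
+x so that y = r sin(theta), z = r (1 - cos(theta)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "AstigmatismModel",
    "SimParams",
    "simulate_septal_molecules",
    "simulate_bead_stack",
    "simulate_ring_localizations",
    "simulate_torus_localizations",
    "simulate_frap_trace",
    "simulate_cluster_movie",
    "simulate_segment_set",
    "simulate_cylinder_cloud",
]

# Default log-normal speed parameters: chosen so the component means are
# ~9.4 nm/s (slow, sPG-track) and ~30 nm/s (fast, Z-track treadmilling)
# with a modest log-spread; mean = exp(u + sigma^2 / 2).
_SLOW_SIGMA = 0.30
_FAST_SIGMA = 0.30
SLOW_LOGPARAMS = (math.log(9.4) - _SLOW_SIGMA**2 / 2, _SLOW_SIGMA)
FAST_LOGPARAMS = (math.log(30.0) - _FAST_SIGMA**2 / 2, _FAST_SIGMA)


@dataclass(frozen=True)
class AstigmatismModel:
    """Quadratic-defocus model of the astigmatic PSF widths.

    sigma1(z) = sigma0 * sqrt(1 + ((z + offset) / depth)^2)
    sigma2(z) = sigma0 * sqrt(1 + ((z - offset) / depth)^2)

    The two curves cross at z = 0 (the focus) and sigma1 - sigma2 is
    strictly increasing in z, which guarantees a unique z lookup.
    Units: nm.
    """

    sigma0: float = 130.0
    offset: float = 250.0
    depth: float = 400.0

    def sigma1(self, z):
        z = np.asarray(z, dtype=float)
        return self.sigma0 * np.sqrt(1.0 + ((z + self.offset) / self.depth) ** 2)

    def sigma2(self, z):
        z = np.asarray(z, dtype=float)
        return self.sigma0 * np.sqrt(1.0 + ((z - self.offset) / self.depth) ** 2)


@dataclass
class SimParams:
    """Parameters of the septal SMT simulation.

    Defaults mirror the experimental acquisition (1 frame/s, 150 frames)
    and the measured population structure: ~55% stationary segments with
    a ~27 s mean dwell, processive molecules with log-normal speeds with
    mean ~9.4 nm/s and ~15 s mean runs; a fast ~30 nm/s population is
    available but off by default.
    """

    radius: float = 400.0                       # nm
    cell_length: float = 3000.0                 # nm
    septum_axial_pos: float = 1500.0            # nm
    n_molecules: int = 4     # sparse labeling: ~<=1 emitter visible at a time
    population_fractions: tuple = (0.55, 0.45, 0.0)  # stationary, slow, fast
    slow_speed_logparams: tuple = SLOW_LOGPARAMS     # (u, sigma), nm/s
    fast_speed_logparams: tuple = FAST_LOGPARAMS
    stationary_dwell_mean: float = 27.0         # s
    run_time_mean: float = 15.0                 # s
    loc_noise_xy: float = 30.0                  # nm
    loc_noise_z: float = 50.0                   # nm
    frame_interval: float = 1.0                 # s
    n_frames: int = 150
    blink_off_mean: float = 2.0                 # frames
    detection_prob: float = 0.8
    n_polar_molecules: int = 0                  # stationary molecules at the poles
    septum_axial_jitter: float = 30.0           # nm, molecule-to-molecule spread
    focal_plane_z: float = 250.0                # nm above the coverslip
    z_rescale: float = 0.75                     # refractive-index mismatch factor
    psf: AstigmatismModel = field(default_factory=AstigmatismModel)
    seed: int = 0

    def validate(self) -> None:
        fr = np.asarray(self.population_fractions, dtype=float)
        if fr.size != 3 or abs(fr.sum() - 1.0) > 1e-12:
            raise ValueError("population_fractions must be 3 values summing to 1")
        if np.any(fr < 0) or np.any(fr > 1):
            raise ValueError("population_fractions must lie in [0, 1]")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        for name in ("cell_length", "frame_interval", "stationary_dwell_mean",
                     "run_time_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_molecules <= 0:
            raise ValueError("n_molecules must be positive")
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ValueError("detection_prob must lie in [0, 1]")


_POP_NAMES = np.array(["stationary", "slow", "fast"])


def _blink_mask(rng, n, detection_prob, off_mean):
    """On/off emission telegraph with geometric off-gaps.

    Off-gap lengths are geometric with mean `off_mean` frames; on-run
    lengths are geometric with a mean chosen so the long-run duty cycle
    equals `detection_prob`.
    """
    if detection_prob >= 1.0 or off_mean <= 0:
        return np.ones(n, dtype=bool)
    on_mean = off_mean * detection_prob / (1.0 - detection_prob)
    p_off = min(1.0, 1.0 / max(on_mean, 1e-9))
    p_on = min(1.0, 1.0 / off_mean)
    mask = np.empty(n, dtype=bool)
    state = rng.random() < detection_prob
    for i in range(n):
        mask[i] = state
        if state:
            if rng.random() < p_off:
                state = False
        else:
            if rng.random() < p_on:
                state = True
    return mask


def simulate_septal_molecules(params: SimParams):
    """Simulate septal molecules and their observed localizations.

    Returns
    -------
    truth : DataFrame
        One row per molecule per live frame: molecule, frame, population,
        theta (continuous, rad), s (true arc, nm), l (axial, nm),
        on (emitting), visible (bottom half), detected.
    locs : DataFrame
        Observed localization table with columns frame (0-based), x, y
        (camera plane, nm), sigma1, sigma2 (nm), intensity, and the
        ground-truth molecule id for bookkeeping.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    r = params.radius
    dt = params.frame_interval

    truth_rows = []
    loc_rows = []

    n_total = params.n_molecules + params.n_polar_molecules
    for mol in range(n_total):
        polar = mol >= params.n_molecules
        if polar:
            pop = 0
            l0 = rng.choice([0.06, 0.94]) * params.cell_length
        else:
            pop = rng.choice(3, p=np.asarray(params.population_fractions, float))
            l0 = params.septum_axial_pos + rng.normal(0.0, params.septum_axial_jitter)

        if pop == 0:
            duration_s = rng.exponential(params.stationary_dwell_mean)
            speed = 0.0
        else:
            duration_s = rng.exponential(params.run_time_mean)
            u, sg = (params.slow_speed_logparams if pop == 1
                     else params.fast_speed_logparams)
            speed = float(rng.lognormal(u, sg))
        direction = 1.0 if rng.random() < 0.5 else -1.0
        omega = direction * speed / r                    # rad / s

        n_live = max(2, int(math.ceil(duration_s / dt)))
        start = int(rng.integers(0, params.n_frames))
        frames = np.arange(start, min(start + n_live, params.n_frames))
        if frames.size == 0:
            continue
        tloc = (frames - frames[0]) * dt
        theta0 = rng.uniform(-math.pi, math.pi)
        theta = theta0 + omega * tloc                    # continuous, unwrapped
        s_true = r * (theta - theta0)
        l = np.full(frames.size, l0)

        on = _blink_mask(rng, frames.size, params.detection_prob,
                         params.blink_off_mean)
        theta_w = np.angle(np.exp(1j * theta))           # wrapped to (-pi, pi]
        visible = np.abs(theta_w) <= math.pi / 2
        detected = on & visible

        y3 = r * np.sin(theta_w)
        z3 = r - r * np.cos(theta_w)

        for k in range(frames.size):
            truth_rows.append((mol, int(frames[k]), _POP_NAMES[pop], theta[k],
                               s_true[k], l[k], bool(on[k]), bool(visible[k]),
                               bool(detected[k])))
        if not detected.any():
            continue
        idx = np.flatnonzero(detected)
        x_obs = l[idx] + rng.normal(0.0, params.loc_noise_xy, idx.size)
        y_obs = y3[idx] + rng.normal(0.0, params.loc_noise_xy, idx.size)
        z_noisy = z3[idx] + rng.normal(0.0, params.loc_noise_z, idx.size)
        # The index mismatch makes the apparent defocus larger than the
        # true one by 1/z_rescale; widths are drawn at the calibration z.
        defocus = (z_noisy - params.focal_plane_z) / params.z_rescale
        s1 = params.psf.sigma1(defocus)
        s2 = params.psf.sigma2(defocus)
        inten = rng.lognormal(math.log(1000.0), 0.3, idx.size)
        for j, k in enumerate(idx):
            loc_rows.append((int(frames[k]), x_obs[j], y_obs[j],
                             s1[j], s2[j], inten[j], mol))

    truth = pd.DataFrame(truth_rows, columns=[
        "molecule", "frame", "population", "theta", "s", "l",
        "on", "visible", "detected"])
    locs = pd.DataFrame(loc_rows, columns=[
        "frame", "x", "y", "sigma1", "sigma2", "intensity", "molecule"])
    locs = locs.sort_values(["frame", "x"], kind="mergesort").reset_index(drop=True)
    return truth, locs


def simulate_bead_stack(z_range=(-600.0, 600.0), step=25.0,
                        sigma_model: AstigmatismModel | None = None,
                        noise: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Bead z-stack width table (z, sigma1, sigma2) for calibration.

    Beads are imaged in the index-matched glass/oil path, so widths are
    evaluated at the true stage z (no rescale enters here).
    """
    lo, hi = z_range
    if not hi > lo:
        raise ValueError("z_range must span a non-empty interval")
    if step <= 0:
        raise ValueError("step must be positive")
    model = sigma_model or AstigmatismModel()
    z = np.arange(lo, hi + step / 2, step)
    if z.size == 0:
        raise ValueError("empty z range")
    s1 = model.sigma1(z)
    s2 = model.sigma2(z)
    if noise > 0:
        rng = np.random.default_rng(seed)
        s1 = s1 + rng.normal(0.0, noise, z.size)
        s2 = s2 + rng.normal(0.0, noise, z.size)
    return pd.DataFrame({"z": z, "sigma1": s1, "sigma2": s2})


def simulate_ring_localizations(n_molecules: int, n_bins: int = 72,
                                clustering: str = "homogeneous",
                                n_clusters: int = 3,
                                cluster_kappa: float = 20.0,
                                diameter: float = 600.0,
                                seed: int = 0):
    """Circumferential ring profile: molecule counts per angular bin.

    clustering='homogeneous' draws angles uniformly; 'clustered'
    concentrates molecules in a few von Mises patches (contiguous arcs).
    Returns a ringstats.RingProfile.
    """
    from .ringstats import RingProfile

    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    rng = np.random.default_rng(seed)
    if clustering == "homogeneous":
        ang = rng.uniform(0.0, 2 * math.pi, n_molecules)
    elif clustering == "clustered":
        centers = rng.uniform(0.0, 2 * math.pi, n_clusters)
        which = rng.integers(0, n_clusters, n_molecules)
        ang = np.mod(rng.vonmises(centers[which], cluster_kappa), 2 * math.pi)
    else:
        raise ValueError(f"unknown clustering mode: {clustering!r}")
    counts, _ = np.histogram(ang, bins=n_bins, range=(0.0, 2 * math.pi))
    bin_size = math.pi * diameter / n_bins
    return RingProfile(z=counts.astype(float), bin_size=bin_size,
                       diameter=diameter)


def simulate_torus_localizations(n: int, diameter: float = 600.0,
                                 width_fwhm: float = 100.0,
                                 thickness_fwhm: float = 60.0,
                                 blur_xy: float = 0.0, blur_z: float = 0.0,
                                 seed: int = 0) -> np.ndarray:
    """3D localizations of a toroidal ring lying in the y-z plane.

    Returns an (n, 3) array of (axial, y, z) positions in nm. width_fwhm
    is the axial (along-cell) extent, thickness_fwhm the radial extent;
    blur_xy / blur_z add measurement blur in quadrature.
    """
    rng = np.random.default_rng(seed)
    f2s = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    phi = rng.uniform(0.0, 2 * math.pi, n)
    rad = diameter / 2.0 + rng.normal(0.0, thickness_fwhm * f2s, n)
    axial = rng.normal(0.0, width_fwhm * f2s, n)
    y = rad * np.cos(phi)
    z = rad * np.sin(phi)
    if blur_xy > 0:
        axial = axial + rng.normal(0.0, blur_xy * f2s, n)
        y = y + rng.normal(0.0, blur_xy * f2s, n)
    if blur_z > 0:
        z = z + rng.normal(0.0, blur_z * f2s, n)
    return np.column_stack([axial, y, z])


def simulate_frap_trace(tau_fast: float = 2.9, tau_slow: float = 54.0,
                        immobile_fraction: float = 0.3, noise: float = 0.01,
                        n_seconds: float = 150.0, frame_interval: float = 1.0,
                        fast_fraction: float = 0.5,
                        global_bleach_loss: float = 0.10, seed: int = 0):
    """Half-ring FRAP trace with two recovery phases and global bleaching.

    The bleached-side signal recovers as
    F(t) = plateau - a_f exp(-t ln2/tau_fast) - a_s exp(-t ln2/tau_slow),
    plateau = 1 - immobile_fraction, a_f + a_s = plateau (so F(0) = 0).
    All three channels (bleached, opposite, outside-septum reference) are
    multiplied by an exponential global-photobleaching envelope that loses
    `global_bleach_loss` of the signal over the acquisition.
    Returns a frap.FRAPTrace.
    """
    from .frap import FRAPTrace

    if tau_fast <= 0 or tau_slow <= 0:
        raise ValueError("recovery time constants must be positive")
    if not 0.0 <= immobile_fraction <= 1.0:
        raise ValueError("immobile_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, n_seconds + frame_interval / 2, frame_interval)
    plateau = 1.0 - immobile_fraction
    a_f = fast_fraction * plateau
    a_s = plateau - a_f
    recovery = (plateau
                - a_f * np.exp(-t * math.log(2.0) / tau_fast)
                - a_s * np.exp(-t * math.log(2.0) / tau_slow))
    if global_bleach_loss > 0:
        k = -math.log(1.0 - global_bleach_loss) / max(t[-1], 1e-9)
    else:
        k = 0.0
    env = np.exp(-k * t)
    bleached = recovery * env
    opposite = 1.0 * env
    outside = 1.0 * env
    if noise > 0:
        bleached = bleached + rng.normal(0.0, noise, t.size)
        opposite = opposite + rng.normal(0.0, noise, t.size)
        outside = outside + rng.normal(0.0, noise / 4, t.size)
    return FRAPTrace(time=t, bleached=bleached, opposite=opposite,
                     outside=outside)


def simulate_cluster_movie(speed: float, frames: int = 60, px_size: float = 100.0,
                           psf_sigma: float = 130.0, frame_interval: float = 1.0,
                           shape=(24, 48), amplitude: float = 1000.0,
                           background: float = 100.0, noise: float = 0.0,
                           stationary_spot: bool = False,
                           seed: int = 0) -> np.ndarray:
    """Movie of a diffraction-limited spot translating along +x (columns).

    Returns a float array of shape (frames, H, W); pixel size in nm.
    Write to disk with `write_movie`.
    """
    if px_size <= 0:
        raise ValueError("px_size must be positive")
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    total_disp_px = speed * frame_interval * (frames - 1) / px_size
    x0 = (w - 1) / 2.0 - total_disp_px / 2.0
    y0 = (h - 1) / 2.0
    sig_px = psf_sigma / px_size
    movie = np.empty((frames, h, w), dtype=float)
    for f in range(frames):
        xc = x0 + speed * frame_interval * f / px_size
        img = background + amplitude * np.exp(
            -(((xx - xc) ** 2) + ((yy - y0) ** 2)) / (2.0 * sig_px**2))
        if stationary_spot:
            img = img + amplitude * np.exp(
                -(((xx - w * 0.2) ** 2) + ((yy - y0) ** 2)) / (2.0 * sig_px**2))
        if noise > 0:
            img = img + rng.normal(0.0, noise, img.shape)
        movie[f] = img
    return movie


def write_movie(movie: np.ndarray, path) -> None:
    """Write a (frames, H, W) movie as a multi-page TIFF."""
    import tifffile

    tifffile.imwrite(path, movie.astype(np.float32))


def read_movie(path) -> np.ndarray:
    import tifffile

    return np.asarray(tifffile.imread(path), dtype=float)


def simulate_segment_set(n_segments: int, fractions=(0.55, 0.45),
                         speed_logparams=SLOW_LOGPARAMS, sigma_loc: float = 30.0,
                         dwell_mean: float = 27.0, run_mean: float = 15.0,
                         min_len: int = 6, frame_interval: float = 1.0,
                         seed: int = 0):
    """Draw isolated 1D segments for classifier benchmarking.

    Each segment is either stationary (constant position + localization
    noise, exponential dwell with mean `dwell_mean`) or processive (line
    at a log-normal speed, exponential run with mean `run_mean`), with
    durations truncated to at least `min_len` frames.

    Returns a list of (t, s, true_label) tuples.
    """
    rng = np.random.default_rng(seed)
    fr = np.asarray(fractions, dtype=float)
    if abs(fr.sum() - 1.0) > 1e-12:
        raise ValueError("fractions must sum to 1")
    out = []
    for _ in range(n_segments):
        stationary = rng.random() < fr[0]
        mean = dwell_mean if stationary else run_mean
        # exponential duration, truncated to >= min_len frames
        n = 0
        while n < min_len:
            n = int(math.ceil(rng.exponential(mean) / frame_interval)) + 1
        t = np.arange(n) * frame_interval
        if stationary:
            s = rng.normal(0.0, sigma_loc, n)
            label = "stationary"
        else:
            v = rng.lognormal(*speed_logparams) * (1 if rng.random() < 0.5 else -1)
            s = v * t + rng.normal(0.0, sigma_loc, n)
            label = "processive"
        out.append((t, s, label))
    return out


def simulate_cylinder_cloud(n: int = 500, params: SimParams | None = None,
                            noise: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Points spread over the visible bottom-half cylinder surface.

    Used to exercise the cell-geometry fit; returns x, y, z columns (nm)
    in the same camera frame as simulate_septal_molecules (z measured
    from the coverslip).
    """
    p = params or SimParams()
    rng = np.random.default_rng(seed)
    theta = rng.uniform(-math.pi / 2, math.pi / 2, n)
    l = rng.uniform(0.0, p.cell_length, n)
    x = l
    y = p.radius * np.sin(theta)
    z = p.radius - p.radius * np.cos(theta)
    if noise > 0:
        x = x + rng.normal(0.0, noise, n)
        y = y + rng.normal(0.0, noise, n)
        z = z + rng.normal(0.0, noise, n)
    return pd.DataFrame({"x": x, "y": y, "z": z})
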