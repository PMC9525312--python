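"""Trajectory segmentation and stationary/processive classification.

An unwrapped 1D trajectory s(t) is split into piecewise-linear segments
by recursive BIC-penalized binary splitting; each segment is fitted with
a line and summarized by two statistics:

* R = stdev(fit residuals) / |net displacement of the fitted line| —
  small R means the displacement dominates the noise, i.e. the motion
  looks directional. (Defined in this orientation so that the printed
  threshold "R <= 0.4 -> processive" is self-consistent.)
* P = the probability of processive movement, estimated by a seeded
  residual-permutation test: the fraction of surrogate segments —
  zero-slope model plus permuted residuals — whose absolute net
  displacement is smaller than the observed one.

A segment is processive iff R <= 0.4 and P >= 0.5 (inclusive); segments
shorter than 6 points are left unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Segment", "segment_track", "segment_stats", "classify_segment",
           "analyze_track", "population_summary"]

R_MAX_DEFAULT = 0.4
P_MIN_DEFAULT = 0.5
MIN_SEGMENT_LEN = 6


@dataclass
class Segment:
    """A classified stretch of an unwrapped trajectory."""

    track_id: int
    start: int            # index range within the unwrapped track
    stop: int             # exclusive
    n_frames: int
    v: float              # fitted slope, nm/s (signed)
    R: float
    P: float
    label: str            # stationary | processive | unclassified
    duration: float       # s, (n_frames - 1) * frame interval
    run_length: float     # |v| * duration, nm

    @property
    def speed(self) -> float:
        return abs(self.v)


def _line_rss(t: np.ndarray, s: np.ndarray) -> float:
    tm = t - t.mean()
    denom = (tm**2).sum()
    slope = (tm @ s) / denom if denom > 0 else 0.0
    resid = s - s.mean() - slope * tm
    return float((resid**2).sum())


def segment_track(utrack, min_len: int = MIN_SEGMENT_LEN,
                  rss_floor: float = 1e-12) -> list[tuple[int, int]]:
    """Recursive binary changepoint splitting of s(t).

    At each level every interior breakpoint leaving at least `min_len`
    points on both sides is tested; the split minimizing the total
    piecewise-linear RSS is accepted if it lowers the BIC relative to a
    single line (Gaussian-residual BIC, 3 extra parameters for the added
    line and breakpoint), then both halves are recursed into.

    Returns half-open index ranges covering the whole track. A track
    shorter than min_len comes back as one (unclassifiable) range.
    """
    data = utrack.data if hasattr(utrack, "data") else utrack
    t = np.asarray(data["t"], dtype=float)
    s = np.asarray(data["s"], dtype=float)
    n = t.size
    if n < min_len:
        return [(0, n)]

    def bic(rss, m, k):
        return m * np.log(max(rss, rss_floor) / m) + k * np.log(m)

    def recurse(i0, i1):
        m = i1 - i0
        if m < 2 * min_len:
            return [(i0, i1)]
        tt, ss = t[i0:i1], s[i0:i1]
        rss1 = _line_rss(tt, ss)
        best = None
        for b in range(min_len, m - min_len + 1):
            rss2 = _line_rss(tt[:b], ss[:b]) + _line_rss(tt[b:], ss[b:])
            if best is None or rss2 < best[1]:
                best = (b, rss2)
        b, rss2 = best
        if bic(rss2, m, 5) < bic(rss1, m, 2):
            return recurse(i0, i0 + b) + recurse(i0 + b, i1)
        return [(i0, i1)]

    return recurse(0, n)


def segment_stats(s, t, B: int = 200, seed: int = 0, rng=None):
    """Line fit plus the R and P statistics of one segment.

    Fits s = v t + b by least squares; the net displacement is the fitted
    line's rise over the segment, Delta = v (t_end - t_start).
    R = stdev(residuals) / |Delta|; P is the fraction of B residual-
    permutation surrogates (built around the zero-slope mean model) whose
    |net displacement| is smaller than |Delta|.

    Returns (v, R, P). Delta == 0 exactly gives R = inf, P = 0
    (stationary by construction). Deterministic given the seed.
    """
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    if s.size < MIN_SEGMENT_LEN:
        raise ValueError(f"segment needs at least {MIN_SEGMENT_LEN} points")
    if rng is None:
        rng = np.random.default_rng(seed)
    tm = t - t.mean()
    denom = float((tm**2).sum())
    v = float((tm @ s) / denom)
    resid = s - s.mean() - v * tm
    span = t[-1] - t[0]
    delta = v * span
    # |Delta| below any physical displacement (numerical zero) counts as
    # exactly zero: stationary by construction
    if abs(delta) < 1e-9:
        return 0.0, np.inf, 0.0
    r_stat = float(np.std(resid) / abs(delta))

    # surrogates: permute the residuals about the stationary (mean) model
    r0 = s - s.mean()
    perms = np.tile(r0, (B, 1))
    perms = rng.permuted(perms, axis=1)
    slopes = perms @ tm / denom
    p_stat = float(np.mean(np.abs(slopes * span) < abs(delta)))
    return v, r_stat, p_stat


def classify_segment(stats, r_max: float = R_MAX_DEFAULT,
                     p_min: float = P_MIN_DEFAULT) -> str:
    """Processive iff R <= r_max and P >= p_min (inclusive thresholds)."""
    _, r_stat, p_stat = stats
    return "processive" if (r_stat <= r_max and p_stat >= p_min) else "stationary"


def analyze_track(utrack, min_len: int = MIN_SEGMENT_LEN, B: int = 200,
                  seed: int = 0, r_max: float = R_MAX_DEFAULT,
                  p_min: float = P_MIN_DEFAULT,
                  breakpoints=None) -> list[Segment]:
    """Segment, fit and classify one unwrapped trajectory.

    `breakpoints` may supply manual index ranges (list of (start, stop))
    to bypass the automatic changepoint search.
    """
    data = utrack.data if hasattr(utrack, "data") else utrack
    track_id = getattr(utrack, "track_id", -1)
    t = np.asarray(data["t"], dtype=float)
    s = np.asarray(data["s"], dtype=float)
    ranges = breakpoints if breakpoints is not None else \
        segment_track(utrack, min_len=min_len)
    rng = np.random.default_rng(seed)
    out = []
    for (i0, i1) in ranges:
        n = i1 - i0
        if n < min_len:
            out.append(Segment(track_id, i0, i1, n, np.nan, np.nan, np.nan,
                               "unclassified", t[i1 - 1] - t[i0] if n else 0.0,
                               np.nan))
            continue
        v, r_stat, p_stat = segment_stats(s[i0:i1], t[i0:i1], B=B, rng=rng)
        label = classify_segment((v, r_stat, p_stat), r_max=r_max, p_min=p_min)
        duration = float(t[i1 - 1] - t[i0])
        out.append(Segment(track_id, i0, i1, n, v, r_stat, p_stat, label,
                           duration, abs(v) * duration))
    return out


def population_summary(segments: list[Segment]) -> dict:
    """Population-level statistics over classified segments.

    Percentages are over classified (stationary + processive) segments;
    speeds are |v| of processive segments; dwell times are stationary
    segment durations; run times/lengths come from processive segments.
    """
    stat = [g for g in segments if g.label == "stationary"]
    proc = [g for g in segments if g.label == "processive"]
    n = len(stat) + len(proc)
    if n == 0:
        return {"n_segments": 0, "pct_stationary": np.nan,
                "pct_processive": np.nan, "speeds": [], "dwell_times": [],
                "run_times": [], "run_lengths": []}
    return {
        "n_segments": n,
        "pct_stationary": 100.0 * len(stat) / n,
        "pct_processive": 100.0 * len(proc) / n,
        "speeds": [g.speed for g in proc],
        "dwell_times": [g.duration for g in stat],
        "run_times": [g.duration for g in proc],
        "run_lengths": [g.run_length for g in proc],
    }
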