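"""Trajectory assembly by nearest-neighbor linking with gap closing.

Linking follows the classic single-particle-tracking recipe: per frame
transition, candidate (track, localization) pairs within the distance
threshold are accepted greedily in order of increasing distance; a track
stays alive for up to `max_gap` dark frames (blinking or defocus) and a
reappearing molecule must lie within the same distance threshold of its
last known position, regardless of gap length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Track",
    "link_localizations",
    "implied_motion_limits",
    "select_septal_tracks",
    "tracks_to_frame",
    "write_tracks",
    "read_tracks",
]


@dataclass
class Track:
    """A linked trajectory: rows of the source localization table."""

    track_id: int
    data: pd.DataFrame  # columns: frame, x, y [, z, ...]; frames strictly increasing

    def __len__(self):
        return len(self.data)

    @property
    def start_frame(self) -> int:
        return int(self.data["frame"].iloc[0])

    @property
    def end_frame(self) -> int:
        return int(self.data["frame"].iloc[-1])


def link_localizations(locs: pd.DataFrame, max_disp: float = 300.0,
                       max_gap: int = 8, coords=("x", "y")) -> list[Track]:
    """Greedy global-nearest-neighbor linking.

    Parameters
    ----------
    locs : localization table, will be processed in frame order.
    max_disp : distance threshold (nm) per frame transition; a molecule
        reappearing after a gap must still be within this distance of its
        last position (the radius is not scaled with gap length).
    max_gap : maximum number of dark frames bridged (8 by default);
        consecutive linked frames may differ by at most max_gap + 1.
    coords : position columns used for the distance (xy by default).

    Returns a partition of the input: every localization belongs to
    exactly one track (singletons allowed). Candidate links are accepted
    in order of increasing distance with deterministic tie-breaking by
    (track last frame, localization order within frame).
    """
    locs = locs.sort_values("frame", kind="mergesort").reset_index(drop=True)
    pos = locs.loc[:, list(coords)].to_numpy(dtype=float)
    frames = locs["frame"].to_numpy()

    track_of = np.full(len(locs), -1, dtype=int)
    # active track state: (last_row_index, last_frame)
    last_row: list[int] = []
    last_frame: list[int] = []
    track_ids: list[int] = []
    next_id = 0

    for f in np.unique(frames):
        rows = np.flatnonzero(frames == f)
        if not last_row:
            for r in rows:
                last_row.append(r); last_frame.append(int(f)); track_ids.append(next_id)
                track_of[r] = next_id; next_id += 1
            continue
        lf = np.asarray(last_frame)
        active = np.flatnonzero((f - lf) <= max_gap + 1)
        cands = []
        if active.size and rows.size:
            apos = pos[np.asarray(last_row)[active]]
            d = np.sqrt(((apos[:, None, :] - pos[rows][None, :, :]) ** 2).sum(-1))
            ai, li = np.nonzero(d <= max_disp)
            for a, j in zip(ai, li):
                cands.append((d[a, j], lf[active[a]], j, active[a]))
        cands.sort()
        used_tracks = set()
        used_locs = set()
        for dist, _, j, a in cands:
            if a in used_tracks or j in used_locs:
                continue
            used_tracks.add(a); used_locs.add(j)
            r = rows[j]
            track_of[r] = track_ids[a]
            last_row[a] = r
            last_frame[a] = int(f)
        for j, r in enumerate(rows):
            if j not in used_locs:
                last_row.append(r); last_frame.append(int(f)); track_ids.append(next_id)
                track_of[r] = next_id; next_id += 1

    tracks = []
    for tid in range(next_id):
        sub = locs.loc[track_of == tid]
        tracks.append(Track(track_id=tid, data=sub.reset_index(drop=True)))
    return tracks


def implied_motion_limits(max_disp: float, frame_interval: float,
                          msd_denominator: float = 4.0):
    """Motion limits implied by the linking distance threshold.

    max_speed = max_disp / frame_interval (nm/s) is unambiguous. The
    implied maximum diffusion coefficient depends on the MSD convention;
    we report max_D = max_disp^2 / (msd_denominator * frame_interval) in
    um^2/s with the 2D convention (denominator 4) by default.
    """
    if max_disp <= 0 or frame_interval <= 0:
        raise ValueError("max_disp and frame_interval must be positive")
    max_speed = max_disp / frame_interval
    max_d = max_disp**2 / (msd_denominator * frame_interval) * 1e-6  # nm^2->um^2
    return max_speed, max_d


def select_septal_tracks(tracks: list[Track], geometry,
                         axial_window: float = 200.0) -> list[Track]:
    """Keep tracks whose mean axial position lies near the septal plane.

    `geometry` is a geometry.CellGeometry; the axial coordinate of each
    track's mean position is compared with the septum position and the
    track is retained when |l_mean - l_septum| <= axial_window (nm).
    """
    kept = []
    a = np.asarray(geometry.axis_direction, dtype=float)
    p0 = np.asarray(geometry.axis_point, dtype=float)
    for tr in tracks:
        cols = ["x", "y", "z"] if "z" in tr.data.columns else ["x", "y"]
        mean = tr.data[cols].mean().to_numpy()
        if len(cols) == 2:
            mean = np.append(mean, p0[2])
        l_mean = float((mean - p0) @ a)
        if abs(l_mean - geometry.septum_axial_pos) <= axial_window:
            kept.append(tr)
    return kept


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Concatenate tracks into one table with a track_id column."""
    if not tracks:
        return pd.DataFrame(columns=["track_id", "frame", "x", "y"])
    parts = []
    for tr in tracks:
        d = tr.data.copy()
        d.insert(0, "track_id", tr.track_id)
        parts.append(d)
    return pd.concat(parts, ignore_index=True)


def write_tracks(tracks: list[Track], path) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False)


def read_tracks(path) -> list[Track]:
    tab = pd.read_csv(path)
    return [Track(track_id=int(tid), data=sub.drop(columns="track_id")
                  .reset_index(drop=True))
            for tid, sub in tab.groupby("track_id", sort=True)]
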