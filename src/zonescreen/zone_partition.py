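"""Slicing drives into per-event-zone subintervals.

A drive's frames are projected onto the route centreline to obtain an
arc-length coordinate per frame; the frames falling between a zone's entry
and exit waypoints (half-open, first traversal only) form that zone's
*subinterval* — the unit later compared by dynamic time warping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .replay_model import DriveRecording
from .synthetic_sim import Environment, EventZone

__all__ = [
    "SUBINTERVAL_CHANNELS",
    "Subinterval",
    "OffRouteWarning",
    "route_progress",
    "extract_subintervals",
    "write_subinterval_csvs",
    "read_subinterval_csvs",
]

#: Channel order used for clustering.
SUBINTERVAL_CHANNELS = ("lane_offset", "throttle", "brake", "steering")


class OffRouteWarning(UserWarning):
    """A frame lies farther from the route than the corridor tolerance."""


@dataclass
class Subinterval:
    """One drive's traversal of one event zone.

    ``channels`` has shape (n_frames, 4) with columns
    :data:`SUBINTERVAL_CHANNELS`; ``timestamps`` are the frame times in
    seconds, strictly increasing.
    """

    zone_id: int
    drive_id: str
    channels: np.ndarray
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[1] != len(SUBINTERVAL_CHANNELS):
            raise ValueError("channels must have shape (n_frames, 4)")
        if len(self.channels) < 2:
            raise ValueError("subinterval needs at least 2 frames")
        if not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.channels)


def project_to_polyline(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Arc length of the nearest point on ``poly`` for each query point.

    Brute-force-equivalent: candidate segments come from a KD-tree over the
    polyline vertices (the nearest vertex bounds the nearest segment to one
    of its incident segments plus immediate neighbours, given vertices far
    denser than the query's distance to the route).
    """
    seg_vec = np.diff(poly, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    cum_s = np.concatenate([[0.0], np.cumsum(seg_len)])
    tree = cKDTree(poly)
    _, vidx = tree.query(points, k=1)
    n_seg = len(seg_vec)
    # candidate segments: the two incident to the nearest vertex plus one
    # neighbour on each side, evaluated in a vectorised block
    offsets = np.array([-2, -1, 0, 1])
    cand = np.clip(vidx[:, None] + offsets[None, :], 0, n_seg - 1)
    p0 = poly[cand]                       # (n, 4, 2)
    d = seg_vec[cand]                     # (n, 4, 2)
    L2 = (seg_len[cand] ** 2)
    rel = points[:, None, :] - p0
    with np.errstate(invalid="ignore", divide="ignore"):
        tpar = np.einsum("nkc,nkc->nk", rel, d) / L2
    tpar = np.clip(np.nan_to_num(tpar), 0.0, 1.0)
    q = p0 + tpar[..., None] * d
    d2 = np.sum((points[:, None, :] - q) ** 2, axis=2)
    best = np.argmin(d2, axis=1)
    rows = np.arange(len(points))
    return cum_s[cand[rows, best]] + tpar[rows, best] * seg_len[cand[rows, best]]


def route_progress(
    env: Environment,
    rec: DriveRecording,
    corridor_tol: float = 8.0,
) -> np.ndarray:
    """Per-frame arc length along the route centreline, clamped monotone.

    Frames farther than ``corridor_tol`` metres from the route trigger an
    off-route warning but are retained with their nearest-point projection.
    Brief reversals are clamped so the returned progress never decreases.
    """
    pts = np.column_stack([rec.channel("x"), rec.channel("y")])
    s = project_to_polyline(pts, env.centerline)
    proj, _ = env.point_at(s)
    dist = np.linalg.norm(pts - proj, axis=1)
    n_off = int(np.sum(dist > corridor_tol))
    if n_off:
        warnings.warn(
            f"{rec.drive_id}: {n_off} frame(s) beyond {corridor_tol} m corridor",
            OffRouteWarning, stacklevel=2)
    s = np.minimum(s, env.route_length)
    return np.maximum.accumulate(s)


def extract_subintervals(
    rec: DriveRecording,
    env: Environment,
    progress: np.ndarray | None = None,
) -> list[Subinterval]:
    """One subinterval per zone the drive traverses with >= 2 frames.

    Membership is half-open, entry <= s < exit, so a frame on a shared
    boundary belongs to exactly one zone.  Because progress is monotone,
    only the first traversal can exist; zones the drive never reaches (or
    crosses within a single frame) are simply absent from the output.
    """
    s = route_progress(env, rec) if progress is None else np.asarray(progress)
    frames = rec.frames
    chans = frames.loc[:, list(SUBINTERVAL_CHANNELS)].to_numpy(dtype=float)
    t = frames["t"].to_numpy(dtype=float)
    out: list[Subinterval] = []
    for zone in env.zones:
        i0 = int(np.searchsorted(s, zone.entry.s, side="left"))
        i1 = int(np.searchsorted(s, zone.exit.s, side="left"))
        if i1 - i0 < 2:
            continue
        out.append(Subinterval(
            zone_id=zone.zone_id,
            drive_id=rec.drive_id,
            channels=chans[i0:i1],
            timestamps=t[i0:i1],
        ))
    return out


# ---------------------------------------------------------------------------
# Long-format CSV I/O (one file per zone)

def write_subinterval_csvs(
    subs_by_zone: dict[int, list[Subinterval]], out_dir: str | Path
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for zone_id, subs in sorted(subs_by_zone.items()):
        rows = []
        for sub in subs:
            for k in range(len(sub)):
                rows.append((sub.drive_id, k, *sub.channels[k], sub.timestamps[k]))
        df = pd.DataFrame(rows, columns=["drive_id", "frame_idx",
                                         *SUBINTERVAL_CHANNELS, "t"])
        df.to_csv(out_dir / f"zone_{zone_id:04d}.csv", index=False)


def read_subinterval_csvs(in_dir: str | Path) -> dict[int, list[Subinterval]]:
    out: dict[int, list[Subinterval]] = {}
    for path in sorted(Path(in_dir).glob("zone_*.csv")):
        zone_id = int(path.stem.split("_")[1])
        df = pd.read_csv(path)
        subs = []
        for drive_id, grp in df.groupby("drive_id", sort=True):
            grp = grp.sort_values("frame_idx")
            subs.append(Subinterval(
                zone_id=zone_id,
                drive_id=str(drive_id),
                channels=grp[list(SUBINTERVAL_CHANNELS)].to_numpy(dtype=float),
                timestamps=grp["t"].to_numpy(dtype=float),
            ))
        out[zone_id] = subs
    return out
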