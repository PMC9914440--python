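"""Link frame-stamped localizations into trajectories; crossing-track removal.

Linking is deterministic frame-to-frame optimal assignment: for each frame
pair the total squared displacement over all matches is minimized (Hungarian
algorithm), jumps above ``max_jump`` are forbidden, and a track may bridge up
to ``max_gap`` missing frames. Tracks that approach each other closer than a
crossing radius in a common frame cannot be disambiguated with QDs and are
removed in pairs before any metric is computed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .trajectories import Trajectory

#: default maximum frame-to-frame jump: 5·sqrt(4·D_max·Δt) with D_max = 1 µm²/s
DEFAULT_MAX_JUMP_UM = 5.0 * np.sqrt(4.0 * 1.0 * 0.030)
DEFAULT_MAX_GAP = 3
#: default crossing radius (µm); the acquisition gives no value, exposed in config
DEFAULT_CROSSING_RADIUS_UM = 0.5

_BIG = 1e12


def link(
    locs: pd.DataFrame,
    max_jump: float = DEFAULT_MAX_JUMP_UM,
    max_gap: int = DEFAULT_MAX_GAP,
    frame_interval: float = 0.030,
) -> list[Trajectory]:
    """Link a localization table (columns frame, x, y in µm) into tracks.

    Every input localization ends up in exactly one track; detections that
    cannot be matched within ``max_jump`` start new tracks. Ties between
    identical costs are broken by input order (stable row order).
    """
    if max_jump <= 0:
        raise ValueError("max_jump must be > 0")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if locs.empty:
        return []

    locs = locs.sort_values("frame", kind="stable").reset_index(drop=True)
    tracks: list[dict] = []  # {'frames': [...], 'xy': [...], 'last_f', 'last_xy'}

    for f, grp in locs.groupby("frame", sort=True):
        pts = grp[["x", "y"]].to_numpy(dtype=float)
        active = [
            k for k, t in enumerate(tracks) if 0 < f - t["last_f"] <= max_gap + 1
        ]
        assigned = np.full(len(pts), -1)
        if active:
            prev = np.array([tracks[k]["last_xy"] for k in active])
            d2 = ((prev[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
            cost = np.where(d2 <= max_jump**2, d2, _BIG)
            # pad to square so unmatched rows/cols are allowed
            n_r, n_c = cost.shape
            size = max(n_r, n_c)
            pad = np.full((size, size), _BIG)
            pad[:n_r, :n_c] = cost
            rows, cols = linear_sum_assignment(pad)
            for r, c in zip(rows, cols):
                if r < n_r and c < n_c and pad[r, c] < _BIG:
                    assigned[c] = active[r]
        for j, pt in enumerate(pts):
            if assigned[j] >= 0:
                t = tracks[assigned[j]]
            else:
                t = {"frames": [], "xy": []}
                tracks.append(t)
            t["frames"].append(int(f))
            t["xy"].append(pt)
            t["last_f"] = int(f)
            t["last_xy"] = pt

    out = []
    pid = 0
    for t in tracks:
        if len(t["frames"]) < 2:
            # singleton tracks carry no displacement information; counted
            # separately by link_with_singletons so totals reconcile
            continue
        out.append(
            Trajectory(
                particle_id=pid,
                frames=np.asarray(t["frames"]),
                xy=np.asarray(t["xy"]),
                frame_interval=frame_interval,
            )
        )
        pid += 1
    return out


def link_with_singletons(
    locs: pd.DataFrame,
    max_jump: float = DEFAULT_MAX_JUMP_UM,
    max_gap: int = DEFAULT_MAX_GAP,
    frame_interval: float = 0.030,
) -> tuple[list[Trajectory], int]:
    """Like :func:`link` but also report how many localizations stayed
    unlinked (singleton tracks), so counts reconcile with the input."""
    trajs = link(locs, max_jump, max_gap, frame_interval)
    n_linked = sum(len(t) for t in trajs)
    return trajs, len(locs) - n_linked


def remove_crossing_tracks(
    trajs: list[Trajectory], crossing_radius: float = DEFAULT_CROSSING_RADIUS_UM
) -> tuple[list[Trajectory], list[Trajectory]]:
    """Remove every pair of trajectories that come within ``crossing_radius``
    of each other in at least one common frame. Returns (kept, removed)."""
    if crossing_radius <= 0:
        raise ValueError("crossing_radius must be > 0")
    flagged = set()
    for i in range(len(trajs)):
        for j in range(i + 1, len(trajs)):
            a, b = trajs[i], trajs[j]
            common, ia, ib = np.intersect1d(
                a.frames, b.frames, assume_unique=True, return_indices=True
            )
            if common.size == 0:
                continue
            d2 = ((a.xy[ia] - b.xy[ib]) ** 2).sum(axis=1)
            if np.any(d2 < crossing_radius**2):
                flagged.add(i)
                flagged.add(j)
    kept = [t for k, t in enumerate(trajs) if k not in flagged]
    removed = [t for k, t in enumerate(trajs) if k in flagged]
    return kept, removed
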