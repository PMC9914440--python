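"""Per-trajectory diffusion metrics and compartment classification.

The mean squared displacement of a trajectory of N positions at lag n·τ is

    MSD(nτ) = (1/(N−n)) · Σ_{i=1..N−n} [(x_{i+n}−x_i)² + (y_{i+n}−y_i)²]

for n = 1..N−1; for tracks with blinking gaps, pairs spanning missing frames
are skipped and the divisor is the number of valid pairs. The diffusion
coefficient comes from an ordinary least-squares fit of the first four MSD
points (origin excluded) to MSD(nτ) = 4·D·nτ + b, where the intercept b
reflects the localization accuracy (b ≈ 4σ² for static noise). The explored
area is the MSD read out at fixed lags (0.42 s and 0.45 s by default, lag
indices 14 and 15 at τ = 30 ms) — a confinement proxy. Dwell time at
synapses is total in-zone time divided by the number of exits; dwell times
below five frames are discarded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .trajectories import Trajectory

logger = logging.getLogger(__name__)

#: camera pixel on the SPT setup; four pixels span the 760 nm inclusion distance
DEFAULT_PIXEL_SIZE_NM = 190.0
DEFAULT_INCLUSION_RADIUS_NM = 760.0
DEFAULT_EA_LAGS_S = (0.42, 0.45)
MIN_DWELL_FRAMES = 5

SYNAPTIC_LABELS = {
    "inhibitory": "inhibitory_synaptic",
    "excitatory": "excitatory_synaptic",
}


@dataclass
class MSDCurve:
    """Per-lag mean squared displacement of one trajectory (µm²)."""

    lag_index: np.ndarray
    lag_time: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    frame_interval: float

    def at_lag_index(self, n: int) -> float | None:
        hit = np.flatnonzero(self.lag_index == n)
        return float(self.msd[hit[0]]) if hit.size else None


@dataclass
class DiffusionEstimate:
    """4-point MSD line fit: D = slope/4 (µm²/s), intercept in µm²."""

    D: float
    intercept: float
    r_squared: float
    n_points_fit: int = 4


@dataclass
class DwellResult:
    total_synaptic_frames: int
    n_exits: int
    dwell_time: float
    censored: bool = False
    discarded: bool = False


def compute_msd(traj: Trajectory, max_lag: int | None = None) -> MSDCurve:
    """Time-averaged MSD of one trajectory, gap-aware and vectorized.

    Lags with zero valid pairs are omitted. ``max_lag`` (frames) limits the
    computation when only the fit region / EA lags are needed.
    """
    span = traj.n_span
    pos = np.full((span, 2), np.nan)
    pos[traj.frames - traj.frames[0]] = traj.xy
    top = span - 1 if max_lag is None else min(max_lag, span - 1)

    lags, msds, counts = [], [], []
    for n in range(1, top + 1):
        diff = pos[n:] - pos[:-n]
        sq = (diff**2).sum(axis=1)
        valid = ~np.isnan(sq)
        m = int(valid.sum())
        if m == 0:
            continue
        lags.append(n)
        msds.append(sq[valid].mean())
        counts.append(m)
    lags = np.asarray(lags, dtype=int)
    return MSDCurve(
        lag_index=lags,
        lag_time=lags * traj.frame_interval,
        msd=np.asarray(msds),
        n_pairs=np.asarray(counts, dtype=int),
        frame_interval=traj.frame_interval,
    )


def fit_diffusion(msd: MSDCurve) -> DiffusionEstimate | None:
    """OLS line through the first four MSD points (lags 1–4), no origin.

    Returns ``None`` when any of lags 1–4 is missing (short or gappy track);
    callers exclude such tracks and log the count. D or the intercept may be
    negative from noise; they are retained here and filtered downstream where
    log-scale statistics require positivity.
    """
    ys = [msd.at_lag_index(n) for n in range(1, 5)]
    if any(y is None for y in ys):
        return None
    x = np.arange(1, 5) * msd.frame_interval
    y = np.asarray(ys)
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DiffusionEstimate(D=float(slope) / 4.0, intercept=float(intercept), r_squared=r2)


def explored_area(
    msd: MSDCurve, lags_s: tuple[float, ...] = DEFAULT_EA_LAGS_S
) -> dict[float, float]:
    """MSD read out at the configured lag times (µm²).

    Each requested lag must be an integer multiple of τ; lags beyond the
    trajectory length are omitted with a warning.
    """
    out: dict[float, float] = {}
    for lag in lags_s:
        ratio = lag / msd.frame_interval
        n = int(round(ratio))
        if abs(ratio - n) > 1e-6:
            raise ValueError(
                f"lag {lag} s is not an integer multiple of tau={msd.frame_interval} s"
            )
        val = msd.at_lag_index(n)
        if val is None:
            warnings.warn(f"EA lag {lag} s beyond trajectory length; omitted")
            continue
        out[lag] = val
    return out


def _distance_map_nm(mask: np.ndarray, pixel_size_nm: float) -> np.ndarray:
    """Euclidean distance (nm) to the nearest mask pixel; 0 inside the mask."""
    if not mask.any():
        return np.full(mask.shape, np.inf)
    return ndimage.distance_transform_edt(~mask.astype(bool)) * pixel_size_nm


def _pixel_indices(traj: Trajectory, pixel_size_nm: float, shape) -> tuple[np.ndarray, np.ndarray]:
    # positions are µm, masks are rasterized with x → columns, y → rows,
    # pixel-center convention with 0-based indices
    cols = np.floor(traj.xy[:, 0] * 1000.0 / pixel_size_nm).astype(int)
    rows = np.floor(traj.xy[:, 1] * 1000.0 / pixel_size_nm).astype(int)
    if (
        rows.min() < 0
        or cols.min() < 0
        or rows.max() >= shape[0]
        or cols.max() >= shape[1]
    ):
        raise ValueError("trajectory leaves the mask image; coordinate frames mismatch")
    return rows, cols


def min_mask_distances_nm(
    traj: Trajectory, mask: np.ndarray, pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
) -> np.ndarray:
    """Per-localization distance (nm) to a binary mask."""
    dmap = _distance_map_nm(mask, pixel_size_nm)
    rows, cols = _pixel_indices(traj, pixel_size_nm, mask.shape)
    return dmap[rows, cols]


def classify_trajectory(
    traj: Trajectory,
    masks: dict[str, np.ndarray],
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    inclusion_radius_nm: float = DEFAULT_INCLUSION_RADIUS_NM,
    label_map: dict[str, str] | None = None,
    outside_label: str = "extrasynaptic",
) -> str:
    """Label a trajectory against a family of marker masks.

    A trajectory is assigned to a marker when at least one localization lies
    within ``inclusion_radius_nm`` of that marker's mask (distance 0 inside
    the mask); it is labeled ``outside_label`` when every localization is at
    least the inclusion radius away from all masks. If it qualifies for two
    markers, the one with the smaller minimal distance wins; an exact tie is
    ``unclassified``. Synaptic masks use the marker names ``inhibitory`` and
    ``excitatory``; a single ``endocytic`` mask with labels
    ``intra_EZ``/``extra_EZ`` follows the same geometry.
    """
    if label_map is None:
        label_map = SYNAPTIC_LABELS
    mins = {}
    for cls, mask in masks.items():
        d = min_mask_distances_nm(traj, mask, pixel_size_nm)
        mins[cls] = float(d.min())
    inside = {c: d for c, d in mins.items() if d < inclusion_radius_nm}
    if not inside:
        return outside_label
    best = min(inside.values())
    winners = [c for c, d in inside.items() if d == best]
    if len(winners) > 1:
        return "unclassified"
    return label_map.get(winners[0], winners[0])


def classify_endocytic(
    traj: Trajectory,
    ez_mask: np.ndarray,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    inclusion_radius_nm: float = DEFAULT_INCLUSION_RADIUS_NM,
) -> str:
    return classify_trajectory(
        traj,
        {"endocytic": ez_mask},
        pixel_size_nm,
        inclusion_radius_nm,
        label_map={"endocytic": "intra_EZ"},
        outside_label="extra_EZ",
    )


def dwell_time(
    traj: Trajectory,
    mask: np.ndarray,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    inclusion_radius_nm: float = DEFAULT_INCLUSION_RADIUS_NM,
) -> DwellResult:
    """Residence time inside the synaptic inclusion zone per exit event.

    ``dwell_time = total_in_frames · τ / n_exits``; with no exit observed the
    total in-time is reported with a censored flag. Dwell times below
    ``MIN_DWELL_FRAMES`` frames carry a discarded flag.
    """
    d = min_mask_distances_nm(traj, mask, pixel_size_nm)
    inside = d < inclusion_radius_nm
    return dwell_from_labels(inside, traj.frame_interval)


def dwell_from_labels(inside: np.ndarray, tau: float) -> DwellResult:
    """Dwell computation on a boolean in/out sequence (unit-testable core)."""
    inside = np.asarray(inside, dtype=bool)
    total = int(inside.sum())
    if total == 0:
        return DwellResult(0, 0, 0.0, censored=False, discarded=False)
    exits = int(np.sum(inside[:-1] & ~inside[1:]))
    if exits == 0:
        dt = total * tau
        return DwellResult(total, 0, dt, censored=True, discarded=dt < MIN_DWELL_FRAMES * tau)
    dt = total * tau / exits
    return DwellResult(total, exits, dt, censored=False, discarded=dt < MIN_DWELL_FRAMES * tau)


def trajectory_metrics_table(
    trajs: list[Trajectory],
    masks: dict[str, np.ndarray] | None = None,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    inclusion_radius_nm: float = DEFAULT_INCLUSION_RADIUS_NM,
    ea_lags_s: tuple[float, ...] = DEFAULT_EA_LAGS_S,
    metadata: dict | None = None,
    max_lag: int | None = None,
) -> pd.DataFrame:
    """Per-trajectory metric rows: D, intercept, EA per lag, compartment.

    ``metadata`` (e.g. condition/culture/neuron) is copied onto every row for
    the statistics layer.
    """
    if max_lag is None:
        max_lag = max(
            [4] + [int(round(l / trajs[0].frame_interval)) for l in ea_lags_s]
        ) if trajs else 4
    rows = []
    n_unfit = 0
    for t in trajs:
        msd = compute_msd(t, max_lag=max_lag)
        est = fit_diffusion(msd)
        if est is None:
            n_unfit += 1
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ea = explored_area(msd, ea_lags_s)
        row = {
            "track_id": t.particle_id,
            "n_locs": len(t),
            "D": est.D,
            "intercept": est.intercept,
            "r_squared": est.r_squared,
        }
        for lag in ea_lags_s:
            row[f"EA_{lag:g}"] = ea.get(lag, np.nan)
        if masks:
            row["compartment"] = classify_trajectory(
                t, masks, pixel_size_nm, inclusion_radius_nm
            )
        if metadata:
            row.update(metadata)
        rows.append(row)
    if n_unfit:
        logger.info("fit_diffusion unavailable for %d trajectories (excluded)", n_unfit)
    return pd.DataFrame(rows)


def mean_msd_curve(
    curves: list[MSDCurve], min_fraction: float = 0.8
) -> pd.DataFrame:
    """Lag-wise mean MSD over trajectories, keeping lags where at least
    ``min_fraction`` of the tracks are defined."""
    if not curves:
        return pd.DataFrame(columns=["lag_index", "lag_time", "mean_msd", "n_tracks"])
    need = int(np.ceil(min_fraction * len(curves)))
    acc: dict[int, list[float]] = {}
    for c in curves:
        for n, v in zip(c.lag_index, c.msd):
            acc.setdefault(int(n), []).append(float(v))
    tau = curves[0].frame_interval
    rows = [
        {"lag_index": n, "lag_time": n * tau, "mean_msd": float(np.mean(v)), "n_tracks": len(v)}
        for n, v in sorted(acc.items())
        if len(v) >= need
    ]
    return pd.DataFrame(rows)


def summarize_population(
    table: pd.DataFrame,
    group_cols: tuple[str, ...] = ("condition", "compartment"),
    ea_lags_s: tuple[float, ...] = DEFAULT_EA_LAGS_S,
) -> pd.DataFrame:
    """Per condition × compartment medians of D and EA plus QD counts.

    Each QD contributes one EA value per configured lag, so the EA sample
    size is (#QDs) × (#lags). Rows for empty cells are omitted.
    """
    ea_cols = [f"EA_{lag:g}" for lag in ea_lags_s if f"EA_{lag:g}" in table.columns]
    group_cols = tuple(c for c in group_cols if c in table.columns)
    rows = []
    grouped = table.groupby(list(group_cols)) if group_cols else [((), table)]
    for key, grp in grouped:
        if grp.empty:
            logger.info("empty population cell %r omitted", key)
            continue
        ea_values = grp[ea_cols].to_numpy().ravel() if ea_cols else np.array([])
        ea_values = ea_values[~np.isnan(ea_values)]
        row = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
        row.update(
            {
                "n_qds": len(grp),
                "median_D": float(grp["D"].median()),
                "median_EA": float(np.median(ea_values)) if ea_values.size else np.nan,
                "n_ea_values": int(ea_values.size),
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
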