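"""STORM post-processing: drift correction, detection merging, rendering,
density-based nanocluster segmentation.

Works on localization tables (frame, x_nm, y_nm) as produced by PSF-fitting
software; raw-movie fitting is out of scope. Drift is estimated from the
center of mass of a reference cluster over a 2000-frame sliding window;
repeated detections of one blinking fluorophore are merged when they fall
within 2σ in space and 15 s in time; rendered images are 20 nm-pixel
detection-count histograms; nanoclusters are connected components of the
thresholded rendering, characterized by area, detection count, and
detections-per-nm² density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

DEFAULT_WINDOW_SIZE = 2000
DEFAULT_WINDOW_STEP = 500
DEFAULT_MERGE_SIGMA_NM = 25.0
DEFAULT_MERGE_WINDOW_S = 15.0
DEFAULT_PIXEL_SIZE_NM = 20.0
DEFAULT_INTENSITY_FRAC = 0.01
DEFAULT_MIN_DENSITY = 0.1  # detections per nm²
DEFAULT_MIN_DETECTIONS = 10
MIN_WINDOW_DETECTIONS = 10


def read_detections(path) -> pd.DataFrame:
    """Read a detection CSV; ThunderSTORM-style headers are normalized."""
    df = pd.read_csv(path)
    rename = {}
    for col in df.columns:
        key = col.strip().strip('"').lower()
        if key in ("x [nm]", "x_nm", "x"):
            rename[col] = "x_nm"
        elif key in ("y [nm]", "y_nm", "y"):
            rename[col] = "y_nm"
        elif key == "frame":
            rename[col] = "frame"
    df = df.rename(columns=rename)
    missing = {"frame", "x_nm", "y_nm"} - set(df.columns)
    if missing:
        raise ValueError(f"detection table lacks columns: {sorted(missing)}")
    return df[["frame", "x_nm", "y_nm"]].astype({"frame": int})


@dataclass
class DriftTrace:
    """Per-frame (dx, dy) in nm, zero at the reference (first) window."""

    frames: np.ndarray  # all frames 0..n-1
    dx: np.ndarray
    dy: np.ndarray
    window_size: int
    window_step: int

    def at(self, frame: np.ndarray) -> np.ndarray:
        return np.column_stack([self.dx[frame], self.dy[frame]])


@dataclass
class RenderedImage:
    """2D detection-count grid; ``origin_nm`` is the coordinate of the
    (row 0, col 0) pixel corner. x maps to columns, y to rows."""

    counts: np.ndarray
    pixel_size_nm: float
    origin_nm: tuple[float, float]  # (x0, y0)


@dataclass
class NanoCluster:
    pixels: np.ndarray  # (n_pix, 2) row/col indices
    area_nm2: float
    n_detections: int
    density_per_nm2: float
    centroid_nm: tuple[float, float]
    n_molecules: int | None = None


def densest_box(dets: pd.DataFrame, box_nm: float = 500.0) -> tuple[float, float, float, float]:
    """Locate the densest ``box_nm`` square (default drift-reference ROI)."""
    x, y = dets["x_nm"].to_numpy(), dets["y_nm"].to_numpy()
    bx = np.floor(x / box_nm).astype(int)
    by = np.floor(y / box_nm).astype(int)
    pairs, counts = np.unique(np.column_stack([bx, by]), axis=0, return_counts=True)
    best = pairs[np.argmax(counts)]
    x0, y0 = best[0] * box_nm, best[1] * box_nm
    return (x0, x0 + box_nm, y0, y0 + box_nm)


def estimate_drift(
    dets: pd.DataFrame,
    window_size: int = DEFAULT_WINDOW_SIZE,
    window_step: int = DEFAULT_WINDOW_STEP,
    roi: tuple[float, float, float, float] | str | None = "auto",
    n_frames: int | None = None,
    roi_size_nm: float = 500.0,
) -> DriftTrace:
    """Sliding-window center-of-mass drift estimate.

    For each window of ``window_size`` frames (stepping by ``window_step``)
    the center of mass of the reference detections is computed; the COM
    estimates the drift at the mean detection frame of the window (for a
    linear drift this makes the estimate exact irrespective of how bursts
    sample the window), relative to the first valid window. Per-frame drift
    follows by linear interpolation between window anchors, extended
    linearly beyond the first/last anchor so slow drift is not clipped at
    the acquisition ends. ``roi``:

    * ``None`` — use all detections (appropriate when the field is a single
      cluster);
    * ``"auto"`` — densest 500 nm box from the first window, re-centered on
      the previous window's COM as the acquisition progresses;
    * explicit ``(xmin, xmax, ymin, ymax)`` in nm — fixed box.

    Windows with fewer than 10 detections are skipped and interpolated over.
    """
    if dets.empty:
        raise ValueError("empty detection table")
    frames = dets["frame"].to_numpy()
    if n_frames is None:
        n_frames = int(frames.max()) + 1
    if window_size > n_frames:
        raise ValueError("window_size exceeds the number of frames")
    xy = dets[["x_nm", "y_nm"]].to_numpy()

    auto = roi == "auto"
    if auto:
        first = xy[(frames >= 0) & (frames < window_size)]
        if len(first) == 0:
            raise ValueError("no detections in the first window")
        sub = pd.DataFrame(first, columns=["x_nm", "y_nm"])
        xmin, xmax, ymin, ymax = densest_box(sub, roi_size_nm)
        center = np.array([(xmin + xmax) / 2, (ymin + ymax) / 2])
        half = roi_size_nm / 2
    elif roi is not None:
        xmin, xmax, ymin, ymax = roi

    anchors_f, coms = [], []
    starts = list(range(0, n_frames - window_size + 1, window_step))
    if starts[-1] != n_frames - window_size:
        starts.append(n_frames - window_size)
    for s in starts:
        in_win = (frames >= s) & (frames < s + window_size)
        pts = xy[in_win]
        win_frames = frames[in_win]
        if roi is not None:
            if auto:
                xmin, xmax = center[0] - half, center[0] + half
                ymin, ymax = center[1] - half, center[1] + half
            sel = (
                (pts[:, 0] >= xmin)
                & (pts[:, 0] < xmax)
                & (pts[:, 1] >= ymin)
                & (pts[:, 1] < ymax)
            )
            pts = pts[sel]
            win_frames = win_frames[sel]
        if len(pts) < MIN_WINDOW_DETECTIONS:
            continue
        com = pts.mean(axis=0)
        anchors_f.append(float(win_frames.mean()))
        coms.append(com)
        if auto:
            center = com
    if not coms:
        raise ValueError("all drift windows empty; cannot estimate drift")
    coms = np.asarray(coms)
    rel = coms - coms[0]
    f = np.arange(n_frames, dtype=float)
    anchors_f = np.asarray(anchors_f)
    dx = np.interp(f, anchors_f, rel[:, 0])
    dy = np.interp(f, anchors_f, rel[:, 1])
    if len(coms) >= 2:
        # extend the boundary segments linearly so slow drift is not clipped
        lo = f < anchors_f[0]
        hi = f > anchors_f[-1]
        for arr, col in ((dx, 0), (dy, 1)):
            s0 = (rel[1, col] - rel[0, col]) / (anchors_f[1] - anchors_f[0])
            s1 = (rel[-1, col] - rel[-2, col]) / (anchors_f[-1] - anchors_f[-2])
            arr[lo] = rel[0, col] + s0 * (f[lo] - anchors_f[0])
            arr[hi] = rel[-1, col] + s1 * (f[hi] - anchors_f[-1])
    return DriftTrace(frames=f.astype(int), dx=dx, dy=dy, window_size=window_size, window_step=window_step)


def apply_drift(dets: pd.DataFrame, trace: DriftTrace) -> pd.DataFrame:
    """Subtract the per-frame drift from detection coordinates."""
    out = dets.copy()
    d = trace.at(out["frame"].to_numpy())
    out["x_nm"] = out["x_nm"].to_numpy() - d[:, 0]
    out["y_nm"] = out["y_nm"].to_numpy() - d[:, 1]
    return out


def merge_detections(
    dets: pd.DataFrame,
    sigma_nm: float = DEFAULT_MERGE_SIGMA_NM,
    time_window_s: float = DEFAULT_MERGE_WINDOW_S,
    frame_interval_s: float = 0.050,
) -> pd.DataFrame:
    """Merge repeated detections of one blinking fluorophore into molecules.

    Detections are scanned in frame order; a detection joins an open
    molecule when it lies within 2σ of the molecule's running mean position
    and within ``time_window_s`` of its last detection (transitive chaining,
    so long blinking trains stay one molecule). Returns a molecule table
    (x_nm, y_nm, n_detections, first_frame, last_frame) conserving the
    detection count.
    """
    if sigma_nm <= 0:
        raise ValueError("sigma_nm must be > 0")
    radius2 = (2.0 * sigma_nm) ** 2
    gap_frames = time_window_s / frame_interval_s
    dets = dets.sort_values("frame", kind="stable")
    frames = dets["frame"].to_numpy()
    xy = dets[["x_nm", "y_nm"]].to_numpy()

    open_mols: list[dict] = []
    closed: list[dict] = []
    for f, p in zip(frames, xy):
        still_open = []
        for m in open_mols:
            if f - m["last"] > gap_frames:
                closed.append(m)
            else:
                still_open.append(m)
        open_mols = still_open
        best, best_d2 = None, radius2
        for m in open_mols:
            d2 = (m["sum"][0] / m["n"] - p[0]) ** 2 + (m["sum"][1] / m["n"] - p[1]) ** 2
            if d2 <= best_d2:
                best, best_d2 = m, d2
        if best is None:
            open_mols.append({"sum": p.copy(), "n": 1, "first": f, "last": f})
        else:
            best["sum"] += p
            best["n"] += 1
            best["last"] = f
    closed.extend(open_mols)
    rows = [
        {
            "x_nm": m["sum"][0] / m["n"],
            "y_nm": m["sum"][1] / m["n"],
            "n_detections": m["n"],
            "first_frame": m["first"],
            "last_frame": m["last"],
        }
        for m in closed
    ]
    return pd.DataFrame(rows, columns=["x_nm", "y_nm", "n_detections", "first_frame", "last_frame"])


def render(
    dets: pd.DataFrame,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    origin_nm: tuple[float, float] | None = None,
    shape: tuple[int, int] | None = None,
) -> RenderedImage:
    """2D histogram of detection coordinates (counts per pixel).

    Bounds default to the data extent padded by one pixel; a fixed
    ``origin_nm``/``shape`` can be supplied for reproducible framing.
    """
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be > 0")
    if dets.empty:
        raise ValueError("cannot render an empty detection table")
    x = dets["x_nm"].to_numpy()
    y = dets["y_nm"].to_numpy()
    p = pixel_size_nm
    if origin_nm is None:
        x0 = (np.floor(x.min() / p) - 1) * p
        y0 = (np.floor(y.min() / p) - 1) * p
    else:
        x0, y0 = origin_nm
    cols = np.floor((x - x0) / p).astype(int)
    rows = np.floor((y - y0) / p).astype(int)
    if shape is None:
        shape = (rows.max() + 2, cols.max() + 2)
    if rows.min() < 0 or cols.min() < 0 or rows.max() >= shape[0] or cols.max() >= shape[1]:
        raise ValueError("detections fall outside the requested frame")
    counts = np.zeros(shape, dtype=np.int64)
    np.add.at(counts, (rows, cols), 1)
    return RenderedImage(counts=counts, pixel_size_nm=p, origin_nm=(x0, y0))


def segment_clusters(
    img: RenderedImage,
    intensity_frac: float = DEFAULT_INTENSITY_FRAC,
    min_density: float = DEFAULT_MIN_DENSITY,
    min_detections: int = DEFAULT_MIN_DETECTIONS,
    connectivity: int = 8,
    density_mode: str = "pixel",
    molecules: pd.DataFrame | None = None,
) -> list[NanoCluster]:
    """Density-threshold nanocluster segmentation on a rendered image.

    The binary image keeps pixels whose count reaches both the intensity
    floor (``intensity_frac`` × max pixel count) and — in the default
    ``density_mode="pixel"`` — the density floor expressed per pixel
    (``min_density`` × pixel area). Connected components (8-connectivity by
    default) with at least ``min_detections`` detections inside their pixels
    become clusters; with ``density_mode="component"`` the density floor is
    instead applied to each component's detections/area ratio. Cluster area
    is (#pixels)·pixel², density is detections/area, so density·area equals
    the detection count exactly. If a molecule table is supplied, molecules
    whose coordinates fall in the cluster's pixels are counted.
    """
    if density_mode not in ("pixel", "component"):
        raise ValueError("density_mode must be 'pixel' or 'component'")
    counts = img.counts
    if counts.max() == 0:
        return []
    p = img.pixel_size_nm
    thr = intensity_frac * counts.max()
    if density_mode == "pixel":
        thr = max(thr, min_density * p * p)
    binary = counts >= max(thr, 1)
    if not binary.any():
        return []
    structure = np.ones((3, 3)) if connectivity == 8 else None
    labels, n_lab = ndimage.label(binary, structure=structure)

    mol_rc = None
    if molecules is not None and len(molecules):
        mc = np.floor((molecules["x_nm"].to_numpy() - img.origin_nm[0]) / p).astype(int)
        mr = np.floor((molecules["y_nm"].to_numpy() - img.origin_nm[1]) / p).astype(int)
        ok = (mr >= 0) & (mc >= 0) & (mr < counts.shape[0]) & (mc < counts.shape[1])
        mol_rc = (mr[ok], mc[ok])

    clusters = []
    for lab in range(1, n_lab + 1):
        sel = labels == lab
        n_det = int(counts[sel].sum())
        if n_det < min_detections:
            continue
        area = float(sel.sum()) * p * p
        density = n_det / area
        if density_mode == "component" and density < min_density:
            continue
        rr, cc = np.nonzero(sel)
        w = counts[rr, cc].astype(float)
        cx = img.origin_nm[0] + (np.average(cc, weights=w) + 0.5) * p
        cy = img.origin_nm[1] + (np.average(rr, weights=w) + 0.5) * p
        n_mol = None
        if mol_rc is not None:
            n_mol = int(np.sum(labels[mol_rc[0], mol_rc[1]] == lab))
        clusters.append(
            NanoCluster(
                pixels=np.column_stack([rr, cc]),
                area_nm2=area,
                n_detections=n_det,
                density_per_nm2=density,
                centroid_nm=(float(cx), float(cy)),
                n_molecules=n_mol,
            )
        )
    return clusters


def cluster_report(
    clusters: list[NanoCluster], metadata: dict | None = None
) -> pd.DataFrame:
    """Per-cluster rows (area nm², n_detections, density nm⁻²) with optional
    neuron/condition/culture metadata for the statistics layer."""
    rows = []
    for c in clusters:
        row = {
            "area_nm2": c.area_nm2,
            "n_detections": c.n_detections,
            "density_per_nm2": c.density_per_nm2,
            "n_molecules": c.n_molecules,
        }
        if metadata:
            row.update(metadata)
        rows.append(row)
    cols = ["area_nm2", "n_detections", "density_per_nm2", "n_molecules"]
    if metadata:
        cols += list(metadata)
    return pd.DataFrame(rows, columns=cols)
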