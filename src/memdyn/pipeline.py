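"""End-to-end orchestration: simulate → track → metrics → stats (SPT),
detections → drift/merge/segment (STORM), images → widefield quant.

A run is described by one flat config (dict or YAML); all randomness flows
from a single root seed split per stage, and a manifest records parameters,
per-stage counts, and output checksums so that identical config + seed give
identical results.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, metrics, stats, storm, tracking
from .synthetic import (
    SceneConfig,
    StormSimConfig,
    TrajectorySimConfig,
    simulate_storm,
    simulate_trajectory,
)
from .trajectories import trajectories_to_table

logger = logging.getLogger(__name__)

MODES = ("spt", "storm", "scenario")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(root_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def simulate_condition_trajectories(
    n_tracks: int,
    base_cfg: dict,
    seed: int,
) -> list:
    """Simulate a population of trajectories with per-track seeds."""
    trajs = []
    for k in range(n_tracks):
        cfg = TrajectorySimConfig(**{**base_cfg, "seed": seed + k})
        t, _ = simulate_trajectory(cfg)
        t.particle_id = k
        trajs.append(t)
    return trajs


def run_scenario_confinement(
    n_per_group: int = 300,
    control_cfg: dict | None = None,
    treated_cfg: dict | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    test_method: str = "auto",
) -> dict:
    """Two-condition SPT scenario: treated particles have reduced mobility
    and tighter confinement (emulating GABA_A_R pharmacology). Computes per-
    track D and EA, compares medians, and tests log-values with
    Mann-Whitney. Returns the summary dict (also written as manifest)."""
    control_cfg = control_cfg or {
        "motion_model": "confined_ou",
        "diffusion_coeff": 0.10,
        "confinement_radius": 0.40,
    }
    treated_cfg = treated_cfg or {
        "motion_model": "confined_ou",
        "diffusion_coeff": 0.05,
        "confinement_radius": 0.20,
    }
    groups = {}
    for cond, cfg in (("control", control_cfg), ("treated", treated_cfg)):
        trajs = simulate_condition_trajectories(
            n_per_group, cfg, _stage_seed(seed, f"sim:{cond}")
        )
        table = metrics.trajectory_metrics_table(trajs, metadata={"condition": cond})
        groups[cond] = table

    table = pd.concat(groups.values(), ignore_index=True)
    summary = metrics.summarize_population(table, group_cols=("condition",))

    result = {"n_per_group": n_per_group, "seed": seed}
    for col, name in (("D", "D"), ("EA_0.42", "EA")):
        ctrl = groups["control"][col].to_numpy()
        trt = groups["treated"][col].to_numpy()
        ctrl_pos, trt_pos = ctrl[ctrl > 0], trt[trt > 0]
        n_excluded = (ctrl.size - ctrl_pos.size) + (trt.size - trt_pos.size)
        test = stats.choose_and_test(np.log(trt_pos), np.log(ctrl_pos), method=test_method)
        result[name] = {
            "median_control": float(np.median(ctrl)),
            "median_treated": float(np.median(trt)),
            "p_value": test.p_value,
            "test": test.test_name,
            "n_excluded_nonpositive": int(n_excluded),
        }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "per_trajectory_metrics.csv", index=False)
        summary.to_csv(out / "population_summary.csv", index=False)
        manifest = dict(result)
        manifest["checksums"] = {
            p.name: _checksum(p) for p in sorted(out.glob("*.csv"))
        }
        io.write_json(manifest, out / "manifest.json")
    return result


def run_spt(config: dict, out_dir: str | Path) -> dict:
    """Tracking + metrics pass over a localization table (or a simulated
    scene when ``simulate`` is present in the config)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    tau = float(config.get("frame_interval", 0.030))

    if "simulate" in config:
        sim = dict(config["simulate"])
        n_tracks = int(sim.pop("n_tracks", 20))
        # particles laid out on a grid so distinct QDs do not overlap at start
        base = np.asarray(sim.pop("start", (10.0, 10.0)), dtype=float)
        spacing = float(sim.pop("grid_spacing", 5.0))
        side = int(np.ceil(np.sqrt(n_tracks)))
        trajs = []
        sim_seed = _stage_seed(seed, "sim")
        for k in range(n_tracks):
            start = base + spacing * np.array([k % side, k // side])
            cfg_k = TrajectorySimConfig(**{**sim, "start": tuple(start), "seed": sim_seed + k})
            t, _ = simulate_trajectory(cfg_k)
            t.particle_id = k
            trajs.append(t)
        locs = trajectories_to_table(trajs)
        locs = locs.rename(columns={"x_nm": "x", "y_nm": "y"})
        locs[["x", "y"]] /= 1000.0
        locs = locs.drop(columns="track_id").sample(frac=1.0, random_state=seed % 2**32)
    elif "trajectories_csv" in config:
        df = pd.read_csv(config["trajectories_csv"])
        locs = pd.DataFrame(
            {"frame": df["frame"], "x": df["x_nm"] / 1000.0, "y": df["y_nm"] / 1000.0}
        )
    else:
        raise StageError("spt input: config needs 'simulate' or 'trajectories_csv'")

    if locs.empty:
        raise StageError("tracking: empty localization table")
    linked, n_singletons = tracking.link_with_singletons(
        locs,
        max_jump=float(config.get("max_jump", tracking.DEFAULT_MAX_JUMP_UM)),
        max_gap=int(config.get("max_gap", tracking.DEFAULT_MAX_GAP)),
        frame_interval=tau,
    )
    kept, removed = tracking.remove_crossing_tracks(
        linked, float(config.get("crossing_radius", tracking.DEFAULT_CROSSING_RADIUS_UM))
    )
    if not kept:
        raise StageError("tracking: no trajectories survive crossing removal")
    table = metrics.trajectory_metrics_table(kept)
    table.to_csv(out / "per_trajectory_metrics.csv", index=False)

    manifest = {
        "mode": "spt",
        "seed": seed,
        "n_localizations": int(len(locs)),
        "n_tracks_linked": len(linked),
        "n_singleton_localizations": n_singletons,
        "n_tracks_removed_crossing": len(removed),
        "n_tracks_kept": len(kept),
        "n_tracks_with_fit": int(len(table)),
        "n_D_nonpositive": int((table["D"] <= 0).sum()),
        "checksums": {"per_trajectory_metrics.csv": _checksum(out / "per_trajectory_metrics.csv")},
    }
    io.write_json(manifest, out / "manifest.json")
    return manifest


def run_storm(config: dict, out_dir: str | Path) -> dict:
    """Drift-correct, merge, render, and segment a STORM detection table
    (or a simulated stream when ``simulate`` is present)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    if "simulate" in config:
        sim_kwargs = dict(config["simulate"])
        sim_kwargs["seed"] = _stage_seed(seed, "storm_sim")
        if "clusters" in sim_kwargs:
            sim_kwargs["clusters"] = [
                (tuple(c[0]), c[1], c[2]) for c in sim_kwargs["clusters"]
            ]
        dets, _ = simulate_storm(StormSimConfig(**sim_kwargs))
    elif "detections_csv" in config:
        dets = storm.read_detections(config["detections_csv"])
    else:
        raise StageError("storm input: config needs 'simulate' or 'detections_csv'")
    if dets.empty:
        raise StageError("storm input: empty detection table")

    trace = storm.estimate_drift(
        dets,
        window_size=int(config.get("drift_window", storm.DEFAULT_WINDOW_SIZE)),
        window_step=int(config.get("drift_step", storm.DEFAULT_WINDOW_STEP)),
        roi=config.get("drift_roi", "auto"),
    )
    corrected = storm.apply_drift(dets, trace)
    molecules = storm.merge_detections(
        corrected,
        sigma_nm=float(config.get("merge_sigma_nm", storm.DEFAULT_MERGE_SIGMA_NM)),
        time_window_s=float(config.get("merge_window_s", storm.DEFAULT_MERGE_WINDOW_S)),
        frame_interval_s=float(config.get("frame_interval", 0.050)),
    )
    img = storm.render(corrected, pixel_size_nm=float(config.get("pixel_size_nm", 20.0)))
    clusters = storm.segment_clusters(
        img,
        intensity_frac=float(config.get("intensity_frac", storm.DEFAULT_INTENSITY_FRAC)),
        min_density=float(config.get("min_density", storm.DEFAULT_MIN_DENSITY)),
        min_detections=int(config.get("min_detections", storm.DEFAULT_MIN_DETECTIONS)),
        molecules=molecules,
    )
    report = storm.cluster_report(clusters, metadata=config.get("metadata"))

    corrected.to_csv(out / "detections_corrected.csv", index=False)
    molecules.to_csv(out / "molecules.csv", index=False)
    report.to_csv(out / "clusters.csv", index=False)
    io.write_counts_tiff(img.counts, out / "rendered.tif")
    manifest = {
        "mode": "storm",
        "seed": seed,
        "n_detections": int(len(dets)),
        "n_molecules": int(len(molecules)),
        "n_clusters": int(len(clusters)),
        "checksums": {p.name: _checksum(p) for p in sorted(out.glob("*.csv"))},
    }
    io.write_json(manifest, out / "manifest.json")
    return manifest


def run(config: dict, out_dir: str | Path) -> dict:
    """Dispatch a run config to its mode handler."""
    mode = config.get("mode")
    if mode == "spt":
        return run_spt(config, out_dir)
    if mode == "storm":
        return run_storm(config, out_dir)
    if mode == "scenario":
        return run_scenario_confinement(
            n_per_group=int(config.get("n_per_group", 300)),
            control_cfg=config.get("control"),
            treated_cfg=config.get("treated"),
            seed=int(config.get("seed", 0)),
            out_dir=out_dir,
        )
    raise StageError(f"unknown mode {mode!r}; expected one of {MODES}")
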