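"""Drift correction, detection merging, rendering, nanocluster segmentation."""

import io

import numpy as np
import pandas as pd
import pytest

from memdyn import storm
from memdyn.synthetic import StormSimConfig, simulate_storm


def dets_frame(frames, x, y):
    return pd.DataFrame({"frame": frames, "x_nm": x, "y_nm": y})


class TestReadDetections:
    def test_thunderstorm_headers_accepted(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text('"frame","x [nm]","y [nm]"\n1,100.5,200.5\n2,101.0,199.0\n')
        df = storm.read_detections(p)
        assert list(df.columns) == ["frame", "x_nm", "y_nm"]
        assert df["x_nm"].iloc[0] == 100.5

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("frame,x_nm\n1,100\n")
        with pytest.raises(ValueError):
            storm.read_detections(p)


class TestDrift:
    def test_static_emitters_give_null_trace(self):
        rng = np.random.default_rng(0)
        n = 4000
        d = dets_frame(
            rng.integers(0, 10000, n),
            1000 + rng.normal(0, 10, n),
            2000 + rng.normal(0, 10, n),
        ).sort_values("frame")
        trace = storm.estimate_drift(d, window_size=2000, window_step=500, roi=None)
        # COM noise scale: sigma/sqrt(n_window) with ~800 detections per window
        assert np.abs(trace.dx).max() < 3 * 10 / np.sqrt(800) * 3
        assert np.abs(trace.dy).max() < 3 * 10 / np.sqrt(800) * 3

    def test_apply_zero_trace_is_identity(self):
        d = dets_frame([0, 1, 2], [10.0, 20.0, 30.0], [1.0, 2.0, 3.0])
        trace = storm.DriftTrace(
            frames=np.arange(3), dx=np.zeros(3), dy=np.zeros(3),
            window_size=2, window_step=1,
        )
        out = storm.apply_drift(d, trace)
        pd.testing.assert_frame_equal(out, d)

    def test_linear_drift_recovered_and_corrected(self):
        cfg = StormSimConfig(
            n_frames=10000, clusters=[((2500.0, 2500.0), 50.0, 200)],
            mean_bursts=6, localization_sigma=10.0,
            drift_model="linear", drift_rate_nm_per_frame=(1.0, -0.5), seed=4,
        )
        dets, gt = simulate_storm(cfg)
        trace = storm.estimate_drift(dets, roi=None, n_frames=cfg.n_frames)
        est = np.column_stack([trace.dx, trace.dy])
        diff = est - gt.true_drift
        diff -= diff.mean(axis=0)  # trace is defined up to the reference offset
        rmse = np.sqrt((diff**2).sum(axis=1).mean())
        assert rmse <= 10.0

        corrected = storm.apply_drift(dets, trace)
        assert corrected["x_nm"].std() <= dets["x_nm"].std()
        assert corrected["y_nm"].std() <= dets["y_nm"].std()
        # re-estimating on corrected data leaves only residual drift
        trace2 = storm.estimate_drift(corrected, roi=None, n_frames=cfg.n_frames)
        assert np.abs(np.column_stack([trace2.dx, trace2.dy])).max() < 15.0

    def test_window_larger_than_acquisition_rejected(self):
        d = dets_frame([0, 1], [0.0, 1.0], [0.0, 1.0])
        with pytest.raises(ValueError):
            storm.estimate_drift(d, window_size=2000)

    def test_default_window_size(self):
        assert storm.DEFAULT_WINDOW_SIZE == 2000


class TestMerge:
    def test_close_in_space_and_time_merged(self):
        # 1σ apart, 5 s apart (100 frames at 50 ms) → one molecule
        d = dets_frame([0, 100], [100.0, 125.0], [0.0, 0.0])
        mol = storm.merge_detections(d, sigma_nm=25.0)
        assert len(mol) == 1
        assert mol["n_detections"].iloc[0] == 2

    def test_distant_detections_stay_separate(self):
        d = dets_frame([0, 1], [0.0, 250.0], [0.0, 0.0])  # 10σ apart
        mol = storm.merge_detections(d, sigma_nm=25.0)
        assert len(mol) == 2

    def test_blinking_train_chains_within_15s_and_splits_beyond(self):
        # bursts every 10 s over 100 s chain transitively into one molecule
        frames = np.concatenate([[k * 200, k * 200 + 1] for k in range(10)])
        d = dets_frame(frames, np.zeros(20), np.zeros(20))
        mol = storm.merge_detections(d, frame_interval_s=0.050)
        assert len(mol) == 1
        # a 20 s dark gap splits the train
        frames = np.array([0, 1, 2, 402, 403])  # gap of 400 frames = 20 s
        d = dets_frame(frames, np.zeros(5), np.zeros(5))
        mol = storm.merge_detections(d, frame_interval_s=0.050)
        assert len(mol) == 2

    def test_conservation_and_determinism(self):
        rng = np.random.default_rng(1)
        n = 500
        d = dets_frame(
            np.sort(rng.integers(0, 3000, n)),
            rng.uniform(0, 2000, n),
            rng.uniform(0, 2000, n),
        )
        a = storm.merge_detections(d)
        b = storm.merge_detections(d)
        assert int(a["n_detections"].sum()) == n
        pd.testing.assert_frame_equal(a, b)


class TestRender:
    def test_binning_arithmetic(self):
        d = dets_frame([0], [100.0], [100.0])
        img = storm.render(d, pixel_size_nm=20.0, origin_nm=(0.0, 0.0), shape=(10, 10))
        assert img.counts[5, 5] == 1
        assert img.counts.sum() == 1

    def test_count_conservation(self):
        rng = np.random.default_rng(2)
        d = dets_frame(np.arange(300), rng.uniform(0, 500, 300), rng.uniform(0, 500, 300))
        img = storm.render(d)
        assert img.counts.sum() == 300
        assert img.pixel_size_nm == 20.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            storm.render(dets_frame([], [], []))


def planted_disc(center, radius, n, jitter, seed, frames_max=30000):
    rng = np.random.default_rng(seed)
    r = radius * np.sqrt(rng.random(n))
    th = rng.random(n) * 2 * np.pi
    x = center[0] + r * np.cos(th) + rng.normal(0, jitter, n)
    y = center[1] + r * np.sin(th) + rng.normal(0, jitter, n)
    return dets_frame(np.sort(rng.integers(0, frames_max, n)), x, y)


class TestSegmentation:
    def test_planted_disc_recovered_once(self):
        d = planted_disc((1000.0, 1000.0), 40.0, 600, 5.0, seed=3)
        img = storm.render(d)
        clusters = storm.segment_clusters(img)
        assert len(clusters) == 1
        c = clusters[0]
        assert c.density_per_nm2 * c.area_nm2 == pytest.approx(c.n_detections)
        assert c.density_per_nm2 >= storm.DEFAULT_MIN_DENSITY
        assert abs(c.centroid_nm[0] - 1000.0) < 20.0

    def test_sparse_background_gives_no_clusters(self):
        rng = np.random.default_rng(5)
        d = dets_frame(np.arange(200), rng.uniform(0, 5000, 200), rng.uniform(0, 5000, 200))
        img = storm.render(d)
        assert storm.segment_clusters(img) == []

    def test_nine_detection_cluster_rejected(self):
        d = planted_disc((500.0, 500.0), 5.0, 9, 0.0, seed=7)
        img = storm.render(d)
        assert storm.segment_clusters(img) == []
        # positive control: enough detections in one pixel to clear the
        # 0.1 nm⁻² density floor (40 per 20 nm pixel)
        d45 = planted_disc((490.0, 490.0), 1.0, 45, 0.0, seed=7)
        assert len(storm.segment_clusters(storm.render(d45))) == 1

    def test_translation_invariance_by_whole_pixels(self):
        d = planted_disc((1000.0, 1000.0), 40.0, 600, 5.0, seed=11)
        shifted = d.copy()
        shifted["x_nm"] += 40.0  # two 20 nm pixels
        shifted["y_nm"] -= 60.0
        a = storm.segment_clusters(storm.render(d, origin_nm=(0.0, 0.0), shape=(100, 100)))
        b = storm.segment_clusters(
            storm.render(shifted, origin_nm=(0.0, 0.0), shape=(100, 100))
        )
        assert len(a) == len(b) == 1
        assert a[0].area_nm2 == b[0].area_nm2
        assert a[0].n_detections == b[0].n_detections

    def test_component_mode_applies_density_to_clusters(self):
        d = planted_disc((1000.0, 1000.0), 40.0, 600, 5.0, seed=3)
        img = storm.render(d)
        comp = storm.segment_clusters(img, density_mode="component", min_density=0.0)
        # without a density floor the binary image keeps single-detection rim
        # pixels, so the component covers more pixels than the default mode
        assert len(comp) == 1
        assert comp[0].area_nm2 > storm.segment_clusters(img)[0].area_nm2

    def test_molecule_counts_attached(self):
        d = planted_disc((1000.0, 1000.0), 40.0, 600, 5.0, seed=3)
        mol = storm.merge_detections(d)
        img = storm.render(d)
        clusters = storm.segment_clusters(img, molecules=mol)
        assert clusters[0].n_molecules is not None
        assert 1 <= clusters[0].n_molecules <= len(mol)


class TestClusterReport:
    def test_empty_input_empty_table(self):
        rep = storm.cluster_report([])
        assert rep.empty
        assert list(rep.columns[:3]) == ["area_nm2", "n_detections", "density_per_nm2"]

    def test_two_planted_clusters_area_ratio(self):
        a = planted_disc((1000.0, 1000.0), 40.0, 600, 5.0, seed=13)
        b = planted_disc((3000.0, 3000.0), 40.0 * np.sqrt(2), 1200, 5.0, seed=14)
        d = pd.concat([a, b], ignore_index=True).sort_values("frame")
        clusters = storm.segment_clusters(storm.render(d))
        rep = storm.cluster_report(clusters, metadata={"condition": "control"})
        assert len(rep) == 2
        ratio = rep["area_nm2"].max() / rep["area_nm2"].min()
        assert ratio == pytest.approx(2.0, rel=0.3)
        assert (rep["condition"] == "control").all()
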