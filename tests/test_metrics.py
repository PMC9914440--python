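"""MSD, diffusion fit, explored area, dwell time, compartment labels.

The MSD implementation is checked against an independent O(N²) double-loop
oracle and against hand-evaluated examples.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memdyn import metrics
from memdyn.trajectories import Trajectory


def msd_bruteforce(frames, xy, tau):
    """Independent oracle: literal double loop over lags and pairs,
    indexing by absolute frame number so gaps are skipped naturally."""
    pos = {int(f): p for f, p in zip(frames, xy)}
    span = int(frames[-1] - frames[0])
    out = {}
    for n in range(1, span + 1):
        acc, cnt = 0.0, 0
        for f in range(int(frames[0]), int(frames[-1]) - n + 1):
            if f in pos and f + n in pos:
                dx = pos[f + n][0] - pos[f][0]
                dy = pos[f + n][1] - pos[f][1]
                acc += dx * dx + dy * dy
                cnt += 1
        if cnt:
            out[n] = (acc / cnt, cnt)
    return out


def random_track(rng, n_max=60, gappy=True):
    n = int(rng.integers(5, n_max))
    frames = np.arange(n)
    if gappy and rng.random() < 0.5:
        keep = np.sort(rng.choice(n, size=max(2, int(0.7 * n)), replace=False))
        frames = frames[keep]
    xy = rng.normal(0, 1, size=(len(frames), 2))
    return Trajectory(0, frames, xy, 0.030)


class TestComputeMSD:
    def test_static_track_msd_zero(self, traj_factory):
        t = traj_factory(np.tile([2.0, 3.0], (20, 1)))
        msd = metrics.compute_msd(t)
        assert np.all(msd.msd == 0.0)
        np.testing.assert_array_equal(msd.n_pairs, 20 - msd.lag_index)

    def test_three_point_hand_example(self, traj_factory):
        # (0,0),(1,0),(1,1) at τ=1 s: MSD(1)=1, MSD(2)=2
        t = traj_factory(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]]), tau=1.0)
        msd = metrics.compute_msd(t)
        np.testing.assert_allclose(msd.msd, [1.0, 2.0])
        np.testing.assert_allclose(msd.lag_time, [1.0, 2.0])

    def test_matches_bruteforce_on_random_tracks(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            t = random_track(rng)
            msd = metrics.compute_msd(t)
            oracle = msd_bruteforce(t.frames, t.xy, t.frame_interval)
            assert list(msd.lag_index) == sorted(oracle)
            for n, v, c in zip(msd.lag_index, msd.msd, msd.n_pairs):
                ref, cnt = oracle[n]
                assert c == cnt
                assert v == pytest.approx(ref, rel=1e-10, abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_property_nonnegative_and_pair_counts(self, seed):
        t = random_track(np.random.default_rng(seed), gappy=False)
        msd = metrics.compute_msd(t)
        assert np.all(msd.msd >= 0)
        # gap-free: n_pairs(n) = N − n
        np.testing.assert_array_equal(msd.n_pairs, len(t) - msd.lag_index)


class TestFitDiffusion:
    def test_exact_linear_case(self, traj_factory):
        curve = metrics.MSDCurve(
            lag_index=np.arange(1, 5),
            lag_time=np.arange(1, 5) * 0.03,
            msd=np.array([0.012, 0.024, 0.036, 0.048]),
            n_pairs=np.full(4, 100),
            frame_interval=0.03,
        )
        est = metrics.fit_diffusion(curve)
        assert est.D == pytest.approx(0.1, abs=1e-12)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)
        assert est.r_squared == pytest.approx(1.0)

    def test_static_track_gives_zero_d(self, traj_factory):
        t = traj_factory(np.tile([1.0, 1.0], (10, 1)))
        est = metrics.fit_diffusion(metrics.compute_msd(t))
        assert est.D == 0.0
        assert est.intercept == 0.0

    def test_short_track_unavailable(self, traj_factory):
        t = traj_factory(np.array([[0.0, 0.0], [0.1, 0.0], [0.2, 0.0]]))
        assert metrics.fit_diffusion(metrics.compute_msd(t)) is None


class TestExploredArea:
    def test_default_lags_map_to_indices_14_15(self, traj_factory):
        rng = np.random.default_rng(2)
        t = traj_factory(rng.normal(0, 0.1, (40, 2)))
        msd = metrics.compute_msd(t)
        ea = metrics.explored_area(msd)
        assert ea[0.42] == msd.at_lag_index(14)
        assert ea[0.45] == msd.at_lag_index(15)

    def test_static_track_ea_zero(self, traj_factory):
        t = traj_factory(np.tile([0.0, 0.0], (40, 1)))
        ea = metrics.explored_area(metrics.compute_msd(t))
        assert ea == {0.42: 0.0, 0.45: 0.0}

    def test_non_multiple_lag_rejected(self, traj_factory):
        t = traj_factory(np.zeros((40, 2)))
        with pytest.raises(ValueError):
            metrics.explored_area(metrics.compute_msd(t), lags_s=(0.431,))

    def test_lag_beyond_length_omitted_with_warning(self, traj_factory):
        t = traj_factory(np.zeros((5, 2)))
        with pytest.warns(UserWarning):
            ea = metrics.explored_area(metrics.compute_msd(t), lags_s=(0.42,))
        assert ea == {}


class TestClassification:
    def px_traj(self, pixels, pixel_nm=190.0):
        """Trajectory whose localizations sit at given (row, col) pixel centers."""
        xy = np.array(
            [[(c + 0.5) * pixel_nm / 1000.0, (r + 0.5) * pixel_nm / 1000.0] for r, c in pixels]
        )
        if len(xy) == 1:
            xy = np.vstack([xy, xy])
        return Trajectory(0, np.arange(len(xy)), xy, 0.030)

    def test_distance_based_labels(self, square_mask):
        masks = {"inhibitory": square_mask}
        # on the mask / 3 px (570 nm) / 5 px (950 nm) from its edge
        on = self.px_traj([(32, 32)])
        near = self.px_traj([(32, 36)])
        far = self.px_traj([(32, 38)])
        assert metrics.classify_trajectory(on, masks) == "inhibitory_synaptic"
        assert metrics.classify_trajectory(near, masks) == "inhibitory_synaptic"
        assert metrics.classify_trajectory(far, masks) == "extrasynaptic"

    def test_closer_marker_wins(self, square_mask):
        other = np.zeros_like(square_mask)
        other[31:34, 44:47] = True  # second marker further from the track
        masks = {"inhibitory": square_mask, "excitatory": other}
        t = self.px_traj([(32, 36)])  # 3 px from inhib, 8 px from excit
        assert metrics.classify_trajectory(t, masks) == "inhibitory_synaptic"

    def test_equidistant_tie_unclassified(self, square_mask):
        other = np.zeros_like(square_mask)
        other[31:34, 39:42] = True  # symmetric around column 36
        masks = {"inhibitory": square_mask, "excitatory": other}
        t = self.px_traj([(32, 36)])
        assert metrics.classify_trajectory(t, masks) == "unclassified"

    def test_component_relabeling_invariance(self, square_mask):
        # splitting the mask into permuted connected components changes nothing
        two = square_mask.copy()
        two[10:12, 10:12] = True
        t = self.px_traj([(32, 36)])
        a = metrics.classify_trajectory(t, {"inhibitory": two})
        b = metrics.classify_trajectory(t, {"inhibitory": two[::1, ::1].copy()})
        assert a == b == "inhibitory_synaptic"

    def test_out_of_bounds_raises(self, square_mask):
        t = self.px_traj([(100, 100)])
        with pytest.raises(ValueError):
            metrics.classify_trajectory(t, {"inhibitory": square_mask})

    def test_endocytic_labels(self, square_mask):
        inside = self.px_traj([(32, 32)])
        outside = self.px_traj([(32, 40)])
        assert metrics.classify_endocytic(inside, square_mask) == "intra_EZ"
        assert metrics.classify_endocytic(outside, square_mask) == "extra_EZ"


class TestDwellTime:
    def test_hand_example_two_exits(self):
        # 10 in, out, 7 in, out → 17τ/2 = 8.5τ = 0.255 s at τ = 30 ms
        labels = [True] * 10 + [False] + [True] * 7 + [False]
        res = metrics.dwell_from_labels(labels, tau=0.030)
        assert res.total_synaptic_frames == 17
        assert res.n_exits == 2
        assert res.dwell_time == pytest.approx(0.255)
        assert not res.censored and not res.discarded

    def test_short_dwell_discarded(self):
        # 3 in-frames with one exit → 3τ < 5τ
        res = metrics.dwell_from_labels([True] * 3 + [False], tau=0.030)
        assert res.dwell_time == pytest.approx(0.090)
        assert res.discarded

    def test_never_exits_censored(self):
        res = metrics.dwell_from_labels([True] * 20, tau=0.030)
        assert res.censored
        assert res.n_exits == 0
        assert res.dwell_time == pytest.approx(20 * 0.030)

    def test_never_synaptic(self):
        res = metrics.dwell_from_labels([False] * 10, tau=0.030)
        assert res.total_synaptic_frames == 0 and not res.discarded

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=200), st.integers(0, 2**31 - 1))
    def test_property_dwell_times_exits_equals_total(self, labels, _):
        res = metrics.dwell_from_labels(labels, tau=0.030)
        if not res.censored and res.n_exits > 0:
            assert res.dwell_time * res.n_exits == pytest.approx(
                res.total_synaptic_frames * 0.030
            )

    def test_geometry_against_mask(self, square_mask):
        # enter the 760 nm zone then leave it: distances via the mask raster
        pix = [(32, 32)] * 4 + [(32, 40)] * 3 + [(32, 33)] * 2 + [(32, 40)]
        t = TestClassification().px_traj(pix)
        res = metrics.dwell_time(t, square_mask)
        assert res.total_synaptic_frames == 6
        assert res.n_exits == 2


class TestSummaries:
    def test_single_trajectory_summary_is_its_values(self, traj_factory):
        rng = np.random.default_rng(8)
        t = traj_factory(np.cumsum(rng.normal(0, 0.05, (60, 2)), axis=0))
        table = metrics.trajectory_metrics_table([t], metadata={"condition": "control"})
        summary = metrics.summarize_population(table, group_cols=("condition",))
        assert summary.loc[0, "median_D"] == pytest.approx(table.loc[0, "D"])
        assert summary.loc[0, "n_qds"] == 1
        # one EA value per configured lag per QD
        assert summary.loc[0, "n_ea_values"] == 2

    def test_population_ordering_detectable(self):
        from memdyn.synthetic import TrajectorySimConfig, simulate_trajectory

        tables = []
        for cond, d in (("control", 0.1), ("treated", 0.01)):
            trajs = []
            for s in range(40):
                cfg = TrajectorySimConfig(
                    n_frames=120, diffusion_coeff=d, localization_sigma=0.02, seed=s
                )
                t, _ = simulate_trajectory(cfg)
                t.particle_id = s
                trajs.append(t)
            tables.append(
                metrics.trajectory_metrics_table(trajs, metadata={"condition": cond})
            )
        import pandas as pd

        table = pd.concat(tables, ignore_index=True)
        summary = metrics.summarize_population(table, group_cols=("condition",)).set_index(
            "condition"
        )
        assert summary.loc["control", "median_D"] > summary.loc["treated", "median_D"]

    def test_mean_msd_curve_lag_coverage(self, traj_factory):
        rng = np.random.default_rng(3)
        curves = [
            metrics.compute_msd(traj_factory(rng.normal(0, 1, (n, 2))))
            for n in (10, 10, 10, 10, 4)
        ]
        mean_curve = metrics.mean_msd_curve(curves, min_fraction=0.8)
        # lag 4+ is defined for only 4/5 = 80% of tracks: still included;
        # lags above 9 exist for none of the short tracks' span
        assert mean_curve["lag_index"].max() == 9
        assert (mean_curve["n_tracks"] >= 4).all()
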