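"""Closest-approach reduction and the time-within-threshold statistic."""

import itertools

import numpy as np
import pandas as pd
import pytest

import codonaffinity as ca
from codonaffinity.synthetic import BoxTrajectory
from codonaffinity.trajectory import min_image_distances


def make_traj(coords_by_group, box_edge=40.0, n_frames=1):
    """Build a one-frame trajectory from {group: (n_atoms, 3) array}."""
    groups = np.concatenate([[g] * len(c) for g, c in coords_by_group.items()])
    frame = np.concatenate([np.asarray(c, float) for c in coords_by_group.values()])
    return BoxTrajectory(
        coords=np.tile(frame, (n_frames, 1, 1)), box_edge=box_edge, groups=groups
    )


def brute_force_min_distance(a, b, edge):
    """Oracle: exhaustive minimum over all atom pairs and 27 periodic images."""
    best = np.inf
    for pa, pb in itertools.product(a, b):
        for shift in itertools.product((-edge, 0.0, edge), repeat=3):
            best = min(best, float(np.linalg.norm(pa - (pb + np.asarray(shift)))))
    return best


class TestMinDistanceSeries:
    def test_pythagoras(self):
        traj = make_traj({"nt": [[0, 0, 0]], "aa0": [[3, 4, 0]]}, box_edge=10.0)
        assert ca.min_distance_series(traj)["distance"].iloc[0] == pytest.approx(5.0)

    def test_minimum_over_copies(self):
        groups = {"nt": [[20.0, 20, 20]], "aa0": [[22.0, 20, 20]]}
        for i in range(1, 10):
            groups[f"aa{i}"] = [[20.0 + 10 + i, 20, 20]]
        traj = make_traj(groups)
        assert ca.min_distance_series(traj)["distance"].iloc[0] == pytest.approx(2.0)

    def test_matches_bruteforce_all_images(self):
        rng = np.random.default_rng(5)
        edge = 12.0
        traj = make_traj(
            {
                "nt": rng.uniform(0, edge, (3, 3)),
                "aa0": rng.uniform(0, edge, (2, 3)),
                "aa1": rng.uniform(0, edge, (2, 3)),
            },
            box_edge=edge,
        )
        got = ca.min_distance_series(traj)["distance"].iloc[0]
        nt = traj.coords[0, traj.groups == "nt"]
        expected = min(
            brute_force_min_distance(nt, traj.coords[0, traj.groups == g], edge)
            for g in ("aa0", "aa1")
        )
        assert got == pytest.approx(expected)

    def test_translation_invariance(self):
        rng = np.random.default_rng(6)
        edge = 40.0
        coords = {"nt": rng.uniform(0, edge, (2, 3)), "aa0": rng.uniform(0, edge, (3, 3))}
        traj = make_traj(coords, edge)
        shift = rng.uniform(-100, 100, 3)
        shifted = make_traj({g: (c + shift) % edge for g, c in coords.items()}, edge)
        assert ca.min_distance_series(shifted)["distance"].iloc[0] == pytest.approx(
            ca.min_distance_series(traj)["distance"].iloc[0]
        )

    def test_empty_subset_rejected(self):
        traj = make_traj({"nt": [[0, 0, 0]], "aa0": [[1, 1, 1]]})
        with pytest.raises(ValueError, match="atom subset"):
            ca.min_distance_series(traj, atom_subset=[1])  # atom 1 is the amino acid


class TestBindingFraction:
    def test_all_below(self):
        df = pd.DataFrame({"run_id": 0, "frame": range(10), "distance": 4.9})
        assert ca.binding_fraction(df).raw_fraction == 1.0

    def test_threshold_zero(self):
        df = pd.DataFrame({"run_id": 0, "frame": range(10), "distance": 3.0})
        assert ca.binding_fraction(df, threshold=0.0).raw_fraction == 0.0

    def test_strictly_below(self):
        df = pd.DataFrame({"run_id": 0, "frame": [0, 1], "distance": [5.0, 4.999]})
        assert ca.binding_fraction(df, 5.0).raw_fraction == 0.5

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"run_id": 0, "frame": range(500), "distance": rng.uniform(0, 10, 500)})
        fracs = [ca.binding_fraction(df, t).raw_fraction for t in np.linspace(0, 12, 20)]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_pooled_equals_frame_weighted_mean(self):
        rng = np.random.default_rng(1)
        parts = []
        for run, n in enumerate((100, 300, 50)):
            parts.append(
                pd.DataFrame(
                    {"run_id": run, "frame": range(n), "distance": rng.uniform(0, 10, n)}
                )
            )
        df = pd.concat(parts, ignore_index=True)
        pooled = ca.binding_fraction(df, 5.0).raw_fraction
        per_run = df.groupby("run_id")["distance"].apply(lambda d: (d < 5).mean())
        sizes = df.groupby("run_id").size()
        assert pooled == pytest.approx((per_run * sizes).sum() / sizes.sum())

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ca.binding_fraction(pd.DataFrame(columns=["run_id", "frame", "distance"]))


class TestBootstrap:
    def test_identical_runs_zero_width(self):
        one = pd.DataFrame({"run_id": 0, "frame": range(20), "distance": [3.0] * 10 + [8.0] * 10})
        df = pd.concat(
            [one.assign(run_id=r) for r in range(5)], ignore_index=True
        )
        lo, hi = ca.bootstrap_ci(df, n_boot=200, seed=0)
        assert lo == hi == 0.5

    def test_single_run_rejected(self):
        df = pd.DataFrame({"run_id": 0, "frame": range(10), "distance": 3.0})
        with pytest.raises(ValueError, match="2 runs"):
            ca.bootstrap_ci(df)

    def test_bounds_in_unit_interval_and_deterministic(self):
        df = ca.gen_distance_series(ca.TwoStateParams(occupancy=0.3, n_runs=10, n_frames=200, seed=2))
        a = ca.bootstrap_ci(df, n_boot=500, seed=3)
        b = ca.bootstrap_ci(df, n_boot=500, seed=3)
        assert a == b
        assert 0.0 <= a[0] <= a[1] <= 1.0

    def test_interval_brackets_point_estimate(self):
        df = ca.gen_distance_series(ca.TwoStateParams(occupancy=0.3, n_runs=30, n_frames=300, seed=4))
        m = ca.measure_binding(df, n_boot=2000, seed=5)
        assert m.ci95[0] <= m.raw_fraction <= m.ci95[1]


class TestProximityHistogram:
    def test_uniform_distances(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {"run_id": 0, "frame": range(20000), "distance": rng.uniform(0, 10, 20000)}
        )
        h = ca.proximity_histogram(df, bin_width=1.0, r_max=10.0)
        np.testing.assert_allclose(h["frequency"], 0.1, atol=0.01)

    def test_sums_to_one(self):
        df = ca.gen_distance_series(ca.TwoStateParams(occupancy=0.4, n_runs=3, n_frames=500, seed=8))
        h = ca.proximity_histogram(df, bin_width=0.25)
        assert h["frequency"].sum() == pytest.approx(1.0)

    def test_mass_below_threshold_equals_binding_fraction(self):
        df = ca.gen_distance_series(ca.TwoStateParams(occupancy=0.35, n_runs=3, n_frames=500, seed=9))
        h = ca.proximity_histogram(df, bin_width=0.5, r_max=12.0)
        mass = h.loc[h["bin_right"] <= 5.0, "frequency"].sum()
        assert mass == pytest.approx(ca.binding_fraction(df, 5.0).raw_fraction)

    def test_volume_divisor_scales_bins(self):
        df = pd.DataFrame({"run_id": 0, "frame": range(10), "distance": 2.0})
        h0 = ca.proximity_histogram(df, bin_width=1.0, r_max=5.0)
        h1 = ca.proximity_histogram(df, bin_width=1.0, r_max=5.0, volume_divisor=0.5)
        np.testing.assert_allclose(h1["frequency"], h0["frequency"] / 0.5)
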