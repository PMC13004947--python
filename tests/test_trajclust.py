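"""Trajectory clustering, control spots, and inside/outside kinetics."""

import numpy as np
import pandas as pd
import pytest

from polclust.trajclust import (
    density_cluster,
    eps_elbow_scan,
    filter_hlb_like,
    inside_outside_kinetics,
    mean_positions,
    place_control_spots,
)

from conftest import make_table


def points_frame(xy):
    xy = np.asarray(xy, float)
    return pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1]})


def brute_force_dbscan(xy, eps, min_samples):
    """Density-reachability oracle: core sets and noise, by direct search."""
    n = len(xy)
    d = np.linalg.norm(xy[:, None] - xy[None, :], axis=2)
    neighbors = [set(np.nonzero(d[i] <= eps)[0]) for i in range(n)]
    core = {i for i in range(n) if len(neighbors[i]) >= min_samples}
    # connected components of core points (linked when within eps)
    comp = {}
    next_label = 0
    for i in sorted(core):
        if i in comp:
            continue
        stack = [i]
        comp[i] = next_label
        while stack:
            j = stack.pop()
            for k in neighbors[j] & core:
                if k not in comp:
                    comp[k] = next_label
                    stack.append(k)
        next_label += 1
    border = {i for i in range(n) if i not in core
              and any(j in core for j in neighbors[i])}
    noise = set(range(n)) - core - border
    core_partition = {}
    for i, lab in comp.items():
        core_partition.setdefault(lab, set()).add(i)
    return core, border, noise, set(map(frozenset, core_partition.values()))


class TestMeanPositions:
    def test_stationary_and_two_point_cases(self):
        table = make_table([[(1.0, 1.0), (1.0, 1.0)],
                            [(0.0, 0.0), (2.0, 0.0)]])
        mp = mean_positions(table)
        np.testing.assert_allclose(mp.loc[0], [1.0, 1.0])
        np.testing.assert_allclose(mp.loc[1], [1.0, 0.0])

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        pos = [rng.normal(size=(5, 2)) for _ in range(4)]
        base = mean_positions(make_table(pos))
        shifted = mean_positions(make_table([p + [2.0, -1.0] for p in pos]))
        np.testing.assert_allclose(shifted.to_numpy(),
                                   base.to_numpy() + [2.0, -1.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_positions(make_table([]))


class TestDensityCluster:
    def test_single_tight_blob_with_isolated_noise(self):
        rng = np.random.default_rng(1)
        blob = rng.uniform(-0.025, 0.025, size=(20, 2))
        lonely = np.column_stack([np.arange(20) * 1.5 + 5.0, np.zeros(20)])
        clusters, labels = density_cluster(
            points_frame(np.vstack([blob, lonely])))
        assert len(clusters) == 1
        assert clusters[0].n_members == 20
        assert (labels.iloc[20:] == -1).all()

    def test_blob_below_min_samples_is_noise(self):
        rng = np.random.default_rng(2)
        blob = rng.uniform(-0.02, 0.02, size=(10, 2))
        clusters, labels = density_cluster(points_frame(blob))
        assert clusters == [] and (labels == -1).all()

    def test_two_distant_blobs(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(-0.05, 0.05, size=(20, 2))
        b = rng.uniform(-0.05, 0.05, size=(20, 2)) + [5.0, 0.0]
        clusters, _ = density_cluster(points_frame(np.vstack([a, b])))
        assert len(clusters) == 2
        assert sorted(c.n_members for c in clusters) == [20, 20]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        xy = np.vstack([rng.uniform(-0.05, 0.05, size=(20, 2)),
                        rng.uniform(-0.05, 0.05, size=(25, 2)) + [3.0, 0.0]])
        perm = rng.permutation(len(xy))
        c1, _ = density_cluster(points_frame(xy))
        c2, _ = density_cluster(points_frame(xy[perm]))
        sets1 = {frozenset(map(tuple, np.round(xy[c.member_ids.astype(int)], 9)))
                 for c in c1}
        sets2 = {frozenset(map(tuple,
                               np.round(xy[perm][c.member_ids.astype(int)], 9)))
                 for c in c2}
        assert sets1 == sets2

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_reachability_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 101))
        # clumpy field so that clusters actually occur
        centers = rng.uniform(0, 3, size=(3, 2))
        xy = np.vstack([
            centers[rng.integers(3)] + rng.normal(scale=0.08, size=2)
            for _ in range(n)])
        eps, min_samples = 0.2, 8
        clusters, labels = density_cluster(points_frame(xy), eps=eps,
                                           min_samples=min_samples)
        core, border, noise, core_partition = brute_force_dbscan(
            xy, eps, min_samples)
        assert len(clusters) == len(core_partition)
        got_noise = set(np.nonzero(labels.to_numpy() == -1)[0])
        assert got_noise == noise
        got_core_partition = set()
        for lab in set(labels) - {-1}:
            members = set(np.nonzero(labels.to_numpy() == lab)[0])
            got_core_partition.add(frozenset(members & core))
        assert got_core_partition == core_partition

    def test_effective_radius_is_max_member_distance(self):
        xy = np.vstack([np.zeros((19, 2)), [[0.15, 0.0]]])
        clusters, _ = density_cluster(points_frame(xy))
        c = clusters[0]
        d = np.linalg.norm(xy - c.centroid, axis=1)
        assert c.radius == pytest.approx(d.max())


class TestEpsElbow:
    def test_single_blob_counts(self):
        rng = np.random.default_rng(5)
        blob = rng.uniform(-0.05, 0.05, size=(30, 2))
        scan = eps_elbow_scan(points_frame(blob), [0.001, 0.2, 0.5])
        assert scan["n_clusters"].tolist() == [0, 1, 1]

    def test_five_blob_field_stabilizes_at_five(self):
        rng = np.random.default_rng(6)
        centers = np.array([[0, 0], [5, 0], [0, 5], [5, 5], [10, 10]], float)
        xy = np.vstack([c + rng.normal(scale=0.04, size=(25, 2))
                        for c in centers])
        scan = eps_elbow_scan(points_frame(xy),
                              np.linspace(0.05, 1.0, 12))
        assert scan["n_clusters"].iloc[-1] == 5
        assert (scan["n_clusters"].iloc[6:] == 5).all()

    def test_decreasing_eps_rejected(self):
        with pytest.raises(ValueError):
            eps_elbow_scan(points_frame(np.zeros((5, 2))), [0.2, 0.1])


class TestControlSpots:
    @staticmethod
    def _clusters():
        rng = np.random.default_rng(7)
        xy = rng.uniform(-0.05, 0.05, size=(20, 2))
        clusters, _ = density_cluster(points_frame(xy))
        return clusters

    def test_thirty_valid_spots_in_large_nucleus(self):
        clusters = self._clusters()
        spots = place_control_spots(clusters, (0.0, 0.0), 5.0, seed=1)
        assert len(spots) == 30
        # every spot: inside mask, disjoint from clusters and other spots
        for i, s in enumerate(spots):
            assert np.hypot(*s.center) + s.radius <= 5.0 + 1e-9
            for c in clusters:
                assert np.linalg.norm(np.asarray(s.center) - c.centroid) \
                    >= s.radius + c.radius
            for t in spots[i + 1:]:
                assert np.linalg.norm(np.asarray(s.center) - np.asarray(t.center)) \
                    >= s.radius + t.radius

    def test_seed_reproducibility(self):
        clusters = self._clusters()
        s1 = place_control_spots(clusters, (0.0, 0.0), 5.0, seed=9)
        s2 = place_control_spots(clusters, (0.0, 0.0), 5.0, seed=9)
        assert s1 == s2

    def test_cramped_nucleus_partial_placement_warns(self):
        clusters = self._clusters()
        with pytest.warns(UserWarning, match="control spots"):
            spots = place_control_spots(clusters, (0.0, 0.0),
                                        clusters[0].radius * 2.5,
                                        seed=2, max_attempts=200)
        assert len(spots) < 30


class TestFilterHlbLike:
    def test_outsized_cluster_dropped(self):
        rng = np.random.default_rng(8)
        small = [rng.uniform(-0.04, 0.04, size=(20, 2)) + [i * 3.0, 0]
                 for i in range(4)]
        big = rng.uniform(-0.35, 0.35, size=(200, 2)) + [0, 6.0]
        clusters, _ = density_cluster(
            points_frame(np.vstack(small + [big])), eps=0.3)
        kept, dropped = filter_hlb_like(clusters, count_percentile=80,
                                        radius_percentile=80)
        assert len(dropped) == 1
        assert dropped[0].n_members == max(c.n_members for c in clusters)


class TestInsideOutside:
    def test_no_clusters_all_outside(self):
        pts = points_frame(np.random.default_rng(9).uniform(-1, 1, (50, 2)))
        state = np.zeros(50, int)
        table = inside_outside_kinetics(pts, state, [], [])
        assert table.loc["outside", "n_trajectories"] == 50
        assert table.loc["inside", "n_trajectories"] == 0

    def test_bound_enrichment_recovered(self):
        # bound trajectories concentrated in one disc; inside bound fraction
        # must exceed outside and roughly match construction
        rng = np.random.default_rng(10)
        n_in, n_out = 200, 800
        xy_in = rng.normal(scale=0.05, size=(n_in, 2))
        xy_out = rng.uniform(-3, 3, size=(n_out, 2))
        xy_out = xy_out[np.linalg.norm(xy_out, axis=1) > 0.5]
        pts = points_frame(np.vstack([xy_in, xy_out]))
        state = np.concatenate([
            (rng.random(n_in) > 0.7).astype(int),        # 70% bound inside
            (rng.random(len(xy_out)) > 0.3).astype(int),  # 30% bound outside
        ])
        from polclust.trajclust import TrajCluster
        cluster = TrajCluster(member_ids=np.arange(n_in),
                              centroid=np.zeros(2), radius=0.3)
        table = inside_outside_kinetics(pts, state, [cluster], [])
        fold = table.attrs["folds"]["inside_vs_outside"]
        assert table.loc["inside", "bound_fraction"] > \
            table.loc["outside", "bound_fraction"]
        assert fold.value == pytest.approx(0.7 / 0.3, rel=0.15)

    def test_uniform_field_control_fold_near_one(self):
        rng = np.random.default_rng(11)
        pts = points_frame(rng.uniform(-4, 4, (3000, 2)))
        state = (rng.random(3000) > 0.5).astype(int) * 0  # all bound
        from polclust.trajclust import ControlSpot, TrajCluster
        cluster = TrajCluster(member_ids=np.array([]),
                              centroid=np.array([1.0, 1.0]), radius=0.5)
        controls = [ControlSpot(center=(-2.0, -2.0), radius=0.5),
                    ControlSpot(center=(2.0, -2.0), radius=0.5)]
        table = inside_outside_kinetics(pts, state, [cluster], controls)
        fold = table.attrs["folds"]["inside_vs_control"]
        assert fold.value == pytest.approx(1.0, abs=1e-9)
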