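"""Volumetric cluster segmentation, HLB removal, lifetimes, mixture fit."""

import numpy as np
import pytest

from polclust.imaging import (
    SegmentedCluster,
    cluster_density,
    detect_hlbs,
    filter_by_enrichment,
    fit_lifetime_mixture,
    normalize_nucleus,
    segment_clusters,
    track_lifetimes,
)
from polclust.synthetic import NucleusMovieConfig, generate_nucleus_movie

VOXEL = (0.3, 0.108, 0.108)


def blob_volume(shape, centers_amps, sigma_um=0.3, baseline=1.0):
    """Nucleus-filling baseline with Gaussian blobs at voxel centers."""
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    vol = np.full(shape, baseline, float)
    for (cz, cy, cx), amp in centers_amps:
        d2 = (((zz - cz) * VOXEL[0]) ** 2 + ((yy - cy) * VOXEL[1]) ** 2
              + ((xx - cx) * VOXEL[2]) ** 2)
        vol += amp * np.exp(-d2 / (2 * sigma_um ** 2))
    return vol


def make_cluster(z, y, x, enrichment=2.0, frame=0, n_voxels=30):
    return SegmentedCluster(
        nucleus_id=0, frame=frame, label=1, centroid=(z, y, x),
        mean_enrichment=enrichment, integrated_intensity=enrichment * n_voxels,
        volume=n_voxels * np.prod(VOXEL), n_voxels=n_voxels)


class TestNormalize:
    def test_uniform_nucleus_maps_to_one(self):
        vol = np.full((6, 20, 20), 7.0)
        mask = np.zeros_like(vol, bool)
        mask[:, 5:15, 5:15] = True
        enr = normalize_nucleus(vol, mask)
        assert np.allclose(enr[mask], 1.0)
        assert np.all(enr[~mask] == 0)

    def test_mean_inside_mask_is_one(self):
        rng = np.random.default_rng(0)
        vol = rng.uniform(1, 5, (6, 20, 20))
        mask = np.zeros((6, 20, 20), bool)
        mask[1:5, 4:16, 4:16] = True
        enr = normalize_nucleus(vol, mask)
        assert enr[mask].mean() == pytest.approx(1.0, abs=1e-9)

    def test_blob_enrichment_matches_direct_arithmetic(self):
        shape = (10, 40, 40)
        vol = blob_volume(shape, [((5, 20, 20), 3.0)])
        mask = np.ones(shape, bool)
        enr = normalize_nucleus(vol, mask)
        assert enr[5, 20, 20] == pytest.approx(4.0 / vol.mean(), rel=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            normalize_nucleus(np.ones((2, 4, 4)), np.zeros((2, 4, 4), bool))


class TestSegmentClusters:
    def test_uniform_nucleus_no_clusters(self):
        vol = np.full((8, 32, 32), 1.0)
        mask = np.ones_like(vol, bool)
        assert segment_clusters(normalize_nucleus(vol, mask), mask) == []

    def test_single_blob_segmented_at_truth(self):
        shape = (12, 48, 48)
        vol = blob_volume(shape, [((6, 24, 24), 3.0)])
        mask = np.ones(shape, bool)
        clusters = segment_clusters(normalize_nucleus(vol, mask), mask)
        assert len(clusters) == 1
        c = clusters[0]
        truth_um = (6 * VOXEL[0], 24 * VOXEL[1], 24 * VOXEL[2])
        for got, want, v in zip(c.centroid, truth_um, VOXEL):
            assert abs(got - want) <= v  # within one voxel

    def test_touching_blobs_split_by_watershed(self):
        shape = (12, 64, 64)
        # centers 1.5 µm apart in y (~14 px)
        vol = blob_volume(shape, [((6, 25, 32), 3.0), ((6, 39, 32), 3.0)])
        mask = np.ones(shape, bool)
        clusters = segment_clusters(normalize_nucleus(vol, mask), mask)
        assert len(clusters) == 2

    def test_well_separated_blob_count_recovered(self):
        # segmentation count equals ground truth for separated bright blobs
        for seed in range(6):
            rng = np.random.default_rng(seed)
            n_blobs = int(rng.integers(1, 4))
            centers = []
            while len(centers) < n_blobs:
                c = (int(rng.integers(3, 9)), int(rng.integers(8, 56)),
                     int(rng.integers(8, 56)))
                if all(np.linalg.norm(np.subtract(c, o) * VOXEL) > 1.8
                       for o in centers):
                    centers.append(c)
            vol = blob_volume((12, 64, 64), [(c, 4.0) for c in centers],
                              sigma_um=0.25)
            mask = np.ones((12, 64, 64), bool)
            clusters = segment_clusters(normalize_nucleus(vol, mask), mask)
            assert len(clusters) == n_blobs, f"seed {seed}"


class TestHlbDetection:
    def test_two_bright_among_dim_blobs(self):
        shape = (12, 64, 64)
        bright = [((6, 12, 12), 12.0), ((6, 50, 50), 10.0)]
        dim = [((6, 12, 50), 2.0), ((6, 50, 12), 2.0), ((6, 31, 31), 2.0)]
        vol = blob_volume(shape, bright + dim)
        mask = np.ones(shape, bool)
        enr = normalize_nucleus(vol, mask)
        clusters = segment_clusters(enr, mask)
        hlbs, rest = detect_hlbs(enr, clusters)
        assert len(hlbs) == 2
        got = {tuple(int(round(c / v)) for c, v in zip(h.centroid, VOXEL))
               for h in hlbs}
        assert got == {(6, 12, 12), (6, 50, 50)}
        assert all(not c.is_hlb for c in rest)

    def test_flat_image_no_hlbs(self):
        clusters = [make_cluster(3.0 * 0.3, 1.0, 1.0)]
        flat = np.ones((8, 32, 32))
        hlbs, rest = detect_hlbs(flat, clusters)
        assert hlbs == [] and rest == clusters

    def test_at_most_two_flagged_among_three_bright(self):
        shape = (12, 64, 64)
        bright = [((6, 12, 12), 12.0), ((6, 50, 50), 10.0), ((6, 12, 50), 8.0)]
        vol = blob_volume(shape, bright)
        mask = np.ones(shape, bool)
        enr = normalize_nucleus(vol, mask)
        clusters = segment_clusters(enr, mask)
        hlbs, rest = detect_hlbs(enr, clusters)
        assert len(hlbs) == 2
        # the two flagged are the brightest of all segmented clusters
        flagged = sorted(h.mean_enrichment for h in hlbs)
        assert flagged == sorted(c.mean_enrichment for c in clusters)[-2:]
        assert min(flagged) >= max((c.mean_enrichment for c in rest),
                                   default=0.0)


class TestEnrichmentFilter:
    def test_threshold_behavior(self):
        low = make_cluster(1, 1, 1, enrichment=1.60)
        high = make_cluster(1, 1, 1, enrichment=1.70)
        assert filter_by_enrichment([low, high]) == [high]
        assert filter_by_enrichment([low, high], threshold=0.0) == [low, high]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        clusters = [make_cluster(1, 1, 1, enrichment=e)
                    for e in rng.uniform(1.0, 3.0, 30)]
        counts = [len(filter_by_enrichment(clusters, thr))
                  for thr in np.linspace(1.0, 3.0, 10)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestClusterDensity:
    def test_count_over_volume(self):
        assert cluster_density(range(12), 100.0) == pytest.approx(0.12)
        assert cluster_density([], 50.0) == 0.0
        assert cluster_density(range(6), 50.0) == \
            pytest.approx(2 * cluster_density(range(6), 100.0))

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            cluster_density([], 0.0)


class TestTrackLifetimes:
    def test_static_cluster_lifetime(self):
        frames = [[make_cluster(1.5, 2.0, 2.0, frame=f)] for f in range(10)]
        tracks = track_lifetimes(frames, frame_interval=10.0)
        assert len(tracks) == 1
        assert tracks[0].lifetime == 100.0
        assert tracks[0].normalized_lifetime == pytest.approx(1.0)

    def test_z_jump_terminates_track(self):
        frames = [[make_cluster(1.0, 2.0, 2.0, frame=0)],
                  [make_cluster(1.9, 2.0, 2.0, frame=1)]]  # 0.9 µm jump in z
        tracks = track_lifetimes(frames, frame_interval=10.0)
        assert len(tracks) == 2
        assert all(t.n_frames == 1 for t in tracks)

    def test_within_tolerance_links(self):
        frames = [[make_cluster(1.0, 2.0, 2.0, frame=0)],
                  [make_cluster(1.5, 2.1, 2.0, frame=1)]]  # dz=0.5, dxy=0.1
        tracks = track_lifetimes(frames, frame_interval=10.0)
        assert len(tracks) == 1 and tracks[0].n_frames == 2

    def test_known_birth_death_recovered_exactly(self):
        # two clusters with disjoint lifetimes at separated positions
        frames = []
        for f in range(12):
            fr = []
            if 2 <= f <= 7:
                fr.append(make_cluster(1.5, 1.0, 1.0, frame=f))
            if 5 <= f <= 11:
                fr.append(make_cluster(1.5, 4.0, 4.0, frame=f))
            frames.append(fr)
        tracks = track_lifetimes(frames, frame_interval=10.0)
        spans = sorted((t.start_frame, t.end_frame) for t in tracks)
        assert spans == [(2, 7), (5, 11)]
        assert sorted(t.lifetime for t in tracks) == [60.0, 70.0]

    def test_end_to_end_noise_free_movie_lifetimes_exact(self):
        cfg = NucleusMovieConfig(shape=(8, 14, 56, 56), n_clusters=2, n_hlbs=0,
                                 cluster_amplitude=4.0,
                                 background_noise_sigma=0.0, seed=13)
        movie, truth, mask = generate_nucleus_movie(cfg)
        # ground-truth blobs must be spatially separated for this check
        xy = truth[["z", "y", "x"]].to_numpy() * np.array(VOXEL)
        assert np.linalg.norm(xy[0] - xy[1]) > 1.5
        frames = []
        for t in range(movie.shape[0]):
            enr = normalize_nucleus(movie[t], mask)
            frames.append(segment_clusters(enr, mask, frame=t))
        tracks = track_lifetimes(frames, frame_interval=cfg.frame_interval)
        want = sorted(
            (int(r.birth_frame), min(int(r.death_frame), movie.shape[0] - 1))
            for r in truth.itertuples())
        got = sorted((t.start_frame, t.end_frame) for t in tracks)
        assert got == want


class TestLifetimeMixture:
    @staticmethod
    def _sample(n, w_short, means, sds, seed):
        rng = np.random.default_rng(seed)
        short = rng.random(n) < w_short
        x = np.where(short, rng.normal(means[0], sds[0], n),
                     rng.normal(means[1], sds[1], n))
        return np.clip(x, 0.1, None)

    def test_recovery_of_two_population_lifetimes(self):
        x = self._sample(300, 0.33, (2.0, 7.0), (0.8, 2.0), seed=1)
        fit = fit_lifetime_mixture(x, seed=0)
        assert fit.weight_long == pytest.approx(0.67, abs=0.05)
        assert fit.mean_short == pytest.approx(2.0, rel=0.15)
        assert fit.mean_long == pytest.approx(7.0, rel=0.15)
        assert fit.mean_short < fit.mean_long
        assert fit.weight_short + fit.weight_long == pytest.approx(1.0)

    def test_fixed_seed_identical_fit(self):
        x = self._sample(100, 0.4, (2.0, 8.0), (0.5, 1.5), seed=2)
        f1 = fit_lifetime_mixture(x, seed=5)
        f2 = fit_lifetime_mixture(x, seed=5)
        assert f1 == f2

    def test_single_population_degenerates_gracefully(self):
        rng = np.random.default_rng(3)
        x = rng.normal(5.0, 1.0, 200)
        fit = fit_lifetime_mixture(x, seed=0)
        # both components land on the single mode
        assert fit.mean_short == pytest.approx(5.0, abs=1.0)
        assert fit.mean_long == pytest.approx(5.0, abs=1.0)

    def test_too_few_lifetimes_rejected(self):
        with pytest.raises(ValueError):
            fit_lifetime_mixture(np.ones(10))

    def test_weight_uncertainty_matches_binomial_resimulation(self):
        # the sqrt(w(1-w)/n) formula vs the empirical spread of refits on
        # well-separated components, within 10%
        fits = [fit_lifetime_mixture(
            self._sample(300, 0.4, (2.0, 10.0), (0.5, 1.0), seed=s),
            seed=0, n_restarts=2).weight_long for s in range(200)]
        empirical_sd = np.std(fits)
        formula = np.sqrt(0.6 * 0.4 / 300)
        assert empirical_sd == pytest.approx(formula, rel=0.10)
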