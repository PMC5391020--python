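"""Data-driven VOI definition: feature matrix, silhouette k-selection, labeling."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from datspect.synthetic import CohortConfig, default_profiles, generate_cohort
from datspect.preprocess import standardize_to_reference
from datspect.voi import (
    VoxelFeatureMatrix,
    build_feature_matrix,
    define_vois,
    hemisphere_split,
    select_k_silhouette,
    voi_mean_uptake,
    voi_means_table,
)
from datspect.volume import STANDARDIZED, UptakeVolume


def _std(data):
    return UptakeVolume(np.asarray(data, float), units=STANDARDIZED)


# --------------------------------------------------------------------------
# brute-force oracle: exhaustive partitions, WCSS-optimal, hand silhouette
# --------------------------------------------------------------------------

def _partitions_into_k(n, k):
    """All assignments of n items into exactly k non-empty unlabeled blocks."""
    def rec(i, blocks):
        if i == n:
            if len(blocks) == k:
                yield [list(b) for b in blocks]
            return
        if len(blocks) + (n - i) < k:
            return
        for b in blocks:
            b.append(i)
            yield from rec(i + 1, blocks)
            b.pop()
        if len(blocks) < k:
            blocks.append([i])
            yield from rec(i + 1, blocks)
            blocks.pop()

    yield from rec(0, [])


def _wcss(points, blocks):
    return sum(
        float(((points[b] - points[b].mean(axis=0)) ** 2).sum()) for b in map(list, blocks)
    )


def _mean_silhouette(points, labels):
    """Hand silhouette: s = (b - a)/max(a, b); singleton clusters score 0."""
    n = len(points)
    dist = np.abs(points[:, None, 0] - points[None, :, 0]) if points.shape[1] == 1 else \
        np.linalg.norm(points[:, None] - points[None, :], axis=-1)
    svals = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            svals.append(0.0)
            continue
        a = dist[i, own].mean()
        b = min(
            dist[i, [j for j in range(n) if labels[j] == lab]].mean()
            for lab in set(labels) if lab != labels[i]
        )
        svals.append((b - a) / max(a, b))
    return float(np.mean(svals))


def _oracle_silhouettes(points, ks):
    out = {}
    for k in ks:
        best = min(_partitions_into_k(len(points), k),
                   key=lambda blocks: _wcss(points, blocks))
        labels = np.empty(len(points), int)
        for lab, block in enumerate(best):
            labels[block] = lab
        out[k] = _mean_silhouette(points, labels)
    kstar = max(sorted(out), key=lambda k: out[k])
    return kstar, out


class TestSelectK:
    def test_two_point_masses_select_k2(self):
        rng = np.random.default_rng(0)
        pts = np.concatenate([rng.normal(0, 0.05, (30, 2)),
                              rng.normal(20, 0.05, (30, 2))])
        k, sil = select_k_silhouette(pts, k_range=range(2, 6), seed=0)
        assert k == 2
        assert sil[2] > 0.95

    def test_matches_exhaustive_partition_oracle(self):
        """k-selection on a 6-point set equals the brute-force WCSS + silhouette oracle."""
        pts = np.array([[0.0], [0.1], [0.2], [10.0], [10.1], [20.0]])
        k_oracle, sil_oracle = _oracle_silhouettes(pts, (2, 3, 4))
        k_impl, sil_impl = select_k_silhouette(pts, k_range=(2, 3, 4), seed=0)
        assert k_impl == k_oracle
        for k in (2, 3, 4):
            assert sil_impl[k] == pytest.approx(sil_oracle[k], abs=1e-9)

    def test_three_blobs_recovered_across_seeds(self):
        """Three well-separated blobs give k* = 3 in >= 95% of seeded runs."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pts = np.concatenate([rng.normal(c, 0.1, (20, 1)) for c in (0.0, 10.0, 20.0)])
            k, _ = select_k_silhouette(pts, k_range=range(2, 5), n_init=5, seed=seed)
            hits += k == 3
        assert hits >= 95

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="more voxels"):
            select_k_silhouette(np.zeros((4, 2)), k_range=range(2, 8))


class TestFeatureMatrix:
    def test_shape_contract(self):
        mask = np.zeros((4, 4, 4), bool)
        mask.reshape(-1)[:10] = True
        scans = [_std(np.random.default_rng(i).normal(size=(4, 4, 4))) for i in range(5)]
        fm = build_feature_matrix(scans, mask)
        assert fm.values.shape == (10, 5)

    def test_rows_index_voxels_across_scans(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[1, 2, 3] = mask[0, 0, 0] = True
        scans = [_std(np.random.default_rng(i).normal(size=(4, 4, 4))) for i in range(3)]
        fm = build_feature_matrix(scans, mask)
        row = np.flatnonzero((fm.voxel_coords == [1, 2, 3]).all(axis=1))[0]
        np.testing.assert_array_equal(fm.values[row], [s.data[1, 2, 3] for s in scans])

    def test_grid_mismatch_rejected(self):
        scans = [_std(np.zeros((4, 4, 4))), _std(np.zeros((4, 4, 4)))]
        with pytest.raises(ValueError, match="mask shape"):
            build_feature_matrix(scans, np.ones((3, 3, 3), bool))


class TestDefineVois:
    def test_recovers_ground_truth_partition(self, default_run):
        """Cluster labels agree with the generator's dorsal/ventral truth (ARI > 0.9)."""
        vois = default_run.vois
        truth = default_run.cohort.truth_labels
        mask = vois.label_map > 0
        ari = adjusted_rand_score(truth[mask], vois.label_map[mask])
        assert ari > 0.9
        assert len(vois.vois) == 4
        assert sorted(v.name for v in vois.vois) == [
            "L_dorsal", "L_ventral", "R_dorsal", "R_ventral"]

    def test_labels_partition_the_mask(self, default_run):
        vois = default_run.vois
        mask = default_run.template.striatum_mask
        assert np.array_equal(vois.label_map > 0, mask)
        assert sum(v.n_voxels for v in vois.vois) == int(mask.sum())
        voxel_cc = np.prod(vois.voxel_size) / 1000.0
        for v in vois.vois:
            assert v.volume_cc == pytest.approx(v.n_voxels * voxel_cc)

    def test_seed_determinism(self, default_run):
        again = define_vois(default_run.std, default_run.template.striatum_mask, seed=42)
        assert np.array_equal(again.label_map, default_run.vois.label_map)
        assert again.k_selected == default_run.vois.k_selected

    def test_uniform_striatum_flagged_unstable(self):
        """A gradient-free striatum yields low silhouettes and an instability flag."""
        rng = np.random.default_rng(4)
        mask = np.zeros((10, 8, 8), bool)
        mask[1:4, 2:6, 2:6] = mask[6:9, 2:6, 2:6] = True
        scans = [_std(np.where(mask, 4.0, 0.0) + rng.normal(0, 0.3, mask.shape))
                 for _ in range(8)]
        vois = define_vois(scans, mask, k_range=range(2, 5), seed=0)
        assert not vois.stable
        assert all(max(d.values()) < 0.25 for d in vois.silhouette_by_k.values())

    def test_empty_hemisphere_rejected(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[6:8, 2:6, 2:6] = True  # right side only
        scans = [_std(np.random.default_rng(i).normal(size=(8, 8, 8))) for i in range(3)]
        with pytest.raises(ValueError, match="hemisphere"):
            define_vois(scans, mask, k_range=(2,), seed=0)

    def test_hemisphere_split_covers_mask(self):
        mask = np.random.default_rng(0).random((9, 5, 5)) > 0.5
        halves = hemisphere_split(mask)
        assert not np.any(halves["L"] & halves["R"])
        assert np.array_equal(halves["L"] | halves["R"], mask)


class TestVoiMeans:
    def test_constant_scan(self, default_run):
        scan = default_run.std[0].with_data(np.full(default_run.std[0].shape, 2.5))
        means = voi_mean_uptake(scan, default_run.vois)
        assert np.allclose(means, 2.5)

    def test_noise_free_subject_recovers_amplitude_exactly(self):
        """A noise-free PD subject's dorsal VOI mean equals the configured amplitude."""
        cfg = CohortConfig(
            n_per_group={"PD": 1, "NMC": 0, "NMNC": 1},
            noise_sd=0.0, background_sd=0.0, amplitude_between_subject_sd=0.0,
            grid_shape=(32, 32, 24), seed=0,
        )
        cohort = generate_cohort(cfg)
        scans = [s.volume.with_data(s.volume.data, units=STANDARDIZED)
                 for s in cohort.subjects]
        vois = define_vois(scans, cohort.striatum_mask, k_range=(2,), seed=0)
        pd_idx = [i for i, s in enumerate(cohort.subjects) if s.group == "PD"][0]
        means = voi_mean_uptake(scans[pd_idx], vois)
        profile = {p.name: p for p in default_profiles()}["PD"]
        # voxel values are bit-exact; the mean reduction may round the last ulp
        assert means["R_dorsal"] == pytest.approx(profile.amplitudes["R_dorsal"], rel=1e-14)
        assert means["L_ventral"] == pytest.approx(profile.amplitudes["L_ventral"], rel=1e-14)

    def test_means_table_shape(self, default_run):
        table = voi_means_table(default_run.std[:3], default_run.vois, ["a", "b", "c"])
        assert table.shape == (3, 4)
        assert list(table.index) == ["a", "b", "c"]
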