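"""Kabsch superposition and GROMOS conformational clustering."""

import numpy as np
import pytest

from tibind.clustering import (cluster_summary, extract_bound_frames,
                               gromos_cluster, kabsch_rmsd,
                               peptide_heavy_selection, rmsd_matrix)
from tibind.observables import profile_from_series


def quaternion_rmsd(X, Y):
    """Independent oracle: Horn's quaternion eigenvalue superposition."""
    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)
    R = X.T @ Y
    K = np.array([
        [R[0, 0] + R[1, 1] + R[2, 2], R[1, 2] - R[2, 1], R[2, 0] - R[0, 2], R[0, 1] - R[1, 0]],
        [R[1, 2] - R[2, 1], R[0, 0] - R[1, 1] - R[2, 2], R[0, 1] + R[1, 0], R[0, 2] + R[2, 0]],
        [R[2, 0] - R[0, 2], R[0, 1] + R[1, 0], R[1, 1] - R[0, 0] - R[2, 2], R[1, 2] + R[2, 1]],
        [R[0, 1] - R[1, 0], R[0, 2] + R[2, 0], R[1, 2] + R[2, 1], R[2, 2] - R[0, 0] - R[1, 1]],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    msd = max(((X ** 2).sum() + (Y ** 2).sum() - 2.0 * lam) / X.shape[0], 0.0)
    return np.sqrt(msd)


def gromos_oracle(matrix, cutoff):
    """Literal transcription of the neighbor-count procedure (brute force)."""
    n = matrix.shape[0]
    alive = list(range(n))
    clusters = []
    while alive:
        best, best_members = None, None
        for i in alive:
            members = [j for j in alive if matrix[i, j] <= cutoff or j == i]
            if best is None or len(members) > len(best_members):
                best, best_members = i, members
        clusters.append((best, sorted(best_members)))
        alive = [j for j in alive if j not in best_members]
    clusters.sort(key=lambda cm: (-len(cm[1]), cm[0]))
    return clusters


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


class TestKabsch:
    def test_identity_is_zero(self):
        X = np.random.default_rng(0).normal(size=(8, 3))
        assert kabsch_rmsd(X, X) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            X = rng.normal(size=(10, 3))
            Y = X @ random_rotation(rng).T + rng.normal(size=3)
            assert kabsch_rmsd(X, Y) == pytest.approx(0.0, abs=1e-10)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        X, Y = rng.normal(size=(2, 7, 3))
        assert kabsch_rmsd(X, Y) == pytest.approx(kabsch_rmsd(Y, X), abs=1e-12)

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = rng.integers(4, 30)
            X, Y = rng.normal(size=(2, n, 3))
            assert kabsch_rmsd(X, Y) == pytest.approx(quaternion_rmsd(X, Y),
                                                      abs=1e-10)

    def test_matches_mdanalysis_cross_check(self):
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd
        rng = np.random.default_rng(4)
        X, Y = rng.normal(size=(2, 12, 3))
        assert kabsch_rmsd(X, Y) == pytest.approx(
            mda_rmsd(Y, X, center=True, superposition=True), abs=1e-8)

    def test_mirror_not_superposed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 3))
        Y = X.copy()
        Y[:, 2] *= -1
        assert kabsch_rmsd(X, Y) > 0.1  # proper rotations only

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))


class TestRmsdMatrix:
    def test_identical_frames_zero(self, small_system):
        _, topo, frames, _ = small_system
        sel = peptide_heavy_selection(topo)
        mat, kept = rmsd_matrix([frames[0], frames[0]], sel, topology=topo)
        assert np.allclose(mat, 0.0, atol=1e-6)

    def test_consistent_with_pairwise_calls(self, small_system):
        _, topo, frames, _ = small_system
        from tibind.observables import unwrap_peptide
        sel = peptide_heavy_selection(topo)
        sub = frames[:4]
        mat, _ = rmsd_matrix(sub, sel, topology=topo)
        coords = [unwrap_peptide(f, topo)[sel] for f in sub]
        for i in range(4):
            for j in range(i + 1, 4):
                assert mat[i, j] == pytest.approx(
                    kabsch_rmsd(coords[i], coords[j]), abs=1e-9)
        assert np.allclose(mat, mat.T)

    def test_two_template_mixture_is_bimodal(self, benchmark, benchmark_profile):
        _, topo, frames, truth = benchmark
        bound, idx = extract_bound_frames(frames, benchmark_profile)
        sel = peptide_heavy_selection(topo)
        mat, kept = rmsd_matrix(bound[:60], sel, topology=topo)
        off = mat[np.triu_indices_from(mat, k=1)]
        # well-separated templates: within-template spread below half the
        # clustering cutoff, between-template distances above the cutoff
        cutoff = 0.15
        assert ((off < cutoff / 2) | (off > cutoff)).all()
        assert (off < cutoff / 2).any() and (off > cutoff).any()
        assert truth.template_rmsd[0, 1] > cutoff

    def test_empty_selection_rejected(self, small_system):
        _, topo, frames, _ = small_system
        with pytest.raises(ValueError, match="selection"):
            rmsd_matrix(frames[:2], np.array([], dtype=int), topology=topo)


class TestGromos:
    def test_all_within_cutoff_single_cluster(self):
        M = np.full((6, 6), 0.05)
        np.fill_diagonal(M, 0.0)
        res = gromos_cluster(M, 0.15)
        assert res.n_clusters == 1
        assert res.populations[0] == pytest.approx(100.0)

    def test_all_beyond_cutoff_singletons(self):
        M = np.full((5, 5), 0.9)
        np.fill_diagonal(M, 0.0)
        res = gromos_cluster(M, 0.15)
        assert res.n_clusters == 5
        assert all(len(m) == 1 for m in res.members)

    def test_populations_non_increasing_and_cover(self):
        rng = np.random.default_rng(6)
        M = rng.uniform(0, 0.4, size=(40, 40))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0.0)
        res = gromos_cluster(M, 0.15)
        assert (np.diff(res.populations) <= 1e-12).all()
        all_members = np.sort(np.concatenate(res.members))
        assert np.array_equal(all_members, np.arange(40))
        assert res.populations.sum() == pytest.approx(100.0)

    def test_matches_oracle_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            n = int(rng.integers(2, 60))
            M = rng.uniform(0, 0.35, size=(n, n))
            M = (M + M.T) / 2
            np.fill_diagonal(M, 0.0)
            res = gromos_cluster(M, 0.15)
            oracle = gromos_oracle(M, 0.15)
            assert [m.tolist() for m in res.members] == [m for _, m in oracle]
            assert res.centroids.tolist() == [c for c, _ in oracle]

    def test_nan_rejected(self):
        M = np.zeros((3, 3))
        M[0, 1] = M[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            gromos_cluster(M, 0.15)

    def test_asymmetric_rejected(self):
        M = np.zeros((3, 3))
        M[0, 1] = 0.3
        with pytest.raises(ValueError, match="symmetric"):
            gromos_cluster(M, 0.15)


class TestExtractAndSummary:
    def test_alternating_profile_every_other_frame(self, small_system):
        _, topo, frames, _ = small_system
        n = len(frames)
        ssd = np.where(np.arange(n) % 2 == 0, 0.5, 1.5)
        prof = profile_from_series(np.arange(n, dtype=float) * 10, ssd, np.ones(n))
        sub, idx = extract_bound_frames(frames, prof)
        assert idx.tolist() == list(range(0, n, 2))

    def test_never_bound_warns_empty(self, small_system):
        _, topo, frames, _ = small_system
        n = len(frames)
        prof = profile_from_series(np.arange(n, dtype=float), np.full(n, 2.0),
                                   np.ones(n))
        with pytest.warns(UserWarning, match="no bound frames"):
            sub, idx = extract_bound_frames(frames, prof)
        assert idx.size == 0

    def test_population_floor_filters_rows(self):
        n = 20
        prof = profile_from_series(np.arange(n, dtype=float),
                                   np.full(n, 0.5), np.linspace(0.5, 1.5, n))
        M = np.full((n, n), 0.9)
        np.fill_diagonal(M, 0.0)
        # cluster frames 0..10 together (55%), 11..16 together (30%), rest apart
        M[:11, :11] = 0.05
        M[11:17, 11:17] = 0.05
        res = gromos_cluster(M, 0.15, frame_ids=np.arange(n))
        table = cluster_summary(res, prof, population_floor_percent=10.0)
        assert len(table) == 2
        assert table["population_percent"].tolist() == pytest.approx([55.0, 30.0])
        assert table["eed_nm"].iloc[0] == pytest.approx(prof.eed[:11].mean())

    def test_representative_time_is_centroid_timestamp(self):
        n = 4
        prof = profile_from_series(np.array([0.0, 10.0, 20.0, 30.0]),
                                   np.full(n, 0.5), np.ones(n))
        M = np.zeros((n, n))
        res = gromos_cluster(M, 0.15, frame_ids=np.arange(n))
        table = cluster_summary(res, prof)
        assert table["representative_time_ps"].iloc[0] == \
            prof.times[res.frame_ids[res.centroids[0]]]
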