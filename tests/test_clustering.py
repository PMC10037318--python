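"""Backbone RMSD, Daura clustering (vs a brute-force oracle) and matching."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pepsurf import (
    Conformation,
    InputError,
    backbone_rmsd,
    cross_cluster_match,
    daura_cluster,
    daura_cluster_from_matrix,
    extract_backbone,
    gen_cluster_ensemble,
    pairwise_rmsd_matrix,
    random_templates,
)
from pepsurf.clustering import MATCHED, NEAR_MATCHED, UNMATCHED


def reference_daura(D, cutoff):
    """Maximally naive re-derivation of the greedy rule, recounting each round.

    Returns [(centroid, sorted members), ...] in extraction order.
    """
    n = D.shape[0]
    unassigned = set(range(n))
    out = []
    while unassigned:
        best, best_count = None, -1
        for i in sorted(unassigned):
            count = sum(1 for j in unassigned if D[i, j] <= cutoff or i == j)
            if count > best_count:
                best, best_count = i, count
        members = sorted(
            j for j in unassigned if D[best, j] <= cutoff or j == best
        )
        out.append((best, tuple(members)))
        unassigned -= set(members)
    return out


def random_conformation(rng, n_atoms=12, scale=3.0):
    return Conformation(coordinates=rng.normal(0, scale, size=(n_atoms, 3)))


class TestBackboneRMSD:
    def test_identity_is_zero(self, rng):
        a = random_conformation(rng)
        assert backbone_rmsd(a, a) == pytest.approx(0.0, abs=1e-12)
        assert backbone_rmsd(a, a, fit=False) == 0.0

    def test_rigid_motion_invariance(self, rng):
        a = random_conformation(rng)
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        b = Conformation(coordinates=a.coordinates @ R.T + [3.0, -2.0, 7.0])
        assert backbone_rmsd(a, b, fit=True) <= 1e-6
        assert backbone_rmsd(a, b, fit=False) > 1.0

    def test_symmetric_and_nonnegative(self, rng):
        a, b = random_conformation(rng), random_conformation(rng)
        assert backbone_rmsd(a, b) == pytest.approx(backbone_rmsd(b, a))
        assert backbone_rmsd(a, b) >= 0

    def test_atom_count_mismatch(self, rng):
        with pytest.raises(InputError, match="mismatch"):
            backbone_rmsd(random_conformation(rng, 4), random_conformation(rng, 5))

    def test_matches_mdanalysis_superposition(self, rng):
        """Independent cross-check against MDAnalysis's fitted RMSD."""
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd

        for _ in range(20):
            a, b = random_conformation(rng), random_conformation(rng)
            ours = backbone_rmsd(a, b, fit=True)
            theirs = mda_rmsd(a.coordinates, b.coordinates,
                              center=True, superposition=True)
            assert ours == pytest.approx(theirs, abs=1e-8)

    def test_four_atom_toys_match_rotation_search_oracle(self, rng):
        """Fitted RMSD equals a brute-force minimisation over rotations.

        The oracle samples 20k random rotations and polishes the best one with
        derivative-free simplex search over rotation vectors — no Kabsch
        algebra anywhere in its path.
        """
        from scipy.optimize import minimize

        for _ in range(5):
            a = random_conformation(rng, n_atoms=4)
            b = Conformation(coordinates=a.coordinates +
                             rng.normal(0, 1.0, size=(4, 3)))
            ours = backbone_rmsd(a, b, fit=True)
            P = a.coordinates - a.coordinates.mean(axis=0)
            Q = b.coordinates - b.coordinates.mean(axis=0)

            def rmsd_of(rotvec):
                R = Rotation.from_rotvec(rotvec).as_matrix()
                return float(np.sqrt(((P @ R.T - Q) ** 2).sum(axis=1).mean()))

            rots = Rotation.random(20000, rng=np.random.default_rng(5))
            cand = np.sqrt(
                ((np.einsum("rij,aj->rai", rots.as_matrix(), P) - Q) ** 2)
                .sum(axis=2).mean(axis=1)
            )
            best = rots[int(np.argmin(cand))].as_rotvec()
            refined = minimize(rmsd_of, best, method="Nelder-Mead",
                               options={"xatol": 1e-10, "fatol": 1e-12}).fun
            assert ours <= refined + 1e-9
            assert ours == pytest.approx(refined, abs=1e-6)

    def test_reflection_never_chosen(self, rng):
        """Mirror images do not fit to zero: the rotation stays proper."""
        a = random_conformation(rng, n_atoms=8)
        mirror = a.coordinates.copy()
        mirror[:, 0] *= -1
        b = Conformation(coordinates=mirror)
        assert backbone_rmsd(a, b, fit=True) > 0.5


class TestDauraCluster:
    def test_all_identical_one_cluster(self):
        conf = Conformation(coordinates=np.arange(12.0).reshape(4, 3))
        result = daura_cluster([conf] * 7, cutoff=2.0, fit=False)
        assert len(result.clusters) == 1
        assert result.clusters[0].centroid == 0
        assert result.clusters[0].population == 7

    def test_cutoff_below_min_pairwise_gives_singletons(self, rng):
        ensemble = [random_conformation(rng) for _ in range(6)]
        D = pairwise_rmsd_matrix(ensemble)
        tiny = 0.5 * D[D > 0].min()
        result = daura_cluster(ensemble, cutoff=tiny)
        assert result.populations() == [1] * 6
        assert [c.centroid for c in result.clusters] == list(range(6))

    def test_empty_and_bad_cutoff_rejected(self, rng):
        with pytest.raises(InputError):
            daura_cluster([], cutoff=2.0)
        with pytest.raises(InputError):
            daura_cluster([random_conformation(rng)], cutoff=-1.0)

    def test_partition_and_population_conservation(self, rng):
        ensemble = [random_conformation(rng, scale=1.2) for _ in range(40)]
        result = daura_cluster(ensemble, cutoff=2.0)
        all_members = [m for c in result.clusters for m in c.members]
        assert sorted(all_members) == list(range(40))
        assert sum(result.populations()) == 40
        pops = result.populations()
        assert pops == sorted(pops, reverse=True)
        for c in result.clusters:
            assert c.centroid in c.members

    def test_matches_brute_force_oracle_on_random_matrices(self):
        """Greedy extraction identical to the naive reference on 100 instances."""
        rng = np.random.default_rng(777)
        for _ in range(100):
            n = int(rng.integers(2, 11))
            X = rng.uniform(0, 4, size=(n, n))
            D = (X + X.T) / 2
            np.fill_diagonal(D, 0.0)
            cutoff = float(rng.uniform(0.5, 3.5))
            ours = daura_cluster_from_matrix(D, cutoff)
            ref = reference_daura(D, cutoff)
            got = sorted(
                ((c.centroid, tuple(sorted(c.members))) for c in ours.clusters)
            )
            assert got == sorted(ref)

    def test_tie_break_lowest_frame_index(self):
        # two disjoint pairs: (0,1) and (2,3); all counts tie at 2,
        # so frame 0 must be extracted first, then frame 2
        D = np.full((4, 4), 10.0)
        np.fill_diagonal(D, 0.0)
        D[0, 1] = D[1, 0] = 1.0
        D[2, 3] = D[3, 2] = 1.0
        result = daura_cluster_from_matrix(D, cutoff=2.0)
        assert [c.centroid for c in result.clusters] == [0, 2]

    def test_relabeling_frames_permutes_clusters_consistently(self, rng):
        """Permuting frames permutes the member sets, not the partition.

        Uses well-separated planted clusters of distinct sizes so the greedy
        neighbour counts are tie-free across clusters; within a cluster every
        member is an equivalent centroid, so member sets are the invariant.
        """
        templates = random_templates(3, n_atoms=24, seed=9, min_rmsd=8.0)
        ensemble, _ = gen_cluster_ensemble(templates, (0.5, 0.3, 0.2), 0.2, 30,
                                           seed=10)
        D = pairwise_rmsd_matrix(ensemble)
        perm = rng.permutation(30)
        base = daura_cluster_from_matrix(D, cutoff=2.0)
        permuted = daura_cluster_from_matrix(D[np.ix_(perm, perm)], cutoff=2.0)
        base_sets = sorted(tuple(sorted(c.members)) for c in base.clusters)
        mapped = sorted(
            tuple(sorted(int(perm[m]) for m in c.members))
            for c in permuted.clusters
        )
        assert mapped == base_sets

    def test_planted_clusters_recovered(self):
        templates = random_templates(3, n_atoms=30, seed=5, min_rmsd=6.0)
        weights = (0.5, 0.3, 0.2)
        ensemble, labels = gen_cluster_ensemble(templates, weights, 0.3, 300,
                                                seed=6)
        result = daura_cluster(ensemble, cutoff=2.0)
        assert len(result.clusters) == 3
        planted = sorted(np.bincount(labels), reverse=True)
        assert result.populations() == planted


class TestCrossClusterMatch:
    def test_self_match_diagonal(self, rng):
        ensemble = [random_conformation(rng, scale=1.2) for _ in range(30)]
        result = daura_cluster(ensemble, cutoff=2.5)
        report = cross_cluster_match(result, result, top_k=3)
        for pair in report.pairs:
            if pair.cluster_a == pair.cluster_b:
                assert pair.status == MATCHED
                assert pair.rmsd == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize(
        "rmsd,status", [(1.0, MATCHED), (2.0, MATCHED), (2.2, NEAR_MATCHED),
                        (2.4999, NEAR_MATCHED), (2.5, UNMATCHED), (3.0, UNMATCHED)]
    )
    def test_status_bands(self, rmsd, status, rng):
        """Centroid pairs placed at a known raw RMSD get the printed bands."""
        from pepsurf.clustering import Cluster, ClusterResult

        base = random_conformation(rng, n_atoms=9)
        # displacement with zero mean and no net rotation risk: compare unfitted
        delta = np.zeros((9, 3))
        delta[:, 2] = rmsd
        other = Conformation(coordinates=base.coordinates + delta)
        a = ClusterResult(clusters=[Cluster(0, (0,))], cutoff=2.0, n_frames=1,
                          centroid_coordinates=[base])
        b = ClusterResult(clusters=[Cluster(0, (0,))], cutoff=2.0, n_frames=1,
                          centroid_coordinates=[other])
        report = cross_cluster_match(a, b, top_k=1, fit=False)
        assert report.pairs[0].rmsd == pytest.approx(rmsd)
        assert report.pairs[0].status == status

    def test_fewer_clusters_than_top_k_warns(self, rng):
        ensemble = [random_conformation(rng) for _ in range(4)]
        result = daura_cluster(ensemble, cutoff=100.0)  # one cluster
        report = cross_cluster_match(result, result, top_k=5)
        assert report.warning is not None
        assert len(report.pairs) == 1


class TestExtractBackbone:
    def test_backbone_selection(self, simple_system):
        traj = simple_system([6.0, 9.0])
        confs = extract_backbone(traj, atom_names=("CA",))
        assert len(confs) == 2
        assert confs[0].n_atoms == 1

    def test_missing_backbone_raises(self, simple_system):
        with pytest.raises(InputError, match="backbone"):
            extract_backbone(simple_system([6.0]), atom_names=("N",))
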