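"""Correlation networks, bundle-relative RMSD and ensemble summaries."""

import numpy as np
import pytest

from rockbundle.analysis import (
    allosteric_path,
    build_network,
    bundle_relative_rmsd,
    contact_mask,
    correlation_matrix,
    ensemble_summary,
    interbundle_coupling_score,
    strongest_edges,
)
from rockbundle.colvars import AtomGroup, CVSpec


def _anchored_frames(motions, n_extra_anchor=3, seed=0):
    """Frames: static anchor atoms (for alignment) + moving nodes.

    ``motions``: (F, M, 3) displacements of the M moving nodes about a base.
    """
    rng = np.random.default_rng(seed)
    F, M, _ = motions.shape
    anchors = rng.normal(size=(n_extra_anchor, 3)) * 3
    base = rng.normal(size=(M, 3)) * 3 + 10
    frames = np.empty((F, n_extra_anchor + M, 3))
    for f in range(F):
        frames[f, :n_extra_anchor] = anchors
        frames[f, n_extra_anchor:] = base + motions[f]
    return frames


class TestCorrelationMatrix:
    def test_identical_motion_perfectly_correlated(self):
        t = np.linspace(0, 2 * np.pi, 40)
        disp = 0.5 * np.sin(t)[:, None] * np.array([1.0, 0.0, 0.0])
        motions = np.stack([disp, disp], axis=1)
        frames = _anchored_frames(motions)
        C = correlation_matrix(frames, AtomGroup((0, 1, 2)))
        assert C[3, 4] == pytest.approx(1.0, abs=1e-10)

    def test_antiphase_motion(self):
        t = np.linspace(0, 2 * np.pi, 40)
        disp = 0.5 * np.sin(t)[:, None] * np.array([1.0, 0.0, 0.0])
        motions = np.stack([disp, -disp], axis=1)
        frames = _anchored_frames(motions)
        C = correlation_matrix(frames, AtomGroup((0, 1, 2)))
        assert C[3, 4] == pytest.approx(-1.0, abs=1e-10)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        frames = rng.normal(size=(25, 5, 3)).cumsum(axis=0) * 0.1
        fit = AtomGroup((0, 1, 2, 3, 4))
        C = correlation_matrix(frames, fit)
        # longhand oracle: same alignment path, explicit frame-by-frame sums
        from rockbundle.analysis import align_frames

        aligned = align_frames(frames, fit)
        mean = aligned.mean(axis=0)
        n = frames.shape[1]
        oracle = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                num = np.mean(
                    [
                        np.dot(aligned[f, i] - mean[i], aligned[f, j] - mean[j])
                        for f in range(frames.shape[0])
                    ]
                )
                vi = np.mean(
                    [np.dot(aligned[f, i] - mean[i], aligned[f, i] - mean[i])
                     for f in range(frames.shape[0])]
                )
                vj = np.mean(
                    [np.dot(aligned[f, j] - mean[j], aligned[f, j] - mean[j])
                     for f in range(frames.shape[0])]
                )
                oracle[i, j] = num / np.sqrt(vi * vj)
        assert np.abs(C - oracle).max() < 1e-10

    def test_zero_variance_node_raises(self):
        # static alignment anchors (identity fit), one moving node, and one
        # static node outside the fit group: the latter is degenerate
        rng = np.random.default_rng(0)
        anchors = rng.normal(size=(3, 3))
        frames = np.zeros((15, 5, 3))
        frames[:, :3] = anchors
        frames[:, 3] = np.array([5.0, 0.0, 0.0])  # static, not in fit group
        frames[:, 4] = np.array([0.0, 5.0, 0.0]) + rng.normal(0, 0.1, (15, 3))
        with pytest.raises(ValueError, match="zero-variance.*\\[3\\]"):
            correlation_matrix(frames, AtomGroup((0, 1, 2)))

    def test_needs_ten_frames(self):
        with pytest.raises(ValueError):
            correlation_matrix(np.zeros((5, 3, 3)), AtomGroup((0, 1, 2)))


class TestContactMask:
    def test_static_pair_within_cutoff(self):
        frames = np.zeros((10, 2, 3))
        frames[:, 1, 0] = 5.0
        M = contact_mask(frames, cutoff=8.0, occupancy=0.75)
        assert M[0, 1] and M[1, 0] and not M[0, 0]

    def test_occupancy_threshold(self):
        frames = np.zeros((10, 2, 3))
        frames[:5, 1, 0] = 5.0  # inside cutoff half the time
        frames[5:, 1, 0] = 20.0
        assert not contact_mask(frames, cutoff=8.0, occupancy=0.75)[0, 1]
        assert contact_mask(frames, cutoff=8.0, occupancy=0.5)[0, 1]

    def test_engineered_occupancies(self):
        frames = np.zeros((10, 3, 3))
        frames[:, 1, 0] = 5.0
        frames[:6, 2, 0] = 5.0  # 0.6 occupancy
        frames[6:, 2, 0] = 50.0
        frames[:8, 2, 1] = 0.0
        M6 = contact_mask(frames, cutoff=8.0, occupancy=0.6)
        M7 = contact_mask(frames, cutoff=8.0, occupancy=0.75)
        assert M6[0, 2] and not M7[0, 2]
        assert M6[0, 1] and M7[0, 1]


class TestNetwork:
    def test_chain_with_perfect_correlation(self):
        n = 4
        C = np.eye(n)
        M = np.zeros((n, n), bool)
        for i in range(n - 1):
            C[i, i + 1] = C[i + 1, i] = 1.0
            M[i, i + 1] = M[i + 1, i] = True
        net = build_network(C, M)
        path = allosteric_path(net, 0, 3)
        assert path == [0, 1, 2, 3]
        total = sum(
            net.graph[a][b]["weight"] for a, b in zip(path, path[1:])
        )
        assert total == pytest.approx(0.0, abs=1e-12)

    def test_disconnected_returns_none(self):
        C = np.eye(4)
        C[0, 1] = C[1, 0] = 0.9
        C[2, 3] = C[3, 2] = 0.9
        M = np.zeros((4, 4), bool)
        M[0, 1] = M[1, 0] = M[2, 3] = M[3, 2] = True
        net = build_network(C, M)
        assert allosteric_path(net, 0, 3) is None

    def test_path_matches_exhaustive_enumeration(self):
        # 6-node weighted fixture vs brute force over all simple paths
        import itertools

        rng = np.random.default_rng(11)
        n = 6
        C = np.eye(n)
        M = np.zeros((n, n), bool)
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.7:
                    c = rng.uniform(0.1, 0.99)
                    C[i, j] = C[j, i] = c
                    M[i, j] = M[j, i] = True
        net = build_network(C, M)
        got = allosteric_path(net, 0, 5)
        best, best_w = None, np.inf
        for r in range(2, n + 1):
            for perm in itertools.permutations(range(1, n - 1), r - 2):
                path = (0, *perm, 5)
                if all(M[a][b] for a, b in zip(path, path[1:])):
                    w = sum(-np.log(abs(C[a][b])) for a, b in zip(path, path[1:]))
                    if w < best_w - 1e-12:
                        best, best_w = list(path), w
        assert got == best

    def test_strongest_edges_sorted(self):
        C = np.eye(3)
        C[0, 1] = C[1, 0] = -0.9
        C[1, 2] = C[2, 1] = 0.5
        M = ~np.eye(3, dtype=bool)
        net = build_network(C, M)
        edges = strongest_edges(net, 2)
        assert edges[0][:2] == (0, 1) and edges[0][2] == pytest.approx(-0.9)
        assert edges[1][2] == pytest.approx(0.5)

    def test_weights_nonnegative_and_monotone_under_edge_addition(self):
        rng = np.random.default_rng(5)
        n = 6
        C = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                C[i, j] = C[j, i] = rng.uniform(0.05, 0.95)
        M1 = np.zeros((n, n), bool)
        for i in range(n - 1):
            M1[i, i + 1] = M1[i + 1, i] = True
        M2 = M1.copy()
        M2[0, 3] = M2[3, 0] = True
        net1, net2 = build_network(C, M1), build_network(C, M2)
        assert all(d["weight"] >= 0 for _, _, d in net1.graph.edges(data=True))
        import networkx as nx

        d1 = nx.dijkstra_path_length(net1.graph, 0, 5)
        d2 = nx.dijkstra_path_length(net2.graph, 0, 5)
        assert d2 <= d1 + 1e-12


class TestCouplingScore:
    def test_identical_motion_scores_one(self, small_system):
        structure, refs = small_system
        n = structure.n_atoms
        C = np.ones((n, n))
        M = np.ones((n, n), bool)
        np.fill_diagonal(M, False)
        net = build_network(C, M)
        score, n_edges = interbundle_coupling_score(net, structure)
        assert score == pytest.approx(1.0)
        assert n_edges > 0

    def test_block_diagonal_scores_zero(self, small_system):
        structure, refs = small_system
        n = structure.n_atoms
        C = np.eye(n)
        b1 = set(structure.bundle_atoms(1).tolist())
        for i in range(n):
            for j in range(n):
                same = (i in b1) == (j in b1)
                C[i, j] = 1.0 if same else 1e-8
        np.fill_diagonal(C, 1.0)
        M = np.ones((n, n), bool)
        np.fill_diagonal(M, False)
        net = build_network(C, M)
        score, _ = interbundle_coupling_score(net, structure)
        assert score < 1e-6

    def test_no_edges_warns_and_zero(self, small_system):
        structure, _ = small_system
        n = structure.n_atoms
        net = build_network(np.eye(n), np.zeros((n, n), bool))
        with pytest.warns(UserWarning):
            score, n_edges = interbundle_coupling_score(net, structure)
        assert score == 0.0 and n_edges == 0


class TestBundleRelativeRmsd:
    def test_reference_trajectory_zero(self, small_system):
        structure, refs = small_system
        frames = np.repeat(refs.of_coords[None], 5, axis=0)
        series = bundle_relative_rmsd(frames, structure, refs, 1, 2)
        assert np.allclose(series, 0.0, atol=1e-10)

    def test_pure_rocking_self_vs_other_fit(self, small_system):
        structure, refs = small_system
        frames = np.stack([refs.of_coords, refs.if_coords])
        self_fit = bundle_relative_rmsd(frames, structure, refs, 1, 1)
        other_fit = bundle_relative_rmsd(frames, structure, refs, 1, 2)
        assert self_fit[1] < 1e-8  # bundle 1 is internally rigid under rocking
        assert other_fit[1] > 1.0

    def test_self_fit_mean_not_worse(self, small_system, rng):
        structure, refs = small_system
        frames = refs.of_coords[None] + rng.normal(
            0, 0.3, size=(6, structure.n_atoms, 3)
        )
        self_fit = bundle_relative_rmsd(frames, structure, refs, 1, 1)
        other_fit = bundle_relative_rmsd(frames, structure, refs, 1, 2)
        assert self_fit.mean() <= other_fit.mean() + 1e-12


class TestEnsembleSummary:
    def test_constant_trajectory(self, small_system):
        structure, refs = small_system
        frames = np.repeat(refs.of_coords[None], 8, axis=0)
        spec = CVSpec(
            kind="com_distance",
            group=structure.bundle_group(1),
            group_b=structure.bundle_group(2),
            name="d",
        )
        summ = ensemble_summary(frames, [spec], {"d": 1.0})
        assert summ.sds["d"] == 0.0
        dens, edges = summ.histograms["d"]
        assert len(dens) == 1 and dens[0] == pytest.approx(1.0)

    def test_histogram_mass_one(self, small_system, rng):
        structure, refs = small_system
        frames = refs.of_coords[None] + rng.normal(
            0, 0.2, size=(40, structure.n_atoms, 3)
        )
        spec = CVSpec(kind="radius_of_gyration", group=structure.bundle_group(1),
                      name="rg")
        summ = ensemble_summary(frames, [spec])
        dens, _ = summ.histograms["rg"]
        assert dens.sum() == pytest.approx(1.0, abs=1e-12)

    def test_reference_delta(self, small_system, rng):
        structure, refs = small_system
        frames = np.repeat(refs.of_coords[None], 12, axis=0)
        spec = CVSpec(kind="radius_of_gyration", group=structure.bundle_group(1),
                      name="rg")
        ref_val = 3.0
        summ = ensemble_summary(frames, [spec], {"rg": ref_val})
        assert summ.reference_deltas["rg"] == pytest.approx(
            abs(summ.means["rg"] - ref_val)
        )
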