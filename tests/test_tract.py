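"""Spectral tract parameterization: thresholding, graphs, Fiedler vector,
orientation, segmentation, box ROIs."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.stats import spearmanr

from aftractometry.tract import (
    TractModel,
    VoxelGraph,
    build_voxel_graph,
    fiedler_vector,
    largest_component,
    orient_and_normalize,
    restrict_core,
    segment_labels,
    threshold_density,
)
from aftractometry.volume import ScalarVolume, center_ras_affine, make_box_roi

from conftest import node_values


def line_mask(n, axis=1):
    shape = [3, 3, 3]
    shape[axis] = n + 2
    m = np.zeros(shape, dtype=np.uint8)
    idx = [1, 1, 1]
    for i in range(n):
        idx[axis] = i + 1
        m[tuple(idx)] = 1
    return ScalarVolume(m, np.eye(4))


def graph_from_adjacency(adj):
    """Wrap an arbitrary symmetric adjacency as a VoxelGraph for the eigensolver."""
    adj = sp.csr_matrix(adj)
    n = adj.shape[0]
    n_comp, labels = connected_components(adj, directed=False)
    return VoxelGraph(
        nodes=np.zeros((n, 3), dtype=int),
        adjacency=adj,
        shape=(n, 1, 1),
        connectivity=26,
        component_labels=labels,
        n_components=n_comp,
    )


def path_graph_fiedler_closed_form(n):
    """Unit eigenvector cos(pi (i + 1/2) / n) of the path-graph Laplacian."""
    v = np.cos(np.pi * (np.arange(n) + 0.5) / n)
    return v / np.linalg.norm(v)


class TestThresholdDensity:
    def test_threshold_keeps_boundary_value(self):
        d = np.zeros((3, 3, 3))
        d[0, 0, 0], d[1, 1, 1], d[2, 2, 2] = 5, 20, 200
        mask = threshold_density(ScalarVolume(d, np.eye(4)), 0.10)
        assert mask.data[1, 1, 1] == 1 and mask.data[2, 2, 2] == 1
        assert mask.data[0, 0, 0] == 0

    def test_uniform_map_fully_kept(self):
        mask = threshold_density(ScalarVolume(np.full((4, 4, 4), 3.0), np.eye(4)))
        assert mask.data.sum() == 64

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_fraction(self, fraction):
        with pytest.raises(ValueError):
            threshold_density(ScalarVolume(np.ones((2, 2, 2)), np.eye(4)), fraction)

    def test_all_zero_density_is_empty_tract(self):
        with pytest.raises(ValueError, match="empty tract"):
            threshold_density(ScalarVolume(np.zeros((2, 2, 2)), np.eye(4)))


class TestRestrictCore:
    def test_limits_beyond_bounding_box_are_noop(self, fitted_tract):
        mask = fitted_tract.mask
        out = restrict_core(mask, y_max=1000.0, z_min=-1000.0)
        np.testing.assert_array_equal(out.data, mask.data)

    def test_straight_tube_half_survives_z_limit(self):
        # tube along z covering z in [0, 80] mm on a unit-spacing grid
        m = np.zeros((3, 3, 81), dtype=np.uint8)
        m[1, 1, :] = 1
        vol = ScalarVolume(m, np.eye(4))
        out = restrict_core(vol, z_min=40.0)
        kept = np.argwhere(out.data)
        assert kept[:, 2].min() == 40 and kept[:, 2].max() == 80

    def test_matches_brute_force_coordinate_filter(self, fitted_tract):
        mask = fitted_tract.mask
        y_max, z_min = 20.0, -10.0
        out = restrict_core(mask, y_max=y_max, z_min=z_min)
        idx = np.argwhere(mask.data.astype(bool))
        keep = []
        for ijk in idx:  # brute-force per-voxel affine oracle
            xyz = mask.affine[:3, :3] @ ijk + mask.affine[:3, 3]
            keep.append(xyz[1] <= y_max and xyz[2] >= z_min)
        assert out.data.sum() == int(np.sum(keep))

    def test_emptying_restriction_names_limits(self, fitted_tract):
        with pytest.raises(ValueError, match="y_max=-1000.0"):
            restrict_core(fitted_tract.mask, y_max=-1000.0, z_min=None)

    def test_voxel_index_units(self):
        m = np.ones((4, 4, 4), dtype=np.uint8)
        out = restrict_core(ScalarVolume(m, 2 * np.eye(4)), z_min=2.0, units="voxel")
        assert out.data.sum() == 4 * 4 * 2


class TestVoxelGraph:
    def test_three_voxel_row_is_path_graph(self):
        g = build_voxel_graph(line_mask(3), connectivity=6)
        assert g.n_nodes == 3 and g.n_edges == 2 and g.n_components == 1

    def test_2x2x2_block_is_complete_under_26(self):
        m = np.zeros((4, 4, 4), dtype=np.uint8)
        m[1:3, 1:3, 1:3] = 1
        g = build_voxel_graph(ScalarVolume(m, np.eye(4)), connectivity=26)
        assert g.n_nodes == 8 and g.n_edges == 28  # complete K8

    def test_gap_gives_two_components(self):
        m = np.zeros((9, 3, 3), dtype=np.uint8)
        m[0:2, 1, 1] = 1
        m[6:9, 1, 1] = 1
        g = build_voxel_graph(ScalarVolume(m, np.eye(4)), connectivity=26)
        assert g.n_components == 2
        reduced = largest_component(g, min_fraction=0.5)
        assert reduced.n_nodes == 3

    def test_largest_component_refuses_fragmented_mask(self):
        m = np.zeros((9, 3, 3), dtype=np.uint8)
        m[0, 1, 1] = 1
        m[4, 1, 1] = 1
        m[8, 1, 1] = 1
        g = build_voxel_graph(ScalarVolume(m, np.eye(4)))
        with pytest.raises(ValueError, match="refusing"):
            largest_component(g)

    def test_single_voxel_is_edgeless(self):
        g = build_voxel_graph(line_mask(1))
        assert g.n_nodes == 1 and g.n_edges == 0

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError):
            build_voxel_graph(line_mask(3), connectivity=8)


class TestFiedler:
    def test_path3_closed_form(self):
        g = build_voxel_graph(line_mask(3), connectivity=6)
        lam, v = fiedler_vector(g)
        assert lam == pytest.approx(1.0, abs=1e-10)
        expected = np.array([1.0, 0.0, -1.0]) / np.sqrt(2)
        dev = min(np.abs(v - expected).max(), np.abs(v + expected).max())
        assert dev < 1e-8

    @pytest.mark.parametrize("n", [5, 20, 101, 200])
    def test_path_n_matches_cosine_closed_form(self, n):
        g = build_voxel_graph(line_mask(n), connectivity=6)
        lam, v = fiedler_vector(g)
        assert lam == pytest.approx(2 * (1 - np.cos(np.pi / n)), rel=1e-9)
        expected = path_graph_fiedler_closed_form(n)
        dev = min(np.abs(v - expected).max(), np.abs(v + expected).max())
        assert dev < 1e-6

    def test_long_path_uses_sparse_solver_and_matches_closed_form(self):
        n = 700  # beyond the dense cutoff
        g = build_voxel_graph(line_mask(n), connectivity=6)
        lam, v = fiedler_vector(g)
        expected = path_graph_fiedler_closed_form(n)
        dev = min(np.abs(v - expected).max(), np.abs(v + expected).max())
        assert dev < 1e-6

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_graph_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        a = (rng.random((n, n)) < 0.15).astype(float)
        a = np.triu(a, 1)
        a[np.arange(n - 1), np.arange(1, n)] = 1  # ensure connectivity via a path
        a = a + a.T
        g = graph_from_adjacency(a)
        lam, v = fiedler_vector(g)
        # independent dense oracle built directly from the adjacency
        lap = np.diag(a.sum(1)) - a
        w, vecs = np.linalg.eigh(lap)
        assert lam == pytest.approx(w[1], abs=1e-8)
        oracle = vecs[:, 1] / np.linalg.norm(vecs[:, 1])
        dev = min(np.abs(v - oracle).max(), np.abs(v + oracle).max())
        assert dev < 1e-6

    def test_disconnected_graph_rejected(self):
        m = np.zeros((9, 3, 3), dtype=np.uint8)
        m[0:2, 1, 1] = 1
        m[6:9, 1, 1] = 1
        g = build_voxel_graph(ScalarVolume(m, np.eye(4)))
        with pytest.raises(ValueError, match="disconnected"):
            fiedler_vector(g)

    def test_permutation_invariance_of_t_field(self, fitted_tract):
        """Relabeling voxel order leaves t as a field over space unchanged."""
        g = fitted_tract.graph
        rng = np.random.default_rng(5)
        perm = rng.permutation(g.n_nodes)
        gp = VoxelGraph(
            nodes=g.nodes[perm],
            adjacency=g.adjacency[perm][:, perm].tocsr(),
            shape=g.shape,
            connectivity=g.connectivity,
            component_labels=g.component_labels[perm],
            n_components=g.n_components,
        )
        _, v = fiedler_vector(gp)
        t = orient_and_normalize(v, gp.nodes, fitted_tract.mask.affine)
        np.testing.assert_allclose(t, fitted_tract.t[perm], atol=1e-6)


class TestOrientAndSegment:
    def test_straight_tube_t_zero_at_anterior_end(self, straight_tube):
        density, _ = straight_tube
        fit = TractModel(density, anchor="frontal").fit()
        y = density.voxel_to_mm(fit.graph.nodes)[:, 1]
        # t = 0 must sit at the most anterior (greatest y) end
        assert y[np.argmin(fit.t)] > y[np.argmax(fit.t)]
        assert fit.t.min() == 0.0 and fit.t.max() == 1.0

    def test_sign_invariance_under_negated_eigenvector(self, fitted_tract):
        g = fitted_tract.graph
        _, v = fiedler_vector(g)
        affine = fitted_tract.mask.affine
        t1 = orient_and_normalize(v, g.nodes, affine)
        t2 = orient_and_normalize(-v, g.nodes, affine)
        np.testing.assert_allclose(t1, t2, atol=1e-12)

    def test_constant_raw_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            orient_and_normalize(np.ones(10), np.zeros((10, 3), dtype=int), np.eye(4))

    def test_segment_label_examples(self):
        labels = segment_labels(np.array([0.0, 0.5, 1.0]), 15)
        np.testing.assert_array_equal(labels, [1, 8, 15])

    def test_t_exactly_one_maps_to_k(self):
        assert segment_labels(np.array([1.0]), 15)[0] == 15

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            segment_labels(np.array([0.5]), 1)

    def test_labels_are_function_of_t_and_idempotent(self, fitted_tract):
        again = segment_labels(fitted_tract.t, fitted_tract.n_segments)
        np.testing.assert_array_equal(again, fitted_tract.labels)

    def test_uniform_straight_tube_has_balanced_segments(self, straight_tube):
        density, _ = straight_tube
        fit = TractModel(density, n_segments=15).fit()
        counts = fit.segment_voxel_counts()
        # one 2 mm column of the tube cross-section
        column = np.max(np.bincount(fit.graph.nodes[:, 1]))
        assert counts.max() - counts.min() <= column


class TestPhantomRecovery:
    def test_monotone_recovery_on_curved_phantom(self, fitted_tract, phantom):
        _, _, t_truth = phantom
        tt = node_values(t_truth, fitted_tract.graph.nodes)
        rho = spearmanr(fitted_tract.t, tt).statistic
        assert rho >= 0.99

    def test_all_fifteen_segments_populated(self, fitted_tract):
        assert (fitted_tract.segment_voxel_counts() > 0).all()


class TestBoxRoi:
    def test_af_seed_box_voxel_count_on_1mm_grid(self):
        # closed box [-42,-30] x [-38,-37] x [20,34] on an integer-mm grid
        shape = (100, 100, 100)
        affine = np.eye(4)
        affine[:3, 3] = -50.0
        roi = make_box_roi(shape, affine, (-42, -30), (-38, -37), (20, 34))
        assert int(roi.data.sum()) == 13 * 2 * 15

    def test_zero_extent_box_is_single_voxel(self):
        affine = np.eye(4)
        roi = make_box_roi((5, 5, 5), affine, (2, 2), (2, 2), (2, 2))
        assert int(roi.data.sum()) == 1

    def test_2mm_grid_matches_brute_force(self):
        shape = (30, 30, 30)
        affine = center_ras_affine(shape, 2.0)
        box = ((-11.0, 4.0), (-38.0, -37.0), (0.0, 13.0))
        roi = make_box_roi(shape, affine, *box)
        count = 0
        for i in range(shape[0]):
            for j in range(shape[1]):
                for k in range(shape[2]):
                    x, y, z = affine[:3, :3] @ (i, j, k) + affine[:3, 3]
                    if box[0][0] <= x <= box[0][1] and box[1][0] <= y <= box[1][1] and box[2][0] <= z <= box[2][1]:
                        count += 1
        assert int(roi.data.sum()) == count

    def test_outside_grid_gives_empty_mask_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            roi = make_box_roi((5, 5, 5), np.eye(4), (100, 110), (0, 1), (0, 1))
        assert roi.data.sum() == 0
        assert any("empty" in r.message for r in caplog.records)

    def test_unordered_range_rejected(self):
        with pytest.raises(ValueError):
            make_box_roi((5, 5, 5), np.eye(4), (3, 1), (0, 1), (0, 1))
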