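"""Positional encoding, unary/pairwise potential heads, baseline kernels."""

import numpy as np
import pytest

from ncrfseg.autodiff import Tensor
from ncrfseg.graph import OFFSETS, build_neighbor_graph
from ncrfseg.nn import MLP
from ncrfseg.potentials import (add_positional_encoding, baseline_potentials,
                                binary_tables_tensor,
                                compute_binary_potentials, compute_unary,
                                encode_features, positional_encoding)


# -- positional encoding ----------------------------------------------

def test_positional_encoding_origin_and_range():
    pe = positional_encoding(5, 7, 8)
    assert pe[0, 0, 0] == 0.0          # sin(0)
    assert pe[0, 0, 1] == 1.0          # cos(0)
    assert pe.min() >= -1.0 and pe.max() <= 1.0


def test_first_group_is_unit_frequency():
    """k=0 gives omega=1, so channel 0 equals sin(column index)."""
    height, width, channels = 4, 9, 8
    pe = positional_encoding(height, width, channels)
    for i in range(height):
        for j in range(width):
            assert pe[i, j, 0] == pytest.approx(np.sin(j))
            assert pe[i, j, 1] == pytest.approx(np.cos(j))
            assert pe[i, j, 2] == pytest.approx(np.sin(i))
            assert pe[i, j, 3] == pytest.approx(np.cos(i))


def test_scalar_loop_oracle_for_all_groups():
    height, width, channels = 3, 4, 12
    pe = positional_encoding(height, width, channels)
    for i in range(height):
        for j in range(width):
            for c in range(channels):
                k = c // 4
                omega = 10000.0 ** (-4.0 * k / channels)
                value = [np.sin(omega * j), np.cos(omega * j),
                         np.sin(omega * i), np.cos(omega * i)][c % 4]
                assert pe[i, j, c] == pytest.approx(value, abs=1e-12)


def test_growing_frequency_flag_flips_exponent():
    pe = positional_encoding(3, 3, 8, growing_frequency=True)
    omega = 10000.0 ** (4.0 / 8)
    assert pe[0, 2, 4] == pytest.approx(np.sin(omega * 2))


def test_encoding_injective_over_positions():
    pe = positional_encoding(32, 32, 8)
    flat = pe.reshape(-1, 8)
    assert len(np.unique(flat.round(12), axis=0)) == 32 * 32


def test_channels_not_divisible_by_four_rejected():
    with pytest.raises(ValueError):
        positional_encoding(4, 4, 6)


def test_add_positional_encoding_is_elementwise_sum(rng):
    pe = positional_encoding(4, 4, 8)
    feats = rng.normal(size=(4, 4, 8))
    np.testing.assert_allclose(add_positional_encoding(feats, pe) - feats,
                               pe, atol=1e-6)
    np.testing.assert_allclose(add_positional_encoding(np.zeros_like(pe), pe),
                               pe)
    with pytest.raises(ValueError):
        add_positional_encoding(feats[:, :, :4], pe)


# -- unary head --------------------------------------------------------

def test_unary_zero_parameters_give_zero_costs(rng):
    feats = rng.normal(size=(3, 3, 4))
    out = compute_unary(feats, np.zeros((4, 2)), np.zeros(2))
    np.testing.assert_array_equal(out, 0)


def test_unary_matches_per_pixel_matrix_vector_products(rng):
    feats = rng.normal(size=(3, 4, 5))
    weight = rng.normal(size=(5, 3))
    bias = rng.normal(size=3)
    out = compute_unary(feats, weight, bias)
    for i in range(3):
        for j in range(4):
            np.testing.assert_allclose(out[i, j], weight.T @ feats[i, j] + bias,
                                       rtol=1e-12)
    with pytest.raises(ValueError):
        compute_unary(feats, np.zeros((4, 3)))


# -- feature embedding -------------------------------------------------

def test_shared_mlp_is_pixelwise_and_permutation_equivariant(rng):
    mlp = MLP([6, 6, 6], rng, dtype=np.float64)
    feats = rng.normal(size=(4, 5, 6))
    out = encode_features(feats, mlp)
    # identical inputs map to identical outputs
    feats2 = feats.copy()
    feats2[2, 2] = feats2[0, 0]
    out2 = encode_features(feats2, mlp)
    np.testing.assert_allclose(out2[2, 2], out2[0, 0])
    # permuting pixels permutes outputs
    perm = rng.permutation(20)
    out_perm = encode_features(feats.reshape(20, 1, 6)[perm], mlp)
    np.testing.assert_allclose(out_perm, out.reshape(20, 1, 6)[perm])


def test_identity_embedding_when_no_network(rng):
    feats = rng.normal(size=(3, 3, 4))
    np.testing.assert_array_equal(encode_features(feats, None), feats)


# -- learned pairwise potentials ---------------------------------------

def test_binary_potentials_positive_and_equal_for_equal_features(rng):
    g = MLP([4, 4, 4], rng, dtype=np.float64)
    graph = build_neighbor_graph(3, 3)
    encoded = np.ones((3, 3, 4))           # phi_p == phi_q on every edge
    pots = compute_binary_potentials(encoded, graph, g)
    reference = pots.matrix((0, 0), (0, 1))
    assert reference.min() > 0
    for p, q in graph.undirected_edges():
        np.testing.assert_allclose(pots.matrix(p, q), reference)


def test_binary_potentials_shared_between_edge_directions(rng):
    g = MLP([4, 4, 9], rng, dtype=np.float64)
    graph = build_neighbor_graph(4, 4)
    encoded = rng.normal(size=(4, 4, 4))
    pots = compute_binary_potentials(encoded, graph, g)
    for p, q in graph.undirected_edges():
        assert pots.matrix(p, q).min() > 0
        np.testing.assert_allclose(pots.matrix(p, q), pots.matrix(q, p).T)


def test_binary_potentials_match_per_edge_evaluation(rng):
    """The grid-vectorised tables agree with direct per-edge evaluation."""
    g = MLP([4, 4, 4], rng, dtype=np.float64)
    graph = build_neighbor_graph(3, 4)
    encoded = rng.normal(size=(3, 4, 4))
    pots = compute_binary_potentials(encoded, graph, g)
    for p, q in graph.undirected_edges():
        d = (encoded[p] - encoded[q]) ** 2
        logits = np.clip(g(Tensor(d[None])).data[0], -30, 30)
        np.testing.assert_allclose(pots.matrix(p, q),
                                   np.exp(logits).reshape(2, 2), rtol=1e-10)


def test_unknown_difference_rejected(rng):
    g = MLP([4, 4, 4], rng, dtype=np.float64)
    with pytest.raises(ValueError, match="difference"):
        binary_tables_tensor(Tensor(np.zeros((1, 3, 3, 4))), g, 2,
                             difference="cosine")


def test_nonfinite_features_rejected(rng):
    g = MLP([4, 4, 4], rng, dtype=np.float64)
    graph = build_neighbor_graph(3, 3)
    encoded = np.full((3, 3, 4), np.nan)
    with pytest.raises(ValueError, match="finite"):
        compute_binary_potentials(encoded, graph, g)


# -- baseline kernels --------------------------------------------------

def test_spatial_kernel_depends_only_on_direction():
    graph = build_neighbor_graph(4, 4)
    pots = baseline_potentials("spatial", None, graph, n_labels=3)
    axis = pots.matrix((1, 1), (1, 2))
    diag = pots.matrix((1, 1), (2, 2))
    assert np.all(np.diag(axis) == 0)
    # diagonal neighbours are farther away, so their coupling is weaker
    assert axis[0, 1] > diag[0, 1] > 0
    assert axis[0, 1] == pytest.approx(np.exp(-0.5))
    assert diag[0, 1] == pytest.approx(np.exp(-1.0))


def test_intensity_kernel_reduces_to_spatial_for_equal_intensities():
    graph = build_neighbor_graph(3, 3)
    flat = np.full((3, 3), 0.4)
    spatial = baseline_potentials("spatial", None, graph, n_labels=2)
    intensity = baseline_potentials("intensity", flat, graph, n_labels=2)
    for p, q in graph.undirected_edges():
        np.testing.assert_allclose(intensity.matrix(p, q),
                                   spatial.matrix(p, q), rtol=1e-12)


def test_intensity_kernel_weakens_across_edges(rng):
    graph = build_neighbor_graph(2, 2)
    image = np.array([[0.0, 1.0], [0.0, 1.0]])
    pots = baseline_potentials("intensity", image, graph, n_labels=2)
    across = pots.matrix((0, 0), (0, 1))[0, 1]     # intensity jump
    along = pots.matrix((0, 0), (1, 0))[0, 1]      # same intensity
    assert across < along


def test_posterior_kernel_constant_for_identical_posteriors():
    graph = build_neighbor_graph(3, 3)
    posterior = np.tile([0.2, 0.8], (3, 3, 1))
    pots = baseline_potentials("posterior", posterior, graph, n_labels=2)
    axis_edges = [e for e in graph.undirected_edges()
                  if abs(e[0][0] - e[1][0]) + abs(e[0][1] - e[1][1]) == 1]
    values = {pots.matrix(p, q)[0, 1] for p, q in axis_edges}
    assert len({round(v, 12) for v in values}) == 1


def test_unknown_baseline_kind_rejected():
    graph = build_neighbor_graph(2, 2)
    with pytest.raises(ValueError, match="kind"):
        baseline_potentials("bilateral", None, graph, n_labels=2)


def test_tables_cover_all_offsets(rng):
    g = MLP([4, 4, 4], rng, dtype=np.float64)
    graph = build_neighbor_graph(5, 5)
    pots = compute_binary_potentials(rng.normal(size=(5, 5, 4)), graph, g)
    assert set(pots.tables) == set(OFFSETS)
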