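"""Mean-field inference: initialisation, message passing, convergence,
and agreement with exact enumeration at weak coupling."""

import numpy as np
import pytest

from ncrfseg.autodiff import Tensor
from ncrfseg.graph import (EdgePotentials, build_neighbor_graph,
                           edgeless_graph, exact_marginals)
from ncrfseg.inference import (InferenceConfig, initialize_q,
                               mean_field_inference, meanfield_tensor,
                               message_passing, messages_tensor)


# -- initialisation ----------------------------------------------------

def test_zero_unary_initialises_uniform():
    q = initialize_q(np.zeros((2, 2, 3)))
    np.testing.assert_allclose(q, 1.0 / 3.0)


def test_dominant_unary_cost_suppresses_label():
    q = initialize_q(np.array([[[0.0, 20.0]]]))
    assert q[0, 0, 0] == pytest.approx(1.0, abs=1e-8)
    assert q[0, 0, 1] == pytest.approx(np.exp(-20) / (1 + np.exp(-20)))


def test_initialisation_matches_edgeless_exact_marginals(rng):
    unary = rng.normal(size=(3, 3, 4))
    marg = exact_marginals(unary, None, edgeless_graph(3, 3),
                           max_bits=24)
    np.testing.assert_allclose(initialize_q(unary), marg, atol=1e-9)


def test_nonfinite_unary_rejected():
    with pytest.raises(ValueError):
        initialize_q(np.array([[[np.inf, 0.0]]]))


# -- message passing ---------------------------------------------------

def test_edgeless_graph_passes_no_messages(rng):
    q = initialize_q(rng.normal(size=(3, 3, 2)))
    binary = EdgePotentials.constant(3, 3, 2, 1.0)
    psi = message_passing(q, binary, edgeless_graph(3, 3))
    np.testing.assert_array_equal(psi, 0)


def test_uniform_q_constant_matrix_gives_degree_times_constant():
    graph = build_neighbor_graph(3, 3)
    c = 0.7
    binary = EdgePotentials.constant(3, 3, 2, c)
    q = np.full((3, 3, 2), 0.5)
    psi = message_passing(q, binary, graph)
    # each incoming message sums c * Q over labels = c, so psi = degree * c
    np.testing.assert_allclose(psi[1, 1], 8 * c)       # interior
    np.testing.assert_allclose(psi[0, 0], 3 * c)       # corner
    np.testing.assert_allclose(psi[0, 1], 5 * c)       # border


def _naive_messages(q, binary, graph):
    """Quadruple loop: pixels x labels x neighbours x neighbour labels."""
    h, w, k = q.shape
    psi = np.zeros_like(q)
    for i in range(h):
        for j in range(w):
            for (p, n) in graph.edges:
                if p != (i, j):
                    continue
                m = binary.matrix(p, n)
                for a in range(k):
                    for b in range(k):
                        psi[i, j, a] += m[a, b] * q[n[0], n[1], b]
    return psi


def test_message_passing_matches_naive_quadruple_loop(rng):
    graph = build_neighbor_graph(5, 5)
    binary = EdgePotentials.random(5, 5, 3, rng, low=0.2, high=1.8)
    q = initialize_q(rng.normal(size=(5, 5, 3)))
    np.testing.assert_allclose(message_passing(q, binary, graph),
                               _naive_messages(q, binary, graph), atol=1e-6)


def test_tensor_messages_match_numpy_path(rng):
    """The differentiable batched path agrees with the per-edge loop."""
    graph = build_neighbor_graph(4, 6)
    binary = EdgePotentials.random(4, 6, 3, rng)
    q = initialize_q(rng.normal(size=(4, 6, 3)))
    tables = {off: Tensor(t[None]) for off, t in binary.tables.items()}
    psi_t = messages_tensor(Tensor(q[None]), tables, 4, 6)
    np.testing.assert_allclose(psi_t.data[0],
                               message_passing(q, binary, graph), atol=1e-10)


# -- mean-field iterations ---------------------------------------------

def test_zero_iterations_returns_initialisation(rng):
    unary = rng.normal(size=(4, 4, 3))
    graph = build_neighbor_graph(4, 4)
    binary = EdgePotentials.random(4, 4, 3, rng)
    q = mean_field_inference(unary, binary, graph,
                             InferenceConfig(iterations=0))
    np.testing.assert_allclose(q, initialize_q(unary))


@pytest.mark.parametrize("iterations", [1, 5, 20])
def test_constant_matrix_is_softmax_invariant(rng, iterations):
    """A constant M adds the same pseudo-potential to every label, which
    the per-pixel softmax cancels."""
    unary = rng.normal(size=(4, 4, 3))
    graph = build_neighbor_graph(4, 4)
    binary = EdgePotentials.constant(4, 4, 3, 1.3)
    q = mean_field_inference(unary, binary, graph,
                             InferenceConfig(iterations=iterations))
    np.testing.assert_allclose(q, initialize_q(unary), atol=1e-6)


def test_normalisation_conserved_across_iterations(rng):
    unary = rng.normal(size=(6, 6, 3))
    graph = build_neighbor_graph(6, 6)
    binary = EdgePotentials.random(6, 6, 3, rng, low=0.5, high=1.5)
    for n in range(6):
        q = mean_field_inference(unary, binary, graph,
                                 InferenceConfig(iterations=n))
        np.testing.assert_allclose(q.sum(-1), 1.0, atol=1e-6)


def test_weak_coupling_agrees_with_exact_marginals():
    rng = np.random.default_rng(11)
    graph = build_neighbor_graph(3, 3)
    agree, total = 0, 0
    for _ in range(50):
        unary = rng.normal(size=(3, 3, 2))
        binary = EdgePotentials.random(3, 3, 2, rng, low=0.9, high=1.1)
        mf = mean_field_inference(unary, binary, graph)
        exact = exact_marginals(unary, binary, graph)
        tv = 0.5 * np.abs(mf - exact).sum(-1)
        assert tv.max() < 0.05
        agree += (mf.argmax(-1) == exact.argmax(-1)).sum()
        total += 9
    assert agree / total >= 0.90


def test_fixed_point_at_bounded_coupling(rng):
    """With M entries <= 2 the update is empirically contractive: after 50
    iterations one more changes Q by < 1e-5."""
    unary = rng.normal(size=(5, 5, 3))
    graph = build_neighbor_graph(5, 5)
    binary = EdgePotentials.random(5, 5, 3, rng, low=0.5, high=2.0)
    q50 = mean_field_inference(unary, binary, graph,
                               InferenceConfig(iterations=50))
    q51 = mean_field_inference(unary, binary, graph,
                               InferenceConfig(iterations=51))
    assert np.abs(q51 - q50).max() < 1e-5


def test_scaled_unary_dominates_pairwise(rng):
    unary = rng.normal(size=(4, 4, 3))
    graph = build_neighbor_graph(4, 4)
    binary = EdgePotentials.random(4, 4, 3, rng, low=0.5, high=1.5)
    q = mean_field_inference(unary * 1e4, binary, graph)
    onehot = np.eye(3)[unary.argmin(-1)]
    np.testing.assert_allclose(q, onehot, atol=1e-6)


def test_early_stop_tolerance(rng):
    unary = rng.normal(size=(4, 4, 2))
    graph = build_neighbor_graph(4, 4)
    binary = EdgePotentials.random(4, 4, 2, rng, low=0.9, high=1.1)
    loose = mean_field_inference(unary, binary, graph,
                                 InferenceConfig(iterations=100, tolerance=1e-3))
    fixed = mean_field_inference(unary, binary, graph,
                                 InferenceConfig(iterations=100))
    np.testing.assert_allclose(loose, fixed, atol=1e-2)


def test_negative_iterations_rejected():
    with pytest.raises(ValueError):
        InferenceConfig(iterations=-1)


def test_meanfield_tensor_matches_numpy_inference(rng):
    unary = rng.normal(size=(4, 5, 3))
    graph = build_neighbor_graph(4, 5)
    binary = EdgePotentials.random(4, 5, 3, rng)
    tables = {off: Tensor(t[None]) for off, t in binary.tables.items()}
    logq, q = meanfield_tensor(Tensor(unary[None]), tables, 5)
    ref = mean_field_inference(unary, binary, graph)
    np.testing.assert_allclose(q.data[0], ref, atol=1e-10)
    np.testing.assert_allclose(np.exp(logq.data[0]), ref, atol=1e-10)
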