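"""Persistence diagrams, Wasserstein distances, uncertainty, graph extraction."""

import itertools

import numpy as np
import pytest

from inie.phantom import generate_vessel_tree, ground_truth_diagram, rasterize_phantom
from inie.topology import (
    PersistenceDiagram,
    UncertaintyWeights,
    VascularGraph,
    betti_numbers,
    extract_graph,
    normalized_persistence_deviation,
    persistence_diagram,
    topological_uncertainty,
    total_persistence_distance,
    wasserstein_exact,
    wasserstein_sliced,
)
from conftest import random_diagram


# ---------------------------------------------------------------------------
# persistence diagrams of images
# ---------------------------------------------------------------------------


def test_constant_image_single_component_no_loops():
    d = persistence_diagram(np.full((32, 32), 0.7))
    assert d.get(0).shape[0] == 1
    assert d.get(1).shape[0] == 0


def test_ring_has_one_component_and_one_persistent_hole(ring_image):
    d = persistence_diagram(ring_image)
    assert d.count_features(0, 0.5) == 1
    assert d.count_features(1, 0.5) == 1
    # the hole lives from the vessel intensity down to the background
    pers1 = d.persistence(1)
    assert pers1.max() == pytest.approx(0.9, abs=1e-6)


def test_diagram_deterministic(ring_image):
    d1 = persistence_diagram(ring_image)
    d2 = persistence_diagram(ring_image)
    for k in (0, 1):
        np.testing.assert_array_equal(d1.get(k), d2.get(k))


def test_small_noise_creates_only_low_persistence_points(ring_image):
    rng = np.random.default_rng(0)
    noisy = ring_image + rng.uniform(-0.01, 0.01, ring_image.shape)
    d = persistence_diagram(noisy)
    # dominant features survive; everything new stays below 0.05
    assert d.count_features(0, 0.05) == 1
    assert d.count_features(1, 0.05) == 1
    for k in (0, 1):
        pers = np.sort(d.persistence(k))
        assert np.all(pers[:-1] <= 0.05)


@pytest.mark.parametrize("eps", [0.01, 0.05])
def test_stability_of_dominant_features(ring_image, eps):
    """Perturbing intensities by eps moves each dominant diagram point by
    at most eps in the L-infinity sense."""
    rng = np.random.default_rng(1)
    noisy = ring_image + rng.uniform(-eps, eps, ring_image.shape)
    d0 = persistence_diagram(ring_image).prune(0.3)
    d1 = persistence_diagram(noisy).prune(0.3)
    for k in (0, 1):
        a, b = d0.get(k), d1.get(k)
        assert a.shape == b.shape
        # match nearest points and check displacement
        for pt in a:
            gap = np.abs(b - pt).max(axis=1).min()
            assert gap <= eps + 1e-12


def test_diagram_csv_roundtrip(tmp_path, ring_image):
    d = persistence_diagram(ring_image)
    path = tmp_path / "diagram.csv"
    d.to_csv(path)
    d2 = PersistenceDiagram.from_csv(path)
    for k in (0, 1):
        np.testing.assert_allclose(
            np.sort(d.get(k), axis=0), np.sort(d2.get(k), axis=0)
        )


def test_diagram_rejects_death_before_birth():
    with pytest.raises(ValueError):
        PersistenceDiagram({0: np.array([[1.0, 0.5]])})


# ---------------------------------------------------------------------------
# Wasserstein distances
# ---------------------------------------------------------------------------


def brute_force_wasserstein(x, y, p=2):
    """Oracle: enumerate every partial matching (remaining points go to the
    diagonal); only feasible for tiny diagrams."""
    n, m = len(x), len(y)
    best = np.inf
    idx_y = list(range(m))
    for k in range(0, min(n, m) + 1):
        for xs in itertools.combinations(range(n), k):
            for ys in itertools.permutations(idx_y, k):
                cost = 0.0
                for i, j in zip(xs, ys):
                    cost += np.abs(x[i] - y[j]).max() ** p
                for i in set(range(n)) - set(xs):
                    cost += ((x[i, 1] - x[i, 0]) / 2) ** p
                for j in set(range(m)) - set(ys):
                    cost += ((y[j, 1] - y[j, 0]) / 2) ** p
                best = min(best, cost)
    return best ** (1.0 / p)


def test_wasserstein_worked_examples():
    assert wasserstein_exact(np.array([[0.0, 2.0]]), np.empty((0, 2)), p=1) == \
        pytest.approx(1.0)
    d = wasserstein_exact(np.array([[0.0, 1.0]]),
                          np.array([[0.0, 1.0], [0.4, 0.5]]), p=1)
    assert d == pytest.approx(0.05)


@pytest.mark.parametrize("p", [1, 2])
def test_exact_matches_brute_force_on_all_small_diagrams(p):
    """Linear-assignment result equals exhaustive matching enumeration for
    every random diagram pair with at most 4 points per side."""
    rng = np.random.default_rng(3)
    for n in range(0, 5):
        for m in range(0, 5):
            for _ in range(3):
                x = random_diagram(rng, n) if n else np.empty((0, 2))
                y = random_diagram(rng, m) if m else np.empty((0, 2))
                assert wasserstein_exact(x, y, p=p) == pytest.approx(
                    brute_force_wasserstein(x, y, p=p), rel=1e-9, abs=1e-12
                )


def test_exact_is_symmetric_zero_on_equal():
    rng = np.random.default_rng(4)
    x = random_diagram(rng, 12)
    y = random_diagram(rng, 9)
    assert wasserstein_exact(x, x) == pytest.approx(0.0, abs=1e-12)
    assert wasserstein_exact(x, y) == pytest.approx(wasserstein_exact(y, x))


def test_sliced_identity_symmetry_and_upper_bound():
    rng = np.random.default_rng(5)
    x = random_diagram(rng, 30)
    y = random_diagram(rng, 20)
    assert wasserstein_sliced(x, x, seed=1) == pytest.approx(0.0, abs=1e-12)
    assert wasserstein_sliced(x, y, seed=1) == wasserstein_sliced(y, x, seed=1)
    assert wasserstein_sliced(x, y, seed=1) >= wasserstein_exact(x, y) - 1e-9


def test_total_persistence_distance_closed_form():
    pts = np.array([[0.0, 1.0], [0.2, 0.6]])
    assert total_persistence_distance(pts, p=1) == pytest.approx(0.5 + 0.2)
    assert total_persistence_distance(pts, p=2) == pytest.approx(
        np.hypot(0.5, 0.2)
    )


# ---------------------------------------------------------------------------
# topological uncertainty and normalized deviation
# ---------------------------------------------------------------------------


def _diag(pts0, pts1):
    return PersistenceDiagram({0: np.asarray(pts0, float).reshape(-1, 2),
                               1: np.asarray(pts1, float).reshape(-1, 2)})


def test_uncertainty_zero_iff_equal_and_linear_in_weights():
    d1 = _diag([[0, 1]], [[0.2, 0.9]])
    d2 = _diag([[0, 0.8]], [[0.2, 0.4]])
    w = UncertaintyWeights(0.5, 0.5, 2)
    assert topological_uncertainty(d1, d1, w) == pytest.approx(0.0, abs=1e-12)
    u = topological_uncertainty(d1, d2, w, method="exact")
    w2 = UncertaintyWeights(1.0, 1.0, 2)
    assert topological_uncertainty(d1, d2, w2, method="exact") == \
        pytest.approx(2 * u)


def test_uncertainty_weight_masking():
    d1 = _diag([[0, 1]], [[0.2, 0.9]])
    d2 = _diag([[0, 1]], [[0.1, 0.3]])  # only degree 1 differs
    w = UncertaintyWeights(1.0, 0.0, 2)
    assert topological_uncertainty(d1, d2, w, method="exact") == \
        pytest.approx(0.0, abs=1e-12)


def test_normalized_deviation_endpoints():
    d_ref = _diag([[0, 1], [0, 0.5]], [[0.1, 0.8]])
    assert normalized_persistence_deviation(d_ref, d_ref) == \
        pytest.approx(0.0, abs=1e-9)
    assert normalized_persistence_deviation(
        PersistenceDiagram.empty(), d_ref, method="exact"
    ) == pytest.approx(100.0)


def test_normalized_deviation_scale_invariance():
    d_ref = _diag([[0, 1], [0, 0.5]], [[0.1, 0.8]])
    d = _diag([[0, 0.9]], [[0.1, 0.7]])
    a = normalized_persistence_deviation(d, d_ref, method="exact")
    b = normalized_persistence_deviation(d.scaled(3.0), d_ref.scaled(3.0),
                                         method="exact")
    assert a == pytest.approx(b)


def test_normalized_deviation_prefers_dropping_small_features():
    rng = np.random.default_rng(6)
    pts = random_diagram(rng, 20)
    order = np.argsort(pts[:, 1] - pts[:, 0])
    d_ref = PersistenceDiagram({0: pts})
    low_removed = PersistenceDiagram({0: pts[order[10:]]})
    high_removed = PersistenceDiagram({0: pts[order[:10]]})
    w = UncertaintyWeights(1.0, 0.0, 2)
    dev_low = normalized_persistence_deviation(low_removed, d_ref, w, method="exact")
    dev_high = normalized_persistence_deviation(high_removed, d_ref, w, method="exact")
    assert dev_low < dev_high


def test_normalized_deviation_degenerate_reference():
    with pytest.raises(ValueError):
        normalized_persistence_deviation(
            PersistenceDiagram.empty(), PersistenceDiagram.empty()
        )


# ---------------------------------------------------------------------------
# graph extraction and Betti numbers
# ---------------------------------------------------------------------------


def test_blank_image_gives_empty_graph():
    g = extract_graph(np.zeros((64, 64)))
    assert g.n_vertices == 0
    assert betti_numbers(g) == (0, 0)


def test_single_segment_graph():
    img = np.full((64, 64), 0.1)
    img[30:34, 10:50] = 1.0
    g = extract_graph(img)
    assert betti_numbers(g) == (1, 0)


def test_betti_numbers_euler_formula():
    path = VascularGraph(np.zeros((3, 2)), [(0, 1, 1.0), (1, 2, 1.0)], 1)
    assert betti_numbers(path) == (1, 0)
    tri = VascularGraph(np.zeros((3, 2)),
                        [(0, 1, 1.0), (1, 2, 1.0), (2, 0, 1.0)], 1)
    assert betti_numbers(tri) == (1, 1)
    two = VascularGraph(np.zeros((6, 2)),
                        [(0, 1, 1), (1, 2, 1), (2, 0, 1), (3, 4, 1), (4, 5, 1)], 2)
    assert betti_numbers(two) == (2, 1)


def test_loop_phantom_graph_betti(two_loop_phantom):
    g = extract_graph(two_loop_phantom.mr_image)
    assert betti_numbers(g) == (1, 2)


def test_persistence_and_graph_betti_agree_on_clean_phantoms():
    """Feature counts above the noise floor match the skeleton-graph Betti
    numbers on 50 seeded phantoms."""
    for seed in range(50):
        n_loops = seed % 4
        tree = generate_vessel_tree(seed, n_loops=n_loops)
        ph = rasterize_phantom(tree, 128)
        d = ground_truth_diagram(ph)
        g = extract_graph(ph.mr_image)
        assert (d.count_features(0, 0.5), d.count_features(1, 0.5)) == (1, n_loops)
        assert betti_numbers(g) == (1, n_loops)
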