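"""Synthetic 2D vascular phantoms with analytically known topology.

A phantom is built in two stages: a :class:`VesselTree` (planar graph with
per-edge radii and a known number of collateral loops) is generated from a
seed, then rasterized into a paired MR intensity grid and PET activity grid
plus a binary vessel label map.  Because every collateral loop is added as
an explicit arc between points of an existing tree, the first Betti number
of the graph is known by construction and can be cross-checked with the
Euler formula beta1 = E - V + C.

Phantoms are 2D only (grids of 64-256 pixels); the closed-loop mathematics
downstream is dimension-agnostic, and the rasterization keeps a
``dimension`` field so a 3D backend could be added without API change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .topology import PersistenceDiagram, persistence_diagram

__all__ = ["VesselTree", "Phantom", "generate_vessel_tree", "rasterize_phantom",
           "ground_truth_diagram"]


@dataclass
class VesselTree:
    """Planar vascular graph: node coordinates in [0, 1]^2 (scaled to the
    grid at rasterization), edges as node-index pairs, one radius per edge
    (in pixels at the reference 128 grid), and the number of collateral
    loops added during generation."""

    nodes: list[tuple[float, float]]
    edges: list[tuple[int, int]]
    radii: list[float]
    loop_count: int
    dimension: int = 2

    def __post_init__(self) -> None:
        n = len(self.nodes)
        seen = set()
        for (a, b), r in zip(self.edges, self.radii):
            if not (0 <= a < n and 0 <= b < n) or a == b:
                raise ValueError(f"invalid edge ({a}, {b})")
            key = (min(a, b), max(a, b))
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)
            if r <= 0:
                raise ValueError("radii must be positive")
        if len(self.radii) != len(self.edges):
            raise ValueError("one radius per edge required")

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.nodes)))
        g.add_edges_from(self.edges)
        return g

    def betti(self) -> tuple[int, int]:
        """(beta0, beta1) from the Euler formula beta1 = E - V + C."""
        g = self.graph()
        c = nx.number_connected_components(g)
        return c, len(self.edges) - len(self.nodes) + c

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [(a, b, r) for (a, b), r in zip(self.edges, self.radii)],
            columns=["node_id_a", "node_id_b", "radius"],
        ).to_csv(path, index=False)


@dataclass
class Phantom:
    """Rasterized phantom: MR intensity in [0, 1], non-negative PET
    activity (kBq/mL semantics), binary vessel label map, and the
    generating tree and seed."""

    mr_image: np.ndarray
    pet_activity: np.ndarray
    label_map: np.ndarray
    tree: VesselTree
    seed: int
    background_level: float = 0.1

    def __post_init__(self) -> None:
        if self.mr_image.shape != self.pet_activity.shape:
            raise ValueError("MR and PET grids must share shape")
        if np.any(self.pet_activity < 0):
            raise ValueError("PET activity must be non-negative")

    @property
    def grid_size(self) -> int:
        return self.mr_image.shape[0]


def generate_vessel_tree(
    seed: int,
    n_primary_branches: int = 4,
    loop_probability: float = 0.5,
    grid_size: int = 128,
    n_loops: int | None = None,
) -> VesselTree:
    """Generate a seeded vascular tree with optional collateral loops.

    A trunk crosses the domain horizontally with jitter; ``n_primary_branches``
    side branches leave the trunk at alternating sides.  Collateral loops are
    added as arcs over trunk segments: each arc joins two existing nodes
    through fresh midpoints, which raises beta1 by exactly one, so the
    Euler-formula beta1 always equals ``loop_count``.  If ``n_loops`` is
    given it fixes the number of loops; otherwise each of three candidate
    sites receives a loop with probability ``loop_probability``.

    Deterministic for a fixed seed.
    """
    if grid_size < 32:
        raise ValueError(f"grid_size must be >= 32, got {grid_size}")
    if not 0.0 <= loop_probability <= 1.0:
        raise ValueError("loop_probability must be in [0, 1]")
    if not 1 <= n_primary_branches <= 5:
        raise ValueError("n_primary_branches must be between 1 and 5")
    rng = np.random.default_rng(seed)

    nodes: list[tuple[float, float]] = []
    edges: list[tuple[int, int]] = []
    radii: list[float] = []

    # trunk: left to right slightly above the middle, mild vertical jitter
    n_trunk = 6
    xs = np.linspace(0.08, 0.92, n_trunk + 1)
    ys = 0.58 + rng.uniform(-0.03, 0.03, n_trunk + 1)
    for x, y in zip(xs, ys):
        nodes.append((float(x), float(y)))
    for i in range(n_trunk):
        edges.append((i, i + 1))
        radii.append(2.5)

    # side branches: two-segment limbs, all above the trunk, fanning from
    # steep (left) to shallow (right) so neighbouring limbs always diverge
    attach_ids = list(range(1, n_trunk))
    for b in range(n_primary_branches):
        a = attach_ids[b % len(attach_ids)]
        ax, ay = nodes[a]
        base = 1.35 - 0.12 * (a - 1)  # radians from horizontal
        ang = base + rng.uniform(-0.05, 0.05)
        length = rng.uniform(0.2, 0.28)
        mx = ax + 0.5 * length * np.cos(ang) + rng.uniform(-0.01, 0.01)
        my = ay + 0.5 * length * np.sin(ang)
        ex = ax + length * np.cos(ang) + rng.uniform(-0.015, 0.015)
        ey = ay + length * np.sin(ang)
        for px, py in ((mx, my), (ex, ey)):
            nodes.append((float(np.clip(px, 0.04, 0.96)), float(np.clip(py, 0.04, 0.96))))
        i_mid, i_end = len(nodes) - 2, len(nodes) - 1
        edges.append((a, i_mid))
        edges.append((i_mid, i_end))
        radii.extend([1.8, 1.5])

    # collateral loops: arcs below trunk segments (1,2), (3,4), (5,6);
    # nothing else occupies the half-plane below the trunk, so arcs are
    # collision-free by construction
    candidate_segments = [(1, 2), (3, 4), (5, 6)]
    if n_loops is None:
        chosen = [s for s in candidate_segments if rng.random() < loop_probability]
    else:
        if not 0 <= n_loops <= len(candidate_segments):
            raise ValueError("n_loops must be between 0 and 3")
        chosen = candidate_segments[:n_loops]
        rng.random(len(candidate_segments))  # keep stream aligned with the stochastic path
    loop_count = 0
    for (a, b) in chosen:
        ax, ay = nodes[a]
        bx, by = nodes[b]
        # arc below the trunk (branches alternate, trunk jitter is small, so
        # a fixed-depth arc cannot collide with branch limbs above)
        depth = rng.uniform(0.14, 0.2)
        m1 = ((2 * ax + bx) / 3, (2 * ay + by) / 3 - depth)
        m2 = ((ax + 2 * bx) / 3, (ay + 2 * by) / 3 - depth)
        nodes.append((float(m1[0]), float(np.clip(m1[1], 0.04, 0.96))))
        nodes.append((float(m2[0]), float(np.clip(m2[1], 0.04, 0.96))))
        i1, i2 = len(nodes) - 2, len(nodes) - 1
        edges.append((a, i1))
        edges.append((i1, i2))
        edges.append((i2, b))
        radii.extend([1.5, 1.5, 1.5])
        loop_count += 1

    return VesselTree(nodes, edges, radii, loop_count)


def _distance_to_segment(yy, xx, p0, p1):
    """Pixel-wise Euclidean distance to the segment p0-p1 (grid units)."""
    v = np.array(p1) - np.array(p0)
    denom = float(v @ v)
    if denom == 0:
        return np.hypot(yy - p0[1], xx - p0[0])
    t = ((xx - p0[0]) * v[0] + (yy - p0[1]) * v[1]) / denom
    t = np.clip(t, 0.0, 1.0)
    cx = p0[0] + t * v[0]
    cy = p0[1] + t * v[1]
    return np.hypot(yy - cy, xx - cx)


def rasterize_phantom(
    tree: VesselTree,
    grid_size: int = 128,
    background_level: float = 0.1,
    seed: int = 0,
    pet_vessel_activity: float = 1.0,
    pet_background_activity: float = 0.1,
) -> Phantom:
    """Rasterize a vessel tree onto a square grid.

    Vessels are drawn as tubes of width 2*radius around each edge segment
    with a flat core and a 1-pixel Gaussian feathered rim, which keeps the
    image piecewise smooth (total-variation priors remain meaningful).  MR
    intensity is ``background_level`` outside vessels and 1 inside; PET
    activity is 1.0 inside vessels and 0.1 outside by default (scaled to a
    count budget only at simulation time).  The label map is the exact
    hard-threshold support of the tubes.
    """
    if grid_size < 32:
        raise ValueError(f"grid_size must be >= 32, got {grid_size}")
    scale = grid_size / 128.0
    radii_px = [r * scale for r in tree.radii]
    if tree.edges and min(radii_px) < 1.0:
        raise ValueError(
            f"smallest vessel radius {min(radii_px):.2f}px < 1px at grid {grid_size}"
        )
    yy, xx = np.mgrid[0:grid_size, 0:grid_size].astype(np.float64)
    dist = np.full((grid_size, grid_size), np.inf)
    label = np.zeros((grid_size, grid_size), dtype=bool)
    soft = np.zeros((grid_size, grid_size))
    for (a, b), r in zip(tree.edges, radii_px):
        p0 = (tree.nodes[a][0] * (grid_size - 1), tree.nodes[a][1] * (grid_size - 1))
        p1 = (tree.nodes[b][0] * (grid_size - 1), tree.nodes[b][1] * (grid_size - 1))
        d = _distance_to_segment(yy, xx, p0, p1)
        dist = np.minimum(dist, d - r)
        label |= d <= r
    if tree.edges:
        # flat core, 1px Gaussian feather outside the tube boundary
        soft = np.where(dist <= 0, 1.0, np.exp(-0.5 * np.clip(dist, 0, None) ** 2))
        soft[dist > 3.0] = 0.0
        # discretizing the union of capsules can leave pixel-scale gaps in
        # junction wedges; they are rasterization artifacts, not anatomy
        from skimage.morphology import remove_small_holes
        label = remove_small_holes(label, max_size=8)
    mr = background_level + (1.0 - background_level) * soft
    pet = pet_background_activity + (pet_vessel_activity - pet_background_activity) * label
    return Phantom(mr, pet, label, tree, seed, background_level)


def ground_truth_diagram(phantom: Phantom) -> PersistenceDiagram:
    """Reference persistence diagram D* of the noiseless MR image
    (superlevel filtration); deterministic, used as the oracle reference
    for topological uncertainty."""
    return persistence_diagram(phantom.mr_image)
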