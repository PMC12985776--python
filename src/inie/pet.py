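"""PET model: parallel-beam projection, Poisson count simulation with a
uniform randoms/scatter term, and OS-EM reconstruction.

Geometry is 2D parallel-beam.  The projector is pixel-driven with linear
detector splatting: each pixel deposits its full activity into the two
detector bins bracketing its projected position, so every angle's
projection carries exactly the total image mass and the backprojector is
the exact matrix transpose.  The detector covers the grid diagonal, so no
pixel ever falls off the detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix, csr_matrix

__all__ = ["Sinogram", "PETProjector", "IdentityProjector", "default_angles",
           "project", "simulate_counts", "osem_reconstruct", "poisson_loglik"]


def default_angles(n_angles: int = 60) -> np.ndarray:
    """Evenly spaced projection angles in [0, 180) degrees."""
    return np.linspace(0.0, 180.0, n_angles, endpoint=False)


@dataclass
class Sinogram:
    """Measured PET counts, shape (n_angles, n_bins), with the acquisition
    angles in degrees and the expected randoms/scatter rate per bin."""

    counts: np.ndarray
    angles: np.ndarray
    randoms_rate: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(np.diff(self.angles) <= 0) or np.any(self.angles < 0) or np.any(
            self.angles >= 180.0
        ):
            raise ValueError("angles must be strictly increasing in [0, 180)")
        if self.randoms_rate < 0:
            raise ValueError("randoms rate must be >= 0")

    @property
    def n_angles(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.counts, index=self.angles)
        df.index.name = "angle_deg"
        df.to_csv(path)


class PETProjector:
    """Sparse parallel-beam system matrix for a square grid.

    Rows are (angle, bin) pairs; the matrix is built once per geometry and
    reused.  ``project`` maps image -> sinogram, ``backproject`` is the
    exact adjoint.
    """

    def __init__(self, grid_size: int, angles: np.ndarray, n_bins: int | None = None):
        self.grid_size = int(grid_size)
        self.angles = np.asarray(angles, dtype=np.float64)
        if n_bins is None:
            n_bins = int(np.ceil(grid_size * np.sqrt(2.0))) + 3
        self.n_bins = int(n_bins)
        self.matrix = self._build()

    def _build(self) -> csr_matrix:
        g = self.grid_size
        yy, xx = np.mgrid[0:g, 0:g].astype(np.float64)
        cx = (g - 1) / 2.0
        px = (xx - cx).ravel()
        py = (yy - cx).ravel()
        n_pix = g * g
        det_c = (self.n_bins - 1) / 2.0
        rows, cols, vals = [], [], []
        for ai, ang in enumerate(self.angles):
            th = np.deg2rad(ang)
            s = px * np.cos(th) + py * np.sin(th) + det_c
            lo = np.floor(s).astype(np.int64)
            w_hi = s - lo
            for off, w in ((0, 1.0 - w_hi), (1, w_hi)):
                b = lo + off
                ok = (b >= 0) & (b < self.n_bins) & (w > 0)
                rows.append(ai * self.n_bins + b[ok])
                cols.append(np.flatnonzero(ok))
                vals.append(w[ok])
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        return coo_matrix(
            (vals, (rows, cols)), shape=(len(self.angles) * self.n_bins, n_pix)
        ).tocsr()

    def project(self, activity: np.ndarray) -> np.ndarray:
        x = np.asarray(activity, dtype=np.float64)
        if x.shape != (self.grid_size, self.grid_size):
            raise ValueError("activity shape does not match projector grid")
        out = self.matrix @ x.ravel()
        return out.reshape(len(self.angles), self.n_bins)

    def backproject(self, sino_values: np.ndarray) -> np.ndarray:
        s = np.asarray(sino_values, dtype=np.float64).ravel()
        return (self.matrix.T @ s).reshape(self.grid_size, self.grid_size)

    def subset(self, indices: np.ndarray) -> "PETProjector":
        sub = object.__new__(PETProjector)
        sub.grid_size = self.grid_size
        sub.angles = self.angles[indices]
        sub.n_bins = self.n_bins
        rows = (indices[:, None] * self.n_bins + np.arange(self.n_bins)).ravel()
        sub.matrix = self.matrix[rows]
        return sub


class IdentityProjector:
    """Trivial system matrix (image space == detector space); used for
    analytic checks of the EM update and the Poisson likelihood."""

    def __init__(self, shape):
        self.shape = shape

    def project(self, x):
        return np.asarray(x, dtype=np.float64)

    def backproject(self, s):
        return np.asarray(s, dtype=np.float64)


_projector_cache: dict[tuple, PETProjector] = {}


def get_projector(grid_size: int, angles, n_bins: int | None = None) -> PETProjector:
    key = (int(grid_size), tuple(np.round(np.asarray(angles, float), 9)), n_bins)
    if key not in _projector_cache:
        _projector_cache[key] = PETProjector(grid_size, np.asarray(angles, float), n_bins)
    return _projector_cache[key]


def project(activity: np.ndarray, angles) -> np.ndarray:
    """Expected (noiseless, real-valued) sinogram of an activity grid."""
    x = np.asarray(activity, dtype=np.float64)
    if np.any(x < 0):
        raise ValueError("activity must be non-negative")
    proj = get_projector(x.shape[0], angles)
    return proj.project(x)


def simulate_counts(expected: np.ndarray, angles, randoms_rate: float = 0.0,
                    seed: int = 0) -> Sinogram:
    """Draw Poisson counts around expected + randoms, element-wise;
    deterministic per seed."""
    exp = np.asarray(expected, dtype=np.float64)
    if np.any(exp < 0):
        raise ValueError("expected sinogram must be non-negative")
    if randoms_rate < 0:
        raise ValueError("randoms rate must be >= 0")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(exp + randoms_rate)
    return Sinogram(counts, np.asarray(angles, float), randoms_rate)


def poisson_loglik(x: np.ndarray, sino: Sinogram, projector) -> float:
    """Poisson log-likelihood (up to the constant log y! term):
    sum(y * log(Ax + r) - (Ax + r))."""
    lam = projector.project(x) + sino.randoms_rate
    y = sino.counts
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(lam), 0.0)
    if not np.all(np.isfinite(term[y > 0])):
        raise ValueError("log argument <= 0 where counts are positive")
    return float(term.sum() - lam.sum())


def osem_reconstruct(
    sino: Sinogram,
    n_iterations: int = 3,
    n_subsets: int = 4,
    init: np.ndarray | None = None,
    projector: PETProjector | IdentityProjector | None = None,
    track_loglik: bool = False,
):
    """Ordered-subsets expectation maximization.

    Multiplicative updates per angle subset:
    x <- x * A_s^T(y_s / (A_s x + r)) / A_s^T 1, with zero-sensitivity
    pixels left untouched.  With ``n_subsets=1`` this is MLEM, whose
    Poisson log-likelihood is non-decreasing across iterations.  Output is
    non-negative by construction.
    """
    if init is None:
        raise ValueError("init (positive grid) is required")
    x = np.asarray(init, dtype=np.float64).copy()
    if np.any(x <= 0):
        raise ValueError("init must be strictly positive")
    if sino.n_angles % n_subsets != 0:
        raise ValueError(
            f"n_subsets={n_subsets} does not divide n_angles={sino.n_angles}"
        )
    if projector is None:
        projector = get_projector(x.shape[0], sino.angles)

    identity = isinstance(projector, IdentityProjector)
    # interleaved angle subsets (standard OS-EM ordering)
    subsets = [np.arange(s, sino.n_angles, n_subsets) for s in range(n_subsets)]
    if identity:
        subs = [(projector, sino.counts)] * 1
        subsets = [np.arange(sino.n_angles)]
    r = sino.randoms_rate
    eps = 1e-12
    loglik = []
    for _ in range(n_iterations):
        for inds in subsets:
            if identity:
                sub_p, y = projector, sino.counts
            else:
                sub_p = projector.subset(inds)
                y = sino.counts[inds]
            lam = sub_p.project(x) + r
            ratio = np.where(lam > eps, y / np.maximum(lam, eps), 0.0)
            sens = sub_p.backproject(np.ones_like(ratio, dtype=np.float64))
            upd = sub_p.backproject(ratio)
            pos = sens > eps
            x[pos] = x[pos] * upd[pos] / sens[pos]
        if track_loglik:
            loglik.append(poisson_loglik(x, sino, projector))
    if track_loglik:
        return x, np.array(loglik)
    return x
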