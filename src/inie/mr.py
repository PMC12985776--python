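"""MR encoding model: orthonormal Fourier transform, variable-density
Poisson-disc sampling masks under a partial-Fourier constraint, and noisy
k-space acquisition with conjugate-symmetric filling.

k-space is stored DC-centered.  The sampling unit for the closed-loop
controller is a whole phase-encode line (one row of k-space); pointwise 2D
Poisson-disc masks are used for static compressed-sensing baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from numba import njit

__all__ = ["KSpace", "SamplingMask", "fourier_encode", "build_sampling_mask",
           "build_line_mask", "acquire", "conjugate_fill", "conjugate_support"]


@dataclass
class KSpace:
    """Complex k-space grid, same shape as the image; DC at grid center."""

    data: np.ndarray
    centered: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)

    @property
    def shape(self):
        return self.data.shape


def fourier_encode(image: np.ndarray, direction: str = "forward"):
    """Orthonormal centered 2D discrete Fourier transform F (or its adjoint).

    With ``norm='ortho'`` the adjoint is the exact inverse, so
    ``fourier_encode(fourier_encode(u), 'adjoint')`` returns ``u`` to
    machine precision.
    """
    if direction == "forward":
        img = np.asarray(image, dtype=np.complex128)
        if img.ndim != 2 or img.shape[0] != img.shape[1]:
            raise ValueError(f"expected a square grid, got shape {img.shape}")
        k = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img), norm="ortho"))
        return KSpace(k)
    elif direction == "adjoint":
        k = image.data if isinstance(image, KSpace) else np.asarray(image)
        if k.ndim != 2 or k.shape[0] != k.shape[1]:
            raise ValueError(f"expected a square grid, got shape {k.shape}")
        return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(k), norm="ortho"))
    raise ValueError(f"direction must be 'forward' or 'adjoint', got {direction!r}")


@dataclass
class SamplingMask:
    """Binary k-space sampling pattern.

    ``acquisition_order`` records the acquired units in draw order: flat
    pixel indices for pointwise masks, row indices for line masks.
    ``min_distance_profile`` maps normalized k-space radius (0 at DC, 1 at
    the corner) to the local Poisson-disc minimum distance in pixels; it is
    ``None`` for line masks.
    """

    mask: np.ndarray
    acquisition_order: list[int]
    partial_fourier_fraction: float = 1.0
    min_distance_profile: Callable[[float], float] | None = None
    unit: str = "point"  # "point" or "line"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def fraction(self) -> float:
        return float(self.mask.mean())

    @property
    def n_rows(self) -> int:
        return self.mask.shape[0]

    def allowed_rows(self) -> np.ndarray:
        """Phase-encode rows inside the partial-Fourier extent."""
        n = self.n_rows
        return np.arange(int(np.ceil(self.partial_fourier_fraction * n)))

    @classmethod
    def from_lines(cls, grid_size: int, lines, partial_fourier_fraction: float = 1.0):
        """Line mask: full phase-encode rows at the given indices."""
        lines = [int(x) for x in lines]
        limit = int(np.ceil(partial_fourier_fraction * grid_size))
        for ln in lines:
            if not 0 <= ln < grid_size:
                raise ValueError(f"line index {ln} outside grid")
            if ln >= limit:
                raise ValueError(
                    f"line {ln} lies beyond the partial-Fourier extent ({limit})"
                )
        m = np.zeros((grid_size, grid_size), dtype=bool)
        m[lines, :] = True
        return cls(m, list(lines), partial_fourier_fraction, None, unit="line")

    def to_csv(self, path) -> None:
        pd.DataFrame({"acquired_index": self.acquisition_order}).to_csv(path, index=False)


@njit(cache=True)
def _dart_throw(rmap, order, nrows, ncols):
    """Sequential dart throwing: accept a candidate unless an accepted point
    q exists with dist(p, q) < min(r(p), r(q))."""
    acc = np.zeros((nrows, ncols), dtype=np.bool_)
    for oi in range(order.shape[0]):
        idx = order[oi]
        r = idx // ncols
        c = idx % ncols
        rp = rmap[r, c]
        w = int(np.ceil(rp))
        ok = True
        for dr in range(-w, w + 1):
            rr = r + dr
            if rr < 0 or rr >= nrows:
                continue
            for dc in range(-w, w + 1):
                cc = c + dc
                if cc < 0 or cc >= ncols:
                    continue
                if not acc[rr, cc]:
                    continue
                d = np.sqrt(dr * dr + dc * dc)
                if d < min(rp, rmap[rr, cc]):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            acc[r, c] = True
    return acc


def build_sampling_mask(
    grid_size: int,
    target_fraction: float,
    partial_fourier_fraction: float = 1.0,
    seed: int = 0,
    density_exponent: float = 2.0,
) -> SamplingMask:
    """Variable-density Poisson-disc sampling mask.

    The local minimum distance grows with k-space radius as
    ``r0 * (1 + rho^density_exponent * gain)`` so sampling is densest near
    DC; ``r0`` is calibrated by bisection until the acquired fraction is
    within a few percent (relative) of ``target_fraction``.  Rows beyond
    the partial-Fourier extent are never acquired.  Deterministic per seed.
    """
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must be in (0, 1]")
    if not 0.5 < partial_fourier_fraction <= 1:
        raise ValueError("partial_fourier_fraction must be in (0.5, 1]")
    if target_fraction > partial_fourier_fraction + 1e-12:
        raise ValueError(
            f"target fraction {target_fraction} exceeds the partial-Fourier "
            f"extent {partial_fourier_fraction}: infeasible"
        )
    n = grid_size
    limit = int(np.ceil(partial_fourier_fraction * n))
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    c0 = n // 2
    rho = np.hypot(yy - c0, xx - c0) / (np.sqrt(2) * n / 2)  # 0 at DC, 1 at corner

    allowed = np.zeros((n, n), dtype=bool)
    allowed[:limit, :] = True
    rng = np.random.default_rng(seed)
    flat_allowed = np.flatnonzero(allowed.ravel())
    order = rng.permutation(flat_allowed).astype(np.int64)

    if target_fraction >= partial_fourier_fraction - 1e-12:
        # saturated: every allowed location
        mask = allowed
        profile = lambda r: 0.0  # noqa: E731
        return SamplingMask(mask, list(order), partial_fourier_fraction, profile)

    def realized(r0: float) -> tuple[float, np.ndarray]:
        rmap = r0 * (1.0 + 4.0 * rho ** density_exponent)
        rmap[~allowed] = 1e9
        acc = _dart_throw(rmap, order, n, n)
        acc &= allowed
        return float(acc.mean()), acc

    lo, hi = 0.05, 8.0
    best = None
    for _ in range(18):
        mid = 0.5 * (lo + hi)
        frac, acc = realized(mid)
        best = (mid, frac, acc)
        if abs(frac - target_fraction) / target_fraction < 0.02:
            break
        if frac > target_fraction:
            lo = mid
        else:
            hi = mid
    r0, frac, acc = best
    profile = lambda r: r0 * (1.0 + 4.0 * r ** density_exponent)  # noqa: E731
    order_kept = [int(i) for i in order if acc.ravel()[i]]
    return SamplingMask(acc, order_kept, partial_fourier_fraction, profile)


def build_line_mask(
    grid_size: int,
    target_fraction: float,
    partial_fourier_fraction: float = 1.0,
    seed: int = 0,
    center_fraction: float = 0.08,
    density_exponent: float = 2.0,
) -> SamplingMask:
    """Static variable-density Poisson-disc mask over phase-encode lines.

    The line dimension is sampled with a 1D Poisson-disc whose minimum gap
    grows with distance from the k-space center (densest near DC); a
    ``center_fraction`` block around DC is always acquired, as in standard
    static compressed-sensing protocols.  ``target_fraction`` counts
    acquired lines over all ``grid_size`` lines.  Deterministic per seed.
    """
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must be in (0, 1]")
    if not 0.5 < partial_fourier_fraction <= 1:
        raise ValueError("partial_fourier_fraction must be in (0.5, 1]")
    n = grid_size
    limit = int(np.ceil(partial_fourier_fraction * n))
    if target_fraction > limit / n + 1e-12:
        raise ValueError("target fraction exceeds the partial-Fourier extent")
    c = n // 2
    n_center = max(2, int(round(center_fraction * n)))
    center = set(range(c - n_center // 2, c + (n_center + 1) // 2))
    n_target = int(round(target_fraction * n))
    rng = np.random.default_rng(seed)
    others = np.array([l for l in range(limit) if l not in center])
    order = rng.permutation(others)
    rho = np.abs(np.arange(n) - c) / c

    def throw(r0: float) -> list[int]:
        acc = sorted(center)
        rad = lambda l: r0 * (1.0 + 4.0 * rho[l] ** density_exponent)  # noqa: E731
        for l in order:
            rl = rad(int(l))
            if all(abs(int(l) - a) >= min(rl, rad(a)) for a in acc):
                acc.append(int(l))
        return sorted(acc)

    lo, hi = 0.02, float(n)
    best = throw(lo)
    for _ in range(20):
        mid = np.sqrt(lo * hi)
        acc = throw(mid)
        if len(acc) > n_target:
            lo = mid
            best = acc
        else:
            hi = mid
            if abs(len(acc) - n_target) <= abs(len(best) - n_target):
                best = acc
    return SamplingMask.from_lines(n, best, partial_fourier_fraction)


def acquire(
    kspace_full: KSpace,
    mask: SamplingMask,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> KSpace:
    """Measure k-space through the mask with complex Gaussian noise.

    y = mask * (F u + n), with E|n|^2 = noise_sigma^2 per sample (the real
    and imaginary parts each carry half the variance).  Off-mask entries
    are exactly zero.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    k = kspace_full.data
    if k.shape != mask.mask.shape:
        raise ValueError("k-space and mask shapes disagree")
    rng = np.random.default_rng(seed)
    if noise_sigma > 0:
        noise = (rng.standard_normal(k.shape) + 1j * rng.standard_normal(k.shape))
        noise *= noise_sigma / np.sqrt(2.0)
    else:
        noise = 0.0
    y = np.where(mask.mask, k + noise, 0.0)
    return KSpace(y)


def _mirror(arr: np.ndarray) -> np.ndarray:
    """Map each centered k-space location to its conjugate-symmetric twin
    (negated frequency)."""
    n = arr.shape[0]
    # work in unshifted coordinates, where the twin of k is (-k) mod n
    u = np.fft.ifftshift(arr)
    rev = (-np.arange(n)) % n
    u = u[np.ix_(rev, rev)]
    return np.fft.fftshift(u)


def conjugate_support(mask: SamplingMask) -> np.ndarray:
    """Support of the k-space after conjugate filling: acquired locations
    plus mirrors of acquired locations."""
    return mask.mask | _mirror(mask.mask)


def conjugate_fill(measured: KSpace, mask: SamplingMask) -> KSpace:
    """Fill unacquired conjugate-symmetric locations of a partial-Fourier
    acquisition.

    Assumes the underlying image is real-valued (zero phase), so
    F(u)(-k) = conj(F(u)(k)); each unacquired location whose mirrored twin
    was acquired receives the conjugate of the twin.  Acquired entries are
    untouched.
    """
    y = measured.data
    filled = y.copy()
    twin = _mirror(np.conj(y))
    twin_mask = _mirror(mask.mask)
    fill_here = (~mask.mask) & twin_mask
    filled[fill_here] = twin[fill_here]
    return KSpace(filled)
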