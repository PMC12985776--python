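"""Joint MR-PET reconstruction: Poisson fidelity, coupling, Hankel prior,
and the alternating solver."""

import numpy as np
import pytest

from inie.mr import KSpace, SamplingMask, acquire, build_sampling_mask, fourier_encode
from inie.pet import IdentityProjector, Sinogram, default_angles, get_projector, simulate_counts
from inie.recon import (
    ReconState,
    ReconWeights,
    coupling_term,
    hankel_project,
    joint_objective,
    poisson_nll,
    solve_joint,
    tv_value,
    weighted_tv_prox,
)


@pytest.fixture(scope="module")
def problem(two_loop_phantom):
    """Shared 30%-sampled joint problem on a two-loop phantom."""
    ph = two_loop_phantom
    g = ph.grid_size
    ang = default_angles(60)
    proj = get_projector(g, ang)
    expected = proj.project(ph.pet_activity)
    scale = 2e5 / expected.sum()
    sino = simulate_counts(expected * scale, ang, 0.2, seed=1)
    mask = build_sampling_mask(g, 0.3, 1.0, seed=2)
    y = acquire(fourier_encode(ph.mr_image), mask, 0.02, seed=3)
    return ph, y, mask, sino, proj, ph.pet_activity * scale


# ---------------------------------------------------------------------------
# Poisson negative log-likelihood
# ---------------------------------------------------------------------------


def test_poisson_nll_worked_example():
    sino = Sinogram(np.array([[2.0, 3.0]]), np.array([5.0]), 0.0)
    val = poisson_nll(np.array([[2.0, 1.0]]), sino)
    assert val == pytest.approx(3 - 2 * np.log(2), abs=1e-9)


def test_poisson_nll_stationary_at_counts():
    y = np.array([[2.0, 3.0, 1.0]])
    sino = Sinogram(y, np.array([5.0]), 0.0)
    # gradient of the identity-system NLL is 1 - y/x, zero at x = y
    x = y.copy()
    eps = 1e-5
    base = poisson_nll(x, sino)
    for j in range(3):
        xp = x.copy()
        xp[0, j] += eps
        assert abs((poisson_nll(xp, sino) - base) / eps) < 1e-4


def test_poisson_nll_linear_in_randoms_when_counts_zero():
    sino1 = Sinogram(np.zeros((1, 4)), np.array([5.0]), 0.5)
    sino2 = Sinogram(np.zeros((1, 4)), np.array([5.0]), 1.0)
    x = np.zeros((1, 4))
    assert poisson_nll(x, sino2) == pytest.approx(2 * poisson_nll(x, sino1))


def test_poisson_nll_domain_error():
    sino = Sinogram(np.array([[3.0]]), np.array([5.0]), 0.0)
    with pytest.raises(ValueError):
        poisson_nll(np.array([[0.0]]), sino)


def test_poisson_nll_plus_tv_midpoint_convex():
    """Midpoint convexity of the x-objective along 100 random segments."""
    rng = np.random.default_rng(0)
    proj = IdentityProjector(None)
    y = rng.poisson(5.0, (1, 16)).astype(float)
    sino = Sinogram(y, np.array([5.0]), 0.1)

    def f(x):
        return poisson_nll(x, sino) + 0.3 * tv_value(x.reshape(4, 4))

    for _ in range(100):
        a = rng.random((1, 16)) * 5 + 0.1
        b = rng.random((1, 16)) * 5 + 0.1
        mid = 0.5 * (a + b)
        assert f(mid) <= 0.5 * (f(a) + f(b)) + 1e-9


# ---------------------------------------------------------------------------
# coupling term
# ---------------------------------------------------------------------------


def test_coupling_zero_for_flat_pet():
    u = np.random.default_rng(1).random((16, 16))
    val, grad = coupling_term(u, np.full((16, 16), 2.0))
    assert val == pytest.approx(0.0, abs=1e-12)


def test_coupling_prefers_coincident_edges():
    u = np.zeros((1, 40))
    u[0, 20:] = 1.0
    x_same = u.copy()
    x_shift = np.zeros((1, 40))
    x_shift[0, 25:] = 1.0
    c_same, _ = coupling_term(u, x_same)
    c_shift, _ = coupling_term(u, x_shift)
    assert c_same < c_shift


def test_coupling_large_eta_reduces_to_plain_tv():
    rng = np.random.default_rng(2)
    u = rng.random((12, 12))
    x = rng.random((12, 12))
    val, _ = coupling_term(u, x, eta=1e12)
    assert val == pytest.approx(tv_value(x), rel=1e-9)


def test_coupling_gradient_matches_finite_differences():
    rng = np.random.default_rng(3)
    u = rng.random((10, 10))
    x = rng.random((10, 10))
    eps_s = 1e-3
    _, grad = coupling_term(u, x, eps=eps_s)
    from inie.recon import _grad2
    gux, guy = _grad2(u)
    gu = np.hypot(gux, guy)
    eta = np.median(gu[gu > 1e-12])
    w = np.exp(-gu / eta)

    def smooth_val(xx):
        gx, gy = _grad2(xx)
        return float((w * np.sqrt(gx ** 2 + gy ** 2 + eps_s ** 2)).sum())

    h = 1e-6
    idx = [(0, 0), (3, 4), (9, 9), (5, 0)]
    for (i, j) in idx:
        xp = x.copy()
        xp[i, j] += h
        fd = (smooth_val(xp) - smooth_val(x)) / h
        assert grad[i, j] == pytest.approx(fd, rel=1e-3, abs=1e-6)


def test_weighted_tv_prox_denoises():
    rng = np.random.default_rng(4)
    clean = np.zeros((48, 48))
    clean[12:36, 12:36] = 1.0
    noisy = clean + rng.normal(0, 0.3, clean.shape)
    out = weighted_tv_prox(noisy, np.full_like(noisy, 0.3))
    assert np.linalg.norm(out - clean) < 0.5 * np.linalg.norm(noisy - clean)


# ---------------------------------------------------------------------------
# Hankel low-rank projection
# ---------------------------------------------------------------------------


def test_hankel_fixes_single_exponential():
    n = 64
    row = np.exp(2j * np.pi * 0.13 * np.arange(n))
    k = KSpace(np.tile(row, (4, 1)))
    out = hankel_project(k, patch=16, rank=1)
    assert np.abs(out.data - k.data).max() < 1e-8


def test_hankel_iteration_drives_rank_down():
    """Repeated projection (Cadzow iteration) converges to a signal whose
    Hankel matrix has numerical rank <= the requested rank."""
    rng = np.random.default_rng(5)
    k = KSpace(rng.standard_normal((1, 64)) + 1j * rng.standard_normal((1, 64)))
    for _ in range(30):
        k = hankel_project(k, patch=16, rank=3)
    from scipy.linalg import hankel as sp_hankel
    H = sp_hankel(k.data[0, :16], k.data[0, 15:])
    s = np.linalg.svd(H, compute_uv=False)
    assert s[3] / s[0] < 1e-3


def test_hankel_denoises_low_rank_signal():
    rng = np.random.default_rng(6)
    n = 64
    clean = (np.exp(2j * np.pi * 0.07 * np.arange(n))
             + 0.5 * np.exp(2j * np.pi * 0.23 * np.arange(n)))
    noisy = clean + 0.1 * (rng.standard_normal(n) + 1j * rng.standard_normal(n))
    out = hankel_project(KSpace(noisy[None, :]), patch=20, rank=2).data[0]
    assert np.linalg.norm(out - clean) < np.linalg.norm(noisy - clean)


def test_hankel_rank_error():
    with pytest.raises(ValueError):
        hankel_project(KSpace(np.ones((1, 32), complex)), patch=8, rank=9)


# ---------------------------------------------------------------------------
# joint objective and solver
# ---------------------------------------------------------------------------


def test_objective_decouples_without_coupling(problem):
    ph, y, mask, sino, proj, _ = problem
    rng = np.random.default_rng(7)
    state = ReconState(rng.random(ph.mr_image.shape).astype(complex),
                       rng.random(ph.mr_image.shape) + 0.1)
    w0 = ReconWeights(0.1, 0.1, 0.0)
    terms = joint_objective(state, y, mask, sino, w0, proj)
    mr_part = terms["mr_fid"] + 0.1 * terms["tv_mr"]
    pet_part = terms["pet_nll"] + 0.1 * terms["tv_pet"]
    assert terms["total"] == pytest.approx(mr_part + pet_part, rel=1e-12)
    assert terms["coupling"] == 0.0


def test_full_mask_noiseless_recovers_truth(two_loop_phantom):
    ph = two_loop_phantom
    g = ph.grid_size
    full = SamplingMask.from_lines(g, range(g))
    y = acquire(fourier_encode(ph.mr_image), full, 0.0, 0)
    ang = default_angles(12)
    sino = simulate_counts(get_projector(g, ang).project(ph.pet_activity) * 10,
                           ang, 0.0, seed=0)
    st = solve_joint(y, full, sino, ReconWeights(0.0, 0.0, 0.0), n_outer=2)
    nrmse = (np.linalg.norm(np.abs(st.u) - ph.mr_image)
             / np.linalg.norm(ph.mr_image))
    assert nrmse < 1e-3


def test_solver_trace_monotone_trend(problem):
    ph, y, mask, sino, proj, _ = problem
    st = solve_joint(y, mask, sino, n_outer=10, projector=proj)
    tot = st.trace_totals()
    rises = np.diff(tot)
    allowed = 0.01 * np.abs(tot[:-1])
    assert np.all(rises <= allowed)


def test_solver_pet_nonnegative(problem):
    ph, y, mask, sino, proj, _ = problem
    st = solve_joint(y, mask, sino, n_outer=5, projector=proj)
    assert np.all(st.x_pet >= 0)


def test_solver_invariant_to_global_phase(problem):
    ph, y, mask, sino, proj, _ = problem
    st1 = solve_joint(y, mask, sino, n_outer=4, projector=proj)
    y_rot = KSpace(y.data * np.exp(1j * 1.234))
    st2 = solve_joint(y_rot, mask, sino, n_outer=4, projector=proj)
    assert np.abs(np.abs(st2.u) - np.abs(st1.u)).max() < 1e-6


def test_coupling_improves_pet_reconstruction(problem):
    """At 30% MR sampling, enabling the cross-modal coupling strictly
    reduces the PET reconstruction error."""
    ph, y, mask, sino, proj, x_true = problem
    st_c = solve_joint(y, mask, sino, ReconWeights(0.08, 0.05, 0.5),
                       n_outer=10, projector=proj)
    st_0 = solve_joint(y, mask, sino, ReconWeights(0.08, 0.05, 0.0),
                       n_outer=10, projector=proj)
    err_c = np.linalg.norm(st_c.x_pet - x_true)
    err_0 = np.linalg.norm(st_0.x_pet - x_true)
    assert err_c < err_0


def test_weights_validation():
    with pytest.raises(ValueError):
        ReconWeights(lambda1=1.5)
    with pytest.raises(ValueError):
        ReconWeights(hankel_rank=0)
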