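"""Closed-loop acquisition control.

The controller alternates: acquire (MR phase-encode line bundles and/or PET
angle blocks) -> joint reconstruction -> persistence diagram -> topological
uncertainty U_t -> next action, until a topological stopping rule fires or
the measurement budget is exhausted.

Two controllers are provided:

* a deterministic greedy one-step look-ahead (``mode='greedy'``) that scores
  every candidate action by a cheap provisional reconstruction and picks the
  one minimizing the expected uncertainty — used for all quantitative
  evaluation;
* a stochastic actor-critic policy (``mode='policy'``) over the same action
  space, trained by temporal-difference learning with the reward
  R_t = -alpha*U_t - beta*T_t - gamma*||x_t - x_{t-1}||^2.

The topological uncertainty is computed on the MR anatomy channel (the
vascular graph lives in the MR angiogram); PET angle blocks are acquired
until the PET reconstruction self-stabilizes, mirroring the reward's
stability term.  See docs/methods.md for the rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mr import KSpace, SamplingMask, acquire, fourier_encode
from .pet import Sinogram, default_angles, get_projector, simulate_counts
from .phantom import Phantom, ground_truth_diagram
from .recon import ReconWeights, solve_joint, zero_filled_recon
from .topology import (
    PersistenceDiagram,
    UncertaintyWeights,
    betti_numbers,
    extract_graph,
    normalized_persistence_deviation,
    persistence_diagram,
    topological_uncertainty,
)

__all__ = ["ControllerState", "ActionSpace", "RewardConfig", "PolicyModel",
           "ClosedLoopTrace", "LoopConfig", "reward", "greedy_select",
           "actor_critic_update", "run_closed_loop", "train_policy"]


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------


@dataclass
class ControllerState:
    """Fixed-length numerical descriptor of the evolving acquisition.

    Entries: beta0, beta1, total persistence (degree 0), total persistence
    (degree 1), current U_t, fraction of budget used, fraction of k-space
    lines acquired, fraction of PET angles acquired.
    """

    descriptor: np.ndarray
    step: int = 0

    def __post_init__(self) -> None:
        self.descriptor = np.asarray(self.descriptor, dtype=np.float64)
        if not np.all(np.isfinite(self.descriptor)):
            raise ValueError("state descriptor must be finite")


@dataclass
class Action:
    """One acquisition action: a bundle of k-space lines or a block of PET
    angle indices."""

    kind: str            # "mr" or "pet"
    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("mr", "pet"):
            raise ValueError("action kind must be 'mr' or 'pet'")
        self.indices = tuple(int(i) for i in self.indices)


@dataclass
class ActionSpace:
    """Disjoint candidate bundles/blocks, never overlapping the visited set."""

    candidate_mr_bundles: list[tuple[int, ...]]
    candidate_pet_blocks: list[tuple[int, ...]]
    visited_lines: set = field(default_factory=set)
    visited_angles: set = field(default_factory=set)

    def __post_init__(self) -> None:
        for b in self.candidate_mr_bundles:
            if self.visited_lines & set(b):
                raise ValueError("MR candidate overlaps visited lines")
        for b in self.candidate_pet_blocks:
            if self.visited_angles & set(b):
                raise ValueError("PET candidate overlaps visited angles")

    def actions(self) -> list[Action]:
        return [Action("mr", b) for b in self.candidate_mr_bundles] + [
            Action("pet", b) for b in self.candidate_pet_blocks
        ]

    def remove(self, action: Action) -> None:
        if action.kind == "mr":
            self.candidate_mr_bundles.remove(tuple(action.indices))
            self.visited_lines |= set(action.indices)
        else:
            self.candidate_pet_blocks.remove(tuple(action.indices))
            self.visited_angles |= set(action.indices)


@dataclass
class RewardConfig:
    """Weights of the immediate reward R_t = -alpha*U_t - beta*T_t
    - gamma_smooth*||x_t - x_{t-1}||^2.

    ``gamma_smooth`` is the reward's stability weight (the RL discount
    factor is a separate quantity, ``PolicyModel.discount_factor``).
    ``time_per_line``/``time_per_angle`` convert acquired units into the
    cumulative time proxy T_t.
    """

    alpha: float = 1.0
    beta: float = 1.0
    gamma_smooth: float = 0.1
    time_per_line: float = 1.0 / 188.0
    time_per_angle: float = 1.0 / 188.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma_smooth", "time_per_line",
                     "time_per_angle"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def reward(u_t: float, t_cost: float, x_t: np.ndarray, x_prev: np.ndarray,
           cfg: RewardConfig) -> float:
    """Immediate reward: exact weighted sum of topological uncertainty,
    cumulative acquisition time, and squared inter-iteration image change."""
    x_t = np.asarray(x_t, dtype=np.float64)
    x_prev = np.asarray(x_prev, dtype=np.float64)
    if x_t.shape != x_prev.shape:
        raise ValueError("x_t and x_prev must share shape")
    change = float(np.sum((x_t - x_prev) ** 2))
    return -cfg.alpha * u_t - cfg.beta * t_cost - cfg.gamma_smooth * change


def greedy_select(state: ControllerState, actions: ActionSpace,
                  lookahead_recon) -> Action:
    """One-step look-ahead: evaluate each candidate with the cheap
    reconstruction handle (mapping action -> expected U after acquiring it)
    and return the argmin; ties broken by candidate order."""
    cands = actions.actions()
    if not cands:
        raise ValueError("no candidate actions available")
    best, best_u = None, np.inf
    for a in cands:
        u = float(lookahead_recon(a))
        if u < best_u - 1e-15:
            best, best_u = a, u
    return best if best is not None else cands[0]


# ---------------------------------------------------------------------------
# actor-critic policy (numpy, manual backprop)
# ---------------------------------------------------------------------------

STATE_DIM = 8
ACTION_FEATURE_DIM = 4


def action_features(action: Action, n_lines: int, n_angles: int) -> np.ndarray:
    """Per-candidate features: modality one-hot, normalized distance of the
    bundle center from the k-space center (0 for PET), bundle size share."""
    if action.kind == "mr":
        center = np.mean(action.indices)
        dist = abs(center - n_lines / 2) / (n_lines / 2)
        return np.array([1.0, 0.0, dist, len(action.indices) / n_lines])
    return np.array([0.0, 1.0, 0.0, len(action.indices) / n_angles])


class PolicyModel:
    """Two-layer perceptron actor + critic.

    The actor scores each candidate from the concatenated state descriptor
    and action features and normalizes the scores with a softmax, so the
    output is a proper distribution over the current candidates.  The
    critic maps the state descriptor to a scalar value estimate.
    """

    def __init__(self, hidden: int = 32, discount_factor: float = 0.99,
                 seed: int = 0):
        if not 0 < discount_factor <= 1:
            raise ValueError("discount factor must be in (0, 1]")
        rng = np.random.default_rng(seed)
        d = STATE_DIM + ACTION_FEATURE_DIM
        s = 1.0 / np.sqrt(d)
        self.W1 = rng.normal(0, s, (hidden, d))
        self.b1 = np.zeros(hidden)
        self.W2 = rng.normal(0, 1.0 / np.sqrt(hidden), hidden)
        self.b2 = 0.0
        sc = 1.0 / np.sqrt(STATE_DIM)
        self.V1 = rng.normal(0, sc, (hidden, STATE_DIM))
        self.c1 = np.zeros(hidden)
        self.V2 = rng.normal(0, 1.0 / np.sqrt(hidden), hidden)
        self.c2 = 0.0
        self.discount_factor = discount_factor
        # feature counts and persistence mass are O(10); bring the state
        # descriptor to the same O(1) scale as the action features so the
        # shared input layer can condition on both
        self.input_scale = np.array([1 / 32, 1 / 32, 1 / 8, 1 / 8, 1, 1, 1, 1])

    def _scaled(self, state: np.ndarray) -> np.ndarray:
        return np.asarray(state, dtype=np.float64) * self.input_scale

    # -- actor ------------------------------------------------------------
    def logits(self, state: np.ndarray, feats: np.ndarray) -> np.ndarray:
        state = self._scaled(state)
        z = np.concatenate(
            (np.broadcast_to(state, (feats.shape[0], state.shape[0])), feats),
            axis=1,
        )
        h = np.tanh(z @ self.W1.T + self.b1)
        return h @ self.W2 + self.b2

    def probabilities(self, state: np.ndarray, feats: np.ndarray) -> np.ndarray:
        lg = self.logits(state, feats)
        lg = lg - lg.max()
        p = np.exp(lg)
        return p / p.sum()

    def log_prob_grad(self, state: np.ndarray, feats: np.ndarray,
                      chosen: int):
        """log pi(a|s) and its gradient w.r.t. actor parameters."""
        state = self._scaled(state)
        z = np.concatenate(
            (np.broadcast_to(state, (feats.shape[0], state.shape[0])), feats),
            axis=1,
        )
        pre = z @ self.W1.T + self.b1
        h = np.tanh(pre)
        lg = h @ self.W2 + self.b2
        lg = lg - lg.max()
        p = np.exp(lg)
        p = p / p.sum()
        logp = float(np.log(p[chosen] + 1e-300))
        # d logp / d logits = onehot - p
        dlg = -p.copy()
        dlg[chosen] += 1.0
        gW2 = dlg @ h
        gb2 = dlg.sum()
        dh = np.outer(dlg, self.W2)
        dpre = dh * (1.0 - h * h)
        gW1 = dpre.T @ z
        gb1 = dpre.sum(axis=0)
        return logp, p, {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2}

    # -- critic -----------------------------------------------------------
    def value(self, state: np.ndarray) -> float:
        state = self._scaled(state)
        h = np.tanh(self.V1 @ state + self.c1)
        return float(self.V2 @ h + self.c2)

    def value_grad(self, state: np.ndarray):
        state = self._scaled(state)
        h = np.tanh(self.V1 @ state + self.c1)
        v = float(self.V2 @ h + self.c2)
        dh = self.V2 * (1.0 - h * h)
        return v, {"V1": np.outer(dh, state), "c1": dh, "V2": h, "c2": 1.0}

    def sample(self, state: np.ndarray, feats: np.ndarray,
               rng: np.random.Generator) -> int:
        p = self.probabilities(state, feats)
        return int(rng.choice(len(p), p=p))


def actor_critic_update(
    trajectory: list,
    policy: PolicyModel,
    lr_actor: float = 1e-3,
    lr_critic: float = 1e-2,
    entropy_bonus: float = 0.01,
) -> dict:
    """One advantage actor-critic pass over a trajectory.

    Each trajectory element is (state_vec, candidate_features, chosen_index,
    reward, next_state_vec or None).  The critic is updated by squared
    TD-error; the actor by score-function gradients weighted with the
    TD advantage (target - V(s)), plus an entropy bonus.  Raises on
    non-finite losses.
    """
    if not trajectory:
        raise ValueError("trajectory must be non-empty")
    g = policy.discount_factor
    actor_loss = 0.0
    critic_loss = 0.0
    for (s, feats, a_idx, r, s_next) in trajectory:
        v, vgrad = policy.value_grad(s)
        target = r + (g * policy.value(s_next) if s_next is not None else 0.0)
        adv = target - v
        # critic: gradient of 0.5 * (v - target)^2 (target held fixed)
        for k, gk in vgrad.items():
            setattr(policy, k, getattr(policy, k) + lr_critic * adv * np.asarray(gk))
        critic_loss += 0.5 * adv ** 2
        # actor: ascend logp * advantage + entropy
        logp, p, agrad = policy.log_prob_grad(s, feats, a_idx)
        ent = -float(np.sum(p * np.log(p + 1e-300)))
        # entropy gradient through logits: dH/dlogit_j = -p_j (log p_j + ent)
        dlg_ent = -p * (np.log(p + 1e-300) + ent)
        s_sc = policy._scaled(s)
        z = np.concatenate(
            (np.broadcast_to(s_sc, (feats.shape[0], s_sc.shape[0])), feats), axis=1
        )
        pre = z @ policy.W1.T + policy.b1
        h = np.tanh(pre)
        gW2e = dlg_ent @ h
        gb2e = dlg_ent.sum()
        dh = np.outer(dlg_ent, policy.W2)
        dpre = dh * (1.0 - h * h)
        gW1e = dpre.T @ z
        gb1e = dpre.sum(axis=0)
        egrad = {"W1": gW1e, "b1": gb1e, "W2": gW2e, "b2": gb2e}
        for k in agrad:
            step = adv * np.asarray(agrad[k]) + entropy_bonus * np.asarray(egrad[k])
            setattr(policy, k, getattr(policy, k) + lr_actor * step)
        actor_loss += -logp * adv - entropy_bonus * ent
    losses = {"actor": actor_loss / len(trajectory),
              "critic": critic_loss / len(trajectory)}
    if not all(np.isfinite(v) for v in losses.values()):
        raise FloatingPointError("non-finite actor-critic loss")
    return losses


# ---------------------------------------------------------------------------
# closed loop
# ---------------------------------------------------------------------------


@dataclass
class LoopConfig:
    """Closed-loop settings (all defaults are the package's study
    conditions; see docs/methods.md)."""

    n_angles: int = 60
    bundle_size: int = 8
    pet_block_size: int = 5
    center_fraction: float = 0.08      # warm-start share of k-space lines
    n_warm_pet_blocks: int = 2         # coarse uniform warm-start angles
    partial_fourier_fraction: float = 0.625
    noise_sigma: float = 0.02
    total_counts: float = 2e5
    randoms_rate: float = 0.2
    pet_chi2_threshold: float = 1.5
    stop_threshold: float = 3.0        # percent, persistence deviation
    stop_patience: int = 2
    n_outer: int = 8
    control_prune: float = 0.05
    weights: ReconWeights = field(default_factory=ReconWeights)
    uncertainty: UncertaintyWeights = field(default_factory=UncertaintyWeights)
    reward: RewardConfig = field(default_factory=RewardConfig)


@dataclass
class StepRecord:
    action: Action | None
    reward: float
    u_t: float
    t_cost: float
    sampling_fraction: float
    deviation_pct: float


@dataclass
class ClosedLoopTrace:
    """Per-step records plus final Tier-I metrics of one episode."""

    steps: list[StepRecord]
    final_metrics: dict
    failed: bool = False

    @property
    def sampling_fractions(self) -> np.ndarray:
        return np.array([s.sampling_fraction for s in self.steps])


def _mr_line_bundles(allowed: np.ndarray, visited: set, size: int):
    """Disjoint bundles of unacquired allowed lines, grouped by contiguous
    position (center-out ordering is induced by the candidates' scores)."""
    free = [int(l) for l in allowed if l not in visited]
    return [tuple(free[i : i + size]) for i in range(0, len(free) - size + 1, size)]


def _pet_blocks(n_angles: int, visited: set, size: int):
    free = [a for a in range(n_angles) if a not in visited]
    return [tuple(free[i : i + size]) for i in range(0, len(free) - size + 1, size)]


class _Episode:
    """Simulation state shared by the greedy and policy controllers."""

    def __init__(self, phantom: Phantom, cfg: LoopConfig, seed: int):
        self.ph = phantom
        self.cfg = cfg
        self.g = phantom.grid_size
        rng = np.random.default_rng(seed)
        self.noise_seed = int(rng.integers(2 ** 31 - 10))
        self.pet_seed = int(rng.integers(2 ** 31 - 10))
        self.rng = rng

        self.full_angles = default_angles(cfg.n_angles)
        self.k_true = fourier_encode(phantom.mr_image)
        proj_full = get_projector(self.g, self.full_angles)
        expected = proj_full.project(phantom.pet_activity)
        self.count_scale = cfg.total_counts / expected.sum()
        self.expected_full = expected * self.count_scale
        # one latent count realization; acquiring an angle reveals its row
        self.counts_full = np.random.default_rng(self.pet_seed).poisson(
            self.expected_full + cfg.randoms_rate
        )

        limit = int(np.ceil(cfg.partial_fourier_fraction * self.g))
        self.allowed_lines = np.arange(limit)
        n_center = max(2, int(round(cfg.center_fraction * self.g)))
        c = self.g // 2
        self.warm_lines = [l for l in range(c - n_center // 2, c + (n_center + 1) // 2)]
        warm_angle_count = cfg.n_warm_pet_blocks * cfg.pet_block_size
        warm_angles = np.round(
            np.linspace(0, cfg.n_angles - 1, warm_angle_count)
        ).astype(int)
        self.acquired_lines: set = set(self.warm_lines)
        self.acquired_angles: set = set(int(a) for a in warm_angles)

        self.d_star = ground_truth_diagram(phantom)
        self.state_mr = None
        self.x_prev = None
        self.pet_converged = False

    def pet_block_chi2(self, block, x_est: np.ndarray) -> float:
        """Poisson-standardized out-of-sample misfit of a newly measured
        angle block against the forward projection of the current estimate;
        ~1 when the block carries no information beyond noise."""
        idx = np.array(sorted(block))
        pred = get_projector(self.g, self.full_angles[idx]).project(x_est) \
            + self.cfg.randoms_rate
        y = self.counts_full[idx]
        return float(np.mean((y - pred) ** 2 / np.maximum(pred, 1e-9)))

    # -- acquisition helpers ---------------------------------------------
    def current_mask(self) -> SamplingMask:
        return SamplingMask.from_lines(
            self.g, sorted(self.acquired_lines), self.cfg.partial_fourier_fraction
        )

    def measured_kspace(self, mask: SamplingMask) -> KSpace:
        return acquire(self.k_true, mask, self.cfg.noise_sigma, self.noise_seed)

    def current_sinogram(self) -> Sinogram:
        idx = np.array(sorted(self.acquired_angles))
        return Sinogram(
            self.counts_full[idx], self.full_angles[idx], self.cfg.randoms_rate
        )

    def units_acquired(self) -> int:
        return len(self.acquired_lines) + len(self.acquired_angles)

    def total_units(self) -> int:
        return self.g + self.cfg.n_angles

    def sampling_fraction(self) -> float:
        return self.units_acquired() / self.total_units()

    # -- reconstruction and topology --------------------------------------
    def reconstruct(self):
        mask = self.current_mask()
        y = self.measured_kspace(mask)
        sino = self.current_sinogram()
        proj = get_projector(self.g, sino.angles)
        st = solve_joint(
            y, mask, sino, self.cfg.weights, n_outer=self.cfg.n_outer,
            projector=proj,
        )
        return st

    def mr_diagram(self, u: np.ndarray) -> PersistenceDiagram:
        return persistence_diagram(np.abs(u))

    def uncertainty(self, d: PersistenceDiagram, d_ref: PersistenceDiagram) -> float:
        return topological_uncertainty(
            d.prune(self.cfg.control_prune), d_ref.prune(self.cfg.control_prune),
            self.cfg.uncertainty, method="exact",
        )

    def cheap_mr_u(self, extra_lines, d_ref: PersistenceDiagram) -> float:
        lines = sorted(self.acquired_lines | set(extra_lines))
        mask = SamplingMask.from_lines(self.g, lines, self.cfg.partial_fourier_fraction)
        y = self.measured_kspace(mask)
        u = zero_filled_recon(y, mask)
        return self.uncertainty(self.mr_diagram(u), d_ref)

    def descriptor(self, d: PersistenceDiagram, u_t: float, budget: float) -> np.ndarray:
        dp = d.prune(self.cfg.control_prune)
        return np.array(
            [
                dp.count_features(0),
                dp.count_features(1),
                dp.total_persistence(0),
                dp.total_persistence(1),
                u_t,
                min(self.sampling_fraction() / budget, 1.0),
                len(self.acquired_lines) / self.g,
                len(self.acquired_angles) / self.cfg.n_angles,
            ]
        )


def _reference_reconstruction(phantom: Phantom, cfg: LoopConfig, seed: int):
    """Fully sampled reference: all k-space lines, all angles, same solver;
    independent noise realization."""
    g = phantom.grid_size
    rng = np.random.default_rng(seed + 777)
    angles = default_angles(cfg.n_angles)
    proj = get_projector(g, angles)
    expected = proj.project(phantom.pet_activity)
    scale = cfg.total_counts / expected.sum()
    sino = simulate_counts(expected * scale, angles, cfg.randoms_rate,
                           int(rng.integers(2 ** 31 - 10)))
    mask = SamplingMask.from_lines(g, range(g), 1.0)
    y = acquire(fourier_encode(phantom.mr_image), mask, cfg.noise_sigma,
                int(rng.integers(2 ** 31 - 10)))
    return solve_joint(y, mask, sino, cfg.weights, n_outer=cfg.n_outer,
                       projector=proj)


def run_closed_loop(
    phantom: Phantom,
    mode: str = "greedy",
    budget: float = 1.0,
    stop_threshold: float | None = None,
    seed: int = 0,
    cfg: LoopConfig | None = None,
    policy: PolicyModel | None = None,
    reference_state=None,
) -> ClosedLoopTrace:
    """Run one closed-loop acquisition episode on a phantom.

    Per step: the controller (greedy look-ahead or stochastic policy) picks
    a k-space line bundle or PET angle block, the joint reconstruction is
    updated, the persistence diagram and uncertainty U_t are recomputed,
    and the reward is logged.  The episode stops when the normalized
    persistence deviation against the converged (fully sampled) reference
    reconstruction stays below the threshold for ``stop_patience``
    consecutive steps and the PET side has stabilized, or when the budget
    (as a fraction of all measurable units) is exhausted.

    Fully reproducible for a fixed seed.  Reconstruction failures mark the
    episode as failed instead of raising.
    """
    if not 0 < budget <= 1:
        raise ValueError("budget must be in (0, 1]")
    if mode not in ("greedy", "policy"):
        raise ValueError("mode must be 'greedy' or 'policy'")
    cfg = cfg or LoopConfig()
    if stop_threshold is None:
        stop_threshold = cfg.stop_threshold
    ep = _Episode(phantom, cfg, seed)
    rng = np.random.default_rng(seed + 1)

    ref = reference_state if reference_state is not None else \
        _reference_reconstruction(phantom, cfg, seed)
    d_ref = persistence_diagram(np.abs(ref.u))

    steps: list[StepRecord] = []
    failed = False
    below = 0
    try:
        st = ep.reconstruct()
    except Exception:
        return ClosedLoopTrace([], {}, failed=True)
    d = ep.mr_diagram(st.u)
    u_t = ep.uncertainty(d, d_ref)
    dev = normalized_persistence_deviation(d, d_ref, cfg.uncertainty, method="exact")
    t_cost = (len(ep.acquired_lines) * cfg.reward.time_per_line
              + len(ep.acquired_angles) * cfg.reward.time_per_angle)
    r0 = reward(u_t, t_cost, np.abs(st.u), np.abs(st.u), cfg.reward)
    steps.append(StepRecord(None, r0, u_t, t_cost, ep.sampling_fraction(), dev))
    ep.x_prev = np.abs(st.u)
    if dev <= stop_threshold:
        below = 1

    max_steps = 100
    if np.isinf(stop_threshold):
        max_steps = 1  # no topological requirement: stop after the warm start
    while len(steps) < max_steps:
        if ep.sampling_fraction() >= budget - 1e-12:
            break
        if below >= cfg.stop_patience and ep.pet_converged:
            break
        mr_bundles = _mr_line_bundles(ep.allowed_lines, ep.acquired_lines,
                                      cfg.bundle_size)
        pet_blocks = [] if ep.pet_converged else _pet_blocks(
            cfg.n_angles, ep.acquired_angles, cfg.pet_block_size
        )
        space = ActionSpace(mr_bundles, pet_blocks,
                            set(ep.acquired_lines), set(ep.acquired_angles))
        cands = space.actions()
        if not cands:
            break

        base_u = ep.cheap_mr_u((), d_ref)  # status quo on the look-ahead scale

        def lookahead(a: Action) -> float:
            if a.kind == "mr":
                return ep.cheap_mr_u(a.indices, d_ref)
            # a PET block cannot move the MR anatomy diagram; its value is
            # PET stabilization, granted while PET has not converged
            return base_u * (0.999 if not ep.pet_converged else 1.001)

        if mode == "greedy":
            if below >= cfg.stop_patience and pet_blocks:
                # MR topology settled: finish PET stabilization first
                action = Action("pet", pet_blocks[0])
            else:
                action = greedy_select(
                    ControllerState(ep.descriptor(d, u_t, budget), len(steps)),
                    space, lookahead,
                )
        else:
            if policy is None:
                raise ValueError("policy mode requires a PolicyModel")
            svec = ep.descriptor(d, u_t, budget)
            feats = np.stack([action_features(a, ep.g, cfg.n_angles) for a in cands])
            action = cands[policy.sample(svec, feats, rng)]

        if action.kind == "mr":
            ep.acquired_lines |= set(action.indices)
        else:
            # out-of-sample consistency of the new block, judged against the
            # estimate reconstructed before the block was measured
            if ep.pet_block_chi2(action.indices, st.x_pet) <= cfg.pet_chi2_threshold:
                ep.pet_converged = True
            ep.acquired_angles |= set(action.indices)

        try:
            st = ep.reconstruct()
        except Exception:
            failed = True
            break
        d = ep.mr_diagram(st.u)
        u_t = ep.uncertainty(d, d_ref)
        dev = normalized_persistence_deviation(d, d_ref, cfg.uncertainty,
                                               method="exact")
        if not ep.pet_converged and not _pet_blocks(
            cfg.n_angles, ep.acquired_angles, cfg.pet_block_size
        ):
            ep.pet_converged = True  # nothing left to measure

        t_cost = (len(ep.acquired_lines) * cfg.reward.time_per_line
                  + len(ep.acquired_angles) * cfg.reward.time_per_angle)
        x_now = np.abs(st.u)
        r = reward(u_t, t_cost, x_now, ep.x_prev, cfg.reward)
        ep.x_prev = x_now
        steps.append(StepRecord(action, r, u_t, t_cost, ep.sampling_fraction(), dev))
        below = below + 1 if dev <= stop_threshold else 0

    # final metrics against the converged reference
    g_ref = extract_graph(np.abs(ref.u))
    g_acc = extract_graph(np.abs(st.u)) if steps else None
    b_ref = betti_numbers(g_ref)
    b_acc = betti_numbers(g_acc) if g_acc is not None else (0, 0)
    frac = ep.sampling_fraction()
    final = {
        "sampling_fraction_pct": 100.0 * frac,
        "sampling_reduction_pct": 100.0 * (1.0 - frac),
        "persistence_deviation_pct": dev if steps else float("nan"),
        "delta_beta0_pct": 100.0 * abs(b_acc[0] - b_ref[0]) / max(b_ref[0], 1),
        "delta_beta1_pct": (100.0 * abs(b_acc[1] - b_ref[1]) / b_ref[1]
                            if b_ref[1] > 0 else 0.0),
        "beta_ref": b_ref,
        "beta_acc": b_acc,
        "n_lines": len(ep.acquired_lines),
        "n_angles": len(ep.acquired_angles),
        "n_steps": len(steps),
    }
    return ClosedLoopTrace(steps, final, failed=failed)


def train_policy(
    n_episodes: int = 100,
    seed: int = 0,
    grid_size: int = 96,
    policy: PolicyModel | None = None,
    lr_actor: float = 1e-3,
    lr_critic: float = 1e-2,
    cfg: LoopConfig | None = None,
) -> PolicyModel:
    """Train the actor-critic policy on a fast surrogate environment.

    Episodes run on small phantoms with the cheap (zero-filled) MR
    reconstruction only, so the reward signal is dominated by the
    topological uncertainty and time terms; the trained policy transfers
    to the full loop through the shared state/action encoding.
    """
    from .phantom import generate_vessel_tree, rasterize_phantom

    cfg = cfg or LoopConfig(n_outer=2)
    policy = policy or PolicyModel(seed=seed)
    rng = np.random.default_rng(seed)
    for epi in range(n_episodes):
        ph = rasterize_phantom(
            generate_vessel_tree(int(rng.integers(2 ** 31 - 10)),
                                 n_loops=int(rng.integers(0, 4))),
            grid_size,
        )
        traj = _surrogate_episode(ph, policy, cfg, int(rng.integers(2 ** 31 - 10)))
        if traj:
            actor_critic_update(traj, policy, lr_actor, lr_critic)
    return policy


def _surrogate_episode(phantom: Phantom, policy: PolicyModel, cfg: LoopConfig,
                       seed: int, max_steps: int = 8):
    """Cheap episode for policy training/evaluation: zero-filled MR recon,
    no PET reconstruction (PET actions only cost time)."""
    ep = _Episode(phantom, cfg, seed)
    rng = np.random.default_rng(seed + 1)
    d_ref = ep.d_star
    mask = ep.current_mask()
    u = zero_filled_recon(ep.measured_kspace(mask), mask)
    d = ep.mr_diagram(u)
    u_t = ep.uncertainty(d, d_ref)
    x_prev = u
    traj = []
    for step in range(max_steps):
        mr_bundles = _mr_line_bundles(ep.allowed_lines, ep.acquired_lines,
                                      cfg.bundle_size)
        pet_blocks = _pet_blocks(cfg.n_angles, ep.acquired_angles,
                                 cfg.pet_block_size)
        space = ActionSpace(mr_bundles, pet_blocks,
                            set(ep.acquired_lines), set(ep.acquired_angles))
        cands = space.actions()
        if not cands:
            break
        svec = ep.descriptor(d, u_t, 1.0)
        feats = np.stack([action_features(a, ep.g, cfg.n_angles) for a in cands])
        a_idx = policy.sample(svec, feats, rng)
        action = cands[a_idx]
        if action.kind == "mr":
            ep.acquired_lines |= set(action.indices)
        else:
            ep.acquired_angles |= set(action.indices)
        mask = ep.current_mask()
        u = zero_filled_recon(ep.measured_kspace(mask), mask)
        d = ep.mr_diagram(u)
        u_t = ep.uncertainty(d, d_ref)
        t_cost = (len(ep.acquired_lines) * cfg.reward.time_per_line
                  + len(ep.acquired_angles) * cfg.reward.time_per_angle)
        r = reward(u_t, t_cost, u, x_prev, cfg.reward)
        x_prev = u
        s_next = ep.descriptor(d, u_t, 1.0) if step < max_steps - 1 else None
        traj.append((svec, feats, a_idx, r, s_next))
    return traj
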