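"""Firefly Sigma Seeker: dispersion-adaptive early stopping + firefly search.

Two pieces cooperate:

* an early-stopping rule whose threshold theta is proportional to the
  population standard deviation of recent validation losses
  (theta = sigma_mult * sigma_loss), alongside the plain
  min-delta/patience rule;
* a firefly-swarm optimizer that searches hyperparameter space (by
  default the sensitivity multiplier sigma_mult jointly with the pruning
  strength alpha): candidates move toward brighter (lower-loss) peers
  with an attraction that decays exponentially with Euclidean distance,
  plus a uniform random perturbation.

All stochastic pieces run off an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "loss_stddev",
    "EarlyStopState",
    "compute_threshold",
    "should_stop",
    "update_threshold",
    "Firefly",
    "SwarmConfig",
    "update_attractiveness",
    "firefly_step",
    "optimize",
]


# ---------------------------------------------------------------------------
# loss dispersion and the adaptive stopping rule
# ---------------------------------------------------------------------------


def loss_stddev(history, window: int) -> float:
    """Population standard deviation of the last ``window`` losses.

    sqrt((1/N) sum (loss_i - mean)^2); zero iff the window is constant.
    """
    values = np.asarray(list(history), dtype=np.float64)
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if window > len(values):
        raise ValueError(
            f"window {window} exceeds history length {len(values)}"
        )
    tail = values[-window:]
    return float(np.sqrt(np.mean((tail - tail.mean()) ** 2)))


@dataclass
class EarlyStopState:
    """Threshold, sensitivity and patience bookkeeping for early stopping.

    ``sigma_mult`` is the tunable sensitivity multiplier the firefly
    search optimizes; ``theta`` is the current adaptive threshold;
    ``min_delta``/``patience`` implement the plain improvement rule
    (stop when validation loss has not improved by at least ``min_delta``
    for ``patience`` epochs).  ``eta_theta`` is the learning rate of the
    gradient-style threshold update.
    """

    sigma_mult: float = 1.0
    theta: float = 0.0
    patience: int = 10
    min_delta: float = 0.01
    eta_theta: float = 0.1
    theta_max: float = 1.0
    window: int = 10
    best_loss_so_far: float = np.inf
    epochs_without_improvement: int = 0

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.min_delta < 0:
            raise ValueError("min_delta must be >= 0")


def compute_threshold(state: EarlyStopState, dispersion: float) -> float:
    """theta = sigma_mult * sigma_loss; zero dispersion gives zero theta."""
    if dispersion < 0:
        raise ValueError(f"dispersion must be >= 0, got {dispersion}")
    return state.sigma_mult * dispersion


def should_stop(state: EarlyStopState, history) -> tuple[bool, str]:
    """Decide whether training should stop, and why.

    Rule (a), the adaptive rule: the epoch-over-epoch loss decrease has
    stayed below theta for ``patience`` consecutive epochs, where the
    theta compared against transition t is computed from the window of
    losses ending at epoch t.  Rule (b), the plain rule: the best loss
    has not improved by at least ``min_delta`` for ``patience`` epochs.
    Neither rule can fire before ``patience`` transitions exist.

    Returns ``(stop, reason)`` with reason in
    {"fss_threshold", "patience", "continue"}.
    """
    values = np.asarray(list(history), dtype=np.float64)
    if len(values) == 0:
        raise ValueError("loss history is empty")

    # rule (b): min-delta / patience on the best loss so far
    best = np.inf
    stale = 0
    for v in values:
        if best - v >= state.min_delta:
            best = v
            stale = 0
        else:
            best = min(best, v)
            stale += 1
    if stale >= state.patience:
        return True, "patience"

    # rule (a): per-epoch decrease below the adaptive threshold
    if len(values) >= state.patience + 1:
        run = 0
        for t in range(len(values) - state.patience, len(values)):
            w = min(state.window, t + 1)
            theta_t = compute_threshold(state, loss_stddev(values[: t + 1], w))
            decrease = values[t - 1] - values[t]
            if decrease < theta_t:
                run += 1
            else:
                run = 0
        if run >= state.patience:
            return True, "fss_threshold"
    return False, "continue"


def update_threshold(state: EarlyStopState, surrogate_gradient: float) -> EarlyStopState:
    """Gradient-style threshold update: theta <- clamp(theta - eta * g).

    Hard pruning has no true gradient in the threshold, so ``g`` is a
    caller-supplied surrogate (the training loop uses a central finite
    difference of the validation loss under masks built at theta +/- delta).
    The result is clamped to [0, theta_max].
    """
    if state.eta_theta < 0:
        raise ValueError("eta_theta must be >= 0")
    state.theta = float(
        np.clip(state.theta - state.eta_theta * surrogate_gradient, 0.0, state.theta_max)
    )
    return state


# ---------------------------------------------------------------------------
# firefly swarm
# ---------------------------------------------------------------------------


@dataclass
class Firefly:
    position: np.ndarray
    brightness: float  # objective value; lower is brighter (minimization)
    attractiveness: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=np.float64)
        if self.attractiveness <= 0:
            raise ValueError("attractiveness must be > 0")


@dataclass
class SwarmConfig:
    """Search-space box and movement parameters of the swarm.

    The symbol gamma plays two roles in the update rules and is split
    here: ``gamma_abs`` is the exponential decay rate of attractiveness
    with distance, ``gamma_rand`` scales the uniform random perturbation.
    ``rand_decay`` geometrically shrinks the perturbation each iteration
    so the swarm settles once it has located a basin.
    """

    bounds: tuple[tuple[float, float], ...] = ((0.1, 5.0), (0.0, 2.0))
    population: int = 15
    iterations: int = 50
    beta: float = 1.0
    gamma_abs: float = 1.0
    gamma_rand: float = 0.3
    rand_decay: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if min(self.beta, self.gamma_abs, self.gamma_rand) < 0:
            raise ValueError("beta, gamma_abs, gamma_rand must be >= 0")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"bound ({lo}, {hi}) must satisfy lo < hi")


def update_attractiveness(A: float, gamma_abs: float, distance: float) -> float:
    """A * exp(-gamma * d): unchanged at d = 0, never exceeds A."""
    if A <= 0:
        raise ValueError("attractiveness must be > 0")
    if distance < 0:
        raise ValueError(f"distance must be >= 0, got {distance}")
    return A * np.exp(-gamma_abs * distance)


def firefly_step(
    swarm: list[Firefly],
    config: SwarmConfig,
    rng: np.random.Generator,
    objective,
    gamma_rand: float | None = None,
) -> list[Firefly]:
    """One synchronous swarm update.

    Every firefly moves sequentially toward each brighter peer by
    beta * A_eff * (x_j - x_i), where A_eff is the peer's attractiveness
    decayed over the pair distance.  Distances are measured in units of
    the box diagonal, which makes the decay rate scale-invariant across
    search spaces.  Each firefly then receives a uniform perturbation
    gamma_rand * range * U[-0.5, 0.5] per dimension (range is the box
    width of that dimension).  Positions are clamped to the box; each
    firefly's stored attractiveness then decays exponentially with the
    distance it just moved, so a settled swarm keeps attracting while
    large jumps damp it; brightness is re-evaluated last.
    """
    if not swarm:
        raise ValueError("swarm is empty")
    if gamma_rand is None:
        gamma_rand = config.gamma_rand
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    span = hi - lo
    diag = float(np.linalg.norm(span))
    old = [(f.position.copy(), f.brightness, f.attractiveness) for f in swarm]
    for i, f in enumerate(swarm):
        x = f.position.copy()
        for j, (xj, bj, aj) in enumerate(old):
            if (bj, j) < (old[i][1], i):  # j is brighter; ties break by index
                d = float(np.linalg.norm(xj - x)) / diag
                a_eff = update_attractiveness(aj, config.gamma_abs, d)
                x = x + config.beta * a_eff * (xj - x)
        x = x + gamma_rand * span * rng.uniform(-0.5, 0.5, size=x.shape)
        f.position = np.clip(x, lo, hi)
    for i, f in enumerate(swarm):
        moved = float(np.linalg.norm(f.position - old[i][0])) / diag
        f.attractiveness = update_attractiveness(
            f.attractiveness, config.gamma_abs, moved
        )
        val = objective(f.position)
        f.brightness = float(val) if np.isfinite(val) else np.inf
    return swarm


def optimize(objective, config: SwarmConfig) -> dict:
    """Minimize ``objective`` over the box with the firefly swarm.

    Elitist bookkeeping: the best position/value ever evaluated is
    tracked outside the swarm, so the per-iteration best trace is
    monotone non-increasing.  Non-finite objective values are penalized
    with +inf and the run continues.

    Returns ``{"best_position", "best_value", "trace"}`` where trace is a
    list of (iteration, best_value, best_position) records.
    """
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])

    def safe(x):
        v = objective(np.asarray(x, dtype=np.float64))
        return float(v) if np.isfinite(v) else np.inf

    swarm = []
    for _ in range(config.population):
        x = rng.uniform(lo, hi)
        swarm.append(Firefly(position=x, brightness=safe(x)))

    best = min(swarm, key=lambda f: f.brightness)
    best_pos, best_val = best.position.copy(), best.brightness
    trace = [{"iteration": 0, "best_value": best_val,
              "best_position": best_pos.tolist()}]
    gamma_rand = config.gamma_rand
    for it in range(1, config.iterations + 1):
        firefly_step(swarm, config, rng, safe, gamma_rand=gamma_rand)
        gamma_rand *= config.rand_decay
        cand = min(swarm, key=lambda f: f.brightness)
        if cand.brightness < best_val:
            best_val = cand.brightness
            best_pos = cand.position.copy()
        trace.append({"iteration": it, "best_value": best_val,
                      "best_position": best_pos.tolist()})
    return {"best_position": best_pos, "best_value": best_val, "trace": trace}
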