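"""Cognitive search: Bayesian source localization with entropy-greedy actions.

The agent maintains a posterior ("belief") over source locations on a
rectangular lattice of candidate cells.  After each move it observes a
Poisson detection count ``k`` during the dwell time ``dt`` and multiplies
every cell's weight by the likelihood ``Pois(k; R(pos|cell) dt)`` where
``R(pos|cell)`` is the plume model rate at the agent position for a source
hypothesized in that cell.  The cell the agent currently occupies is zeroed
(the source was evidently not there) and the belief is renormalized.

Actions are one lattice step forward (upwind, +y), backward, left, right, or
stay.  The agent picks the action maximizing the expected reduction of the
Shannon entropy S of the belief,

    gain(a) = P_found * S  +  (1 - P_found) * sum_k rho_k (S - S|k)

where ``P_found`` is the belief mass at the landing cell, ``rho_k`` the
predictive probability of observing ``k`` detections there (a mixture over
the belief of Poisson distributions, truncated to k in {0, 1} by default with
``rho_1 = 1 - rho_0``), and ``S|k`` the entropy of the correspondingly
updated belief.  Ties are broken uniformly at random with the trial's seeded
generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .plume import PlumeParams, correlation_length

__all__ = [
    "ACTIONS",
    "ACTION_STEPS",
    "Belief",
    "InfotaxisConfig",
    "detection_rate_from_sources",
    "update_belief",
    "entropy",
    "expected_entropy_gain",
    "choose_action",
]

#: The five admissible actions.  Forward is upwind (+y); left is -x when
#: facing upwind.
ACTIONS: tuple[str, ...] = ("forward", "backward", "left", "right", "stay")

#: Lattice displacement (dx, dy) of each action, in grid steps.
ACTION_STEPS: dict[str, tuple[int, int]] = {
    "forward": (0, 1),
    "backward": (0, -1),
    "left": (-1, 0),
    "right": (1, 0),
    "stay": (0, 0),
}


@dataclass(frozen=True)
class InfotaxisConfig:
    """Tunable parameters of the discrete infotaxis agent.

    ``step_length`` is the lattice spacing (m); the dwell time of a moving
    action is ``step_length / speed + wait`` and of a stay ``stay_wait``.
    ``max_steps`` is the hard episode cap (timeout failure).  ``k_max``
    truncates the detection-count expectation in the gain; the default 1 is
    the standard infotaxis choice (R dt is small), larger values evaluate the
    full mixture with the remaining tail mass assigned to ``k_max``.

    ``model_plume`` holds the parameters of the agent's *likelihood* model.
    They are deliberately distinct from the environment plume: the searcher
    only assumes an encounter-rate field, and a broad model correlation
    length (here ~0.57 m) is what makes silence informative — exactly as in
    the robotic assay, where the likelihood parameters were calibrated
    to reproduce the measured detection rates rather than taken from the
    physical plume.  The model emission rate is scaled with the dose at run
    time.
    """

    step_length: float = 0.10
    speed: float = 0.04
    wait: float = 1.0
    stay_wait: float = 3.0
    max_steps: int = 125
    k_max: int = 1
    model_plume: PlumeParams = field(default_factory=lambda: PlumeParams(
        emission_rate=0.2, patch_lifetime=400.0, diffusivity=0.25,
        wind_speed=0.88, agent_size=0.1))

    def action_dt(self, action: str) -> float:
        if action == "stay":
            return self.stay_wait
        return self.step_length / self.speed + self.wait


class Belief:
    """Normalized posterior over source-location grid cells.

    ``xs`` and ``ys`` are the cell-center coordinates (1D, uniform spacing),
    ``prob`` the (ny, nx) weight array summing to one.
    """

    __slots__ = ("xs", "ys", "prob")

    def __init__(self, xs: np.ndarray, ys: np.ndarray, prob: np.ndarray):
        self.xs = np.asarray(xs, dtype=float)
        self.ys = np.asarray(ys, dtype=float)
        prob = np.asarray(prob, dtype=float)
        if prob.shape != (len(self.ys), len(self.xs)):
            raise ValueError("prob must have shape (len(ys), len(xs))")
        if np.any(prob < 0):
            raise ValueError("belief weights must be non-negative")
        total = prob.sum()
        if not math.isfinite(total) or total <= 0:
            raise ValueError("belief weights must have positive finite sum")
        self.prob = prob / total

    @property
    def spacing(self) -> float:
        return float(self.xs[1] - self.xs[0]) if len(self.xs) > 1 else float(
            self.ys[1] - self.ys[0]
        )

    @classmethod
    def uniform(cls, xs, ys, exclude=None) -> "Belief":
        """Uniform prior, optionally excluding the cell containing a point
        (typically the start: the agent knows the source is not underfoot)."""
        xs = np.asarray(xs, dtype=float)
        ys = np.asarray(ys, dtype=float)
        prob = np.ones((len(ys), len(xs)))
        b = cls(xs, ys, prob)
        if exclude is not None:
            iy, ix = b.cell_index(exclude)
            prob = b.prob.copy()
            prob[iy, ix] = 0.0
            b = cls(xs, ys, prob)
        return b

    def cell_index(self, pos) -> tuple[int, int]:
        """Indices (iy, ix) of the cell whose center is nearest ``pos``."""
        x, y = float(pos[0]), float(pos[1])
        h = self.spacing
        ix = int(round((x - self.xs[0]) / h))
        iy = int(round((y - self.ys[0]) / h))
        if not (0 <= ix < len(self.xs) and 0 <= iy < len(self.ys)):
            raise IndexError(f"position {(x, y)} outside the belief grid")
        return iy, ix

    def copy(self) -> "Belief":
        return Belief(self.xs, self.ys, self.prob.copy())


def detection_rate_from_sources(pos, belief: Belief, params: PlumeParams) -> np.ndarray:
    """R(pos | cell) for every grid cell: the plume-model rate the agent at
    ``pos`` would experience if the source sat at that cell.  Shape (ny, nx)."""
    x, y = float(pos[0]), float(pos[1])
    dx = x - belief.xs[None, :]
    dy = y - belief.ys[:, None]
    lam = correlation_length(params)
    dist = np.hypot(dx, dy)
    np.maximum(dist, params.agent_size, out=dist)
    from scipy.special import k0e as _k0e

    # same overflow-safe factorization as plume.mean_detection_rate
    prefactor = params.emission_rate / math.log(lam / params.agent_size)
    exponent = -(dist / lam + dy * params.wind_speed / (2.0 * params.diffusivity))
    return prefactor * _k0e(dist / lam) * np.exp(exponent)


def _poisson_pmf(k: int, mu: np.ndarray) -> np.ndarray:
    if k == 0:
        return np.exp(-mu)
    return np.exp(k * np.log(np.maximum(mu, 1e-300)) - mu - gammaln(k + 1))


def update_belief(belief: Belief, pos, dt: float, k: int,
                  params: PlumeParams, rates: np.ndarray | None = None) -> Belief:
    """Posterior update after observing ``k`` detections during ``dt`` at ``pos``.

    Each cell weight is multiplied by ``Pois(k; R(pos|cell) dt)``; the cell
    containing ``pos`` is zeroed (source not found there) and the result is
    renormalized.  ``rates`` may supply a precomputed ``R(pos|cell)`` array.

    Raises
    ------
    ValueError
        If the posterior collapses to all-zero mass (inconsistent history),
        or for invalid ``dt`` / ``k``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if k < 0:
        raise ValueError("detection count must be non-negative")
    if rates is None:
        rates = detection_rate_from_sources(pos, belief, params)
    mu = rates * dt
    weights = belief.prob * _poisson_pmf(k, mu)
    try:
        iy, ix = belief.cell_index(pos)
        weights[iy, ix] = 0.0  # source was evidently not underfoot
    except IndexError:
        pass  # observer outside the candidate grid: nothing to zero
    total = weights.sum()
    if not total > 0:
        raise ValueError(
            "belief update produced an all-zero posterior (inconsistent history)"
        )
    return Belief(belief.xs, belief.ys, weights)


def entropy(belief: Belief) -> float:
    """Shannon entropy of the belief in bits, with 0 log 0 := 0."""
    p = belief.prob[belief.prob > 0]
    return float(-(p * np.log2(p)).sum())


def expected_entropy_gain(belief: Belief, action: str, pos, dt: float,
                          params: PlumeParams,
                          config: InfotaxisConfig | None = None) -> float:
    """Expected entropy reduction of taking ``action`` from ``pos``.

    The landing cell must lie inside the grid (the caller filters admissible
    actions).  The detection-count expectation is truncated at
    ``config.k_max`` (default 1), the final branch receiving the tail mass.
    """
    if config is None:
        config = InfotaxisConfig()
    step = ACTION_STEPS[action]
    h = belief.spacing
    landing = (float(pos[0]) + step[0] * h, float(pos[1]) + step[1] * h)
    iy, ix = belief.cell_index(landing)  # raises if outside grid

    s0 = entropy(belief)
    p_found = float(belief.prob[iy, ix])

    rates = detection_rate_from_sources(landing, belief, params)
    mu = rates * dt

    gain_not_found = 0.0
    mass_left = 1.0
    for k in range(config.k_max + 1):
        if k < config.k_max:
            rho_k = float((belief.prob * _poisson_pmf(k, mu)).sum())
        else:
            rho_k = mass_left  # truncation: tail mass on the last branch
        rho_k = max(rho_k, 0.0)
        mass_left -= rho_k
        if rho_k == 0.0:
            continue
        try:
            s_k = entropy(update_belief(belief, landing, dt, k, params, rates=rates))
        except ValueError:
            # all mass at the landing cell for this branch: zero entropy left
            s_k = 0.0
        gain_not_found += rho_k * (s0 - s_k)
    return p_found * s0 + (1.0 - p_found) * gain_not_found


def admissible_actions(belief: Belief, pos) -> list[str]:
    """Actions whose landing cell lies inside the grid ('stay' always does)."""
    out = []
    h = belief.spacing
    for action in ACTIONS:
        step = ACTION_STEPS[action]
        landing = (float(pos[0]) + step[0] * h, float(pos[1]) + step[1] * h)
        try:
            belief.cell_index(landing)
        except IndexError:
            continue
        out.append(action)
    return out


def choose_action(belief: Belief, pos, params: PlumeParams,
                  rng: np.random.Generator,
                  config: InfotaxisConfig | None = None,
                  tie_tol: float = 1e-12) -> str:
    """Argmax of :func:`expected_entropy_gain` over admissible actions.

    Ties (gains within ``tie_tol`` of the maximum) are broken uniformly at
    random; exactly one draw is consumed from ``rng`` per call so that runs
    are reproducible action-for-action given the seed.
    """
    if config is None:
        config = InfotaxisConfig()
    actions = admissible_actions(belief, pos)
    if not actions:
        raise ValueError("no admissible action from this position")
    gains = np.array([
        expected_entropy_gain(belief, a, pos, config.action_dt(a), params, config)
        for a in actions
    ])
    best = gains.max()
    candidates = [a for a, g in zip(actions, gains) if best - g <= tie_tol]
    return candidates[int(rng.integers(len(candidates)))]
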