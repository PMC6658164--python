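"""The six-variant Q-learning model family.

The base model updates the chosen action's value toward the trial outcome,

    Q_a(t+1) = (1 - alpha) * Q_a(t) + alpha * R(t),        (chosen action)
    Q_a(t+1) = Q_a(t),                                     (unchosen action)

and selects actions with a softmax of the value difference,

    P_L(t) = 1 / (1 + exp(-beta * (Q_L(t) - Q_R(t)) + b)).

Variants split the learning rate by outcome (alpha_pos on rewarded trials,
alpha_neg on unrewarded trials), add a side-bias term b, subtract per-outcome
penalty terms gamma_win / gamma_lose from the chosen action's value (these
parameterize win-stay / lose-switch tendencies), or add uncertainty-driven
exploration (epsilon, rho).

Sign convention: b enters the softmax with a plus sign inside the exponent,
so *positive* b lowers P_L.  The :attr:`ParamSet.left_bias` accessor reports
the left-favoring bias as ``-b`` for readability.

Model registry (free parameters; all others pinned):

====== ==========================================================
 1     alpha (tied pos/neg), beta
 2     alpha, beta, bias
 3     alpha_pos, alpha_neg, beta, bias
 4     alpha, beta, bias, gamma_win, gamma_lose
 5     alpha_pos, alpha_neg, beta, bias, gamma_win, gamma_lose
 6     model 5 + epsilon, rho (uncertainty exploration)
====== ==========================================================

Uncertainty exploration (model 6): each action carries an accumulator U that
grows by epsilon per trial the action goes unchosen and resets to zero when
chosen; the softmax argument gains rho * (U_L - U_R).  This is one concrete
member of the family of uncertainty-bonus exploration rules; the model-variant
interface allows substituting another.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._kernels import replay
from .core_io import Session

__all__ = [
    "ParamSet",
    "ModelSpec",
    "ActionValues",
    "ValueTrajectory",
    "MODELS",
    "ConstraintError",
    "update_values",
    "choice_prob_left",
    "session_loglik",
    "value_trajectory",
]

PARAM_NAMES = (
    "alpha_pos",
    "alpha_neg",
    "beta",
    "bias",
    "gamma_win",
    "gamma_lose",
    "epsilon",
    "rho",
)

#: floor applied to choice probabilities before taking logs, so deterministic-
#: looking fits yield finite (and bit-reproducible) log-likelihoods
P_FLOOR = 1e-12


class ConstraintError(ValueError):
    """ParamSet violates a bound or a model's equality/zero constraint."""


@dataclass(frozen=True)
class ParamSet:
    """Full 8-parameter vector; models pin subsets of it.

    alpha_pos / alpha_neg in [0, 1]; beta >= 0; epsilon >= 0; bias, gamma
    and rho unrestricted in sign.
    """

    alpha_pos: float = 0.5
    alpha_neg: float = 0.5
    beta: float = 1.0
    bias: float = 0.0
    gamma_win: float = 0.0
    gamma_lose: float = 0.0
    epsilon: float = 0.0
    rho: float = 0.0

    @classmethod
    def create(cls, alpha: float | None = None, **kwargs) -> "ParamSet":
        """Convenience constructor; ``alpha=`` sets both learning rates."""
        if alpha is not None:
            kwargs.setdefault("alpha_pos", alpha)
            kwargs.setdefault("alpha_neg", alpha)
        return cls(**kwargs)

    @property
    def left_bias(self) -> float:
        """Bias toward the left target on the probability scale (= -b)."""
        return -self.bias

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}

    def check_bounds(self) -> None:
        if not (0.0 <= self.alpha_pos <= 1.0 and 0.0 <= self.alpha_neg <= 1.0):
            raise ConstraintError("learning rates must lie in [0, 1]")
        if self.beta < 0:
            raise ConstraintError("beta must be >= 0")
        if self.epsilon < 0:
            raise ConstraintError("epsilon must be >= 0")
        for n in PARAM_NAMES:
            if not np.isfinite(getattr(self, n)):
                raise ConstraintError(f"{n} is not finite")


@dataclass(frozen=True)
class ModelSpec:
    """A model variant: which entries of the 8-vector are free.

    ``"alpha"`` in ``free`` means a single tied learning rate
    (alpha_pos = alpha_neg).  Pinned parameters are zero except through
    the tie.
    """

    model_id: int
    free: tuple[str, ...]

    @property
    def n_params(self) -> int:
        return len(self.free)

    def validate_params(self, params: ParamSet) -> None:
        params.check_bounds()
        if "alpha" in self.free and params.alpha_pos != params.alpha_neg:
            raise ConstraintError(
                f"model {self.model_id} ties alpha_pos = alpha_neg"
            )
        fixed_zero = []
        expanded = self.expanded_free()
        for n in PARAM_NAMES:
            if n not in expanded and getattr(params, n) != 0.0:
                fixed_zero.append(n)
        # beta is free in every model; alpha always free (possibly tied)
        if fixed_zero:
            raise ConstraintError(
                f"model {self.model_id} pins {', '.join(fixed_zero)} at 0"
            )

    def expanded_free(self) -> tuple[str, ...]:
        """Free names on the 8-parameter space (``alpha`` -> both rates)."""
        out: list[str] = []
        for n in self.free:
            if n == "alpha":
                out.extend(["alpha_pos", "alpha_neg"])
            else:
                out.append(n)
        return tuple(out)

    def paramset_from_vector(self, x: Sequence[float]) -> ParamSet:
        if len(x) != self.n_params:
            raise ConstraintError(
                f"model {self.model_id} takes {self.n_params} parameters"
            )
        kwargs: dict[str, float] = {n: 0.0 for n in PARAM_NAMES}
        for name, v in zip(self.free, x):
            if name == "alpha":
                kwargs["alpha_pos"] = kwargs["alpha_neg"] = float(v)
            else:
                kwargs[name] = float(v)
        return ParamSet(**kwargs)

    def vector_from_paramset(self, params: ParamSet) -> np.ndarray:
        out = []
        for name in self.free:
            out.append(params.alpha_pos if name == "alpha" else getattr(params, name))
        return np.asarray(out, dtype=float)


MODELS: dict[int, ModelSpec] = {
    1: ModelSpec(1, ("alpha", "beta")),
    2: ModelSpec(2, ("alpha", "beta", "bias")),
    3: ModelSpec(3, ("alpha_pos", "alpha_neg", "beta", "bias")),
    4: ModelSpec(4, ("alpha", "beta", "bias", "gamma_win", "gamma_lose")),
    5: ModelSpec(5, ("alpha_pos", "alpha_neg", "beta", "bias", "gamma_win", "gamma_lose")),
    6: ModelSpec(
        6,
        (
            "alpha_pos",
            "alpha_neg",
            "beta",
            "bias",
            "gamma_win",
            "gamma_lose",
            "epsilon",
            "rho",
        ),
    ),
}


@dataclass(frozen=True)
class ActionValues:
    """Action values (and uncertainty accumulators) carried across trials."""

    q_left: float = 0.0
    q_right: float = 0.0
    u_left: float = 0.0
    u_right: float = 0.0


def update_values(
    q: ActionValues,
    choice: str,
    reward: int,
    params: ParamSet,
    model: ModelSpec | None = None,
) -> ActionValues:
    """One value-update step: chosen action moves toward the outcome.

    On rewarded trials the chosen value becomes
    ``(1 - alpha_pos) * Q + alpha_pos * R - gamma_win``; on unrewarded trials
    alpha_neg / gamma_lose apply.  The unchosen action's value is unchanged.
    The chosen action's uncertainty resets to 0; the unchosen one grows by
    epsilon.
    """
    if reward == 1:
        a, g = params.alpha_pos, params.gamma_win
    else:
        a, g = params.alpha_neg, params.gamma_lose
    r = float(reward)
    if choice == "L":
        return ActionValues(
            q_left=(1.0 - a) * q.q_left + a * r - g,
            q_right=q.q_right,
            u_left=0.0,
            u_right=q.u_right + params.epsilon,
        )
    return ActionValues(
        q_left=q.q_left,
        q_right=(1.0 - a) * q.q_right + a * r - g,
        u_left=q.u_left + params.epsilon,
        u_right=0.0,
    )


def choice_prob_left(
    q: ActionValues, params: ParamSet, model: ModelSpec | None = None
) -> float:
    """Softmax probability of choosing left; saturates instead of overflowing."""
    arg = (
        params.beta * (q.q_left - q.q_right)
        - params.bias
        + params.rho * (q.u_left - q.u_right)
    )
    if arg >= 0:
        return 1.0 / (1.0 + np.exp(-arg))
    e = np.exp(arg)
    return float(e / (1.0 + e))


@dataclass
class ValueTrajectory:
    """Per-trial pre-choice values and choice probabilities on a session.

    ``q_high``/``q_low`` are the values of the currently higher-/lower-
    reward-probability side (via the session's ``high_side`` labels).
    """

    q_left: np.ndarray
    q_right: np.ndarray
    p_left: np.ndarray
    q_high: np.ndarray
    q_low: np.ndarray


def _pack(sessions: Sequence[Session]):
    """Concatenate sessions into flat arrays with session-start markers."""
    is_left = np.concatenate([s.arrays()["is_left"] for s in sessions])
    reward = np.concatenate([s.arrays()["reward"] for s in sessions])
    starts = np.zeros(is_left.shape[0], dtype=np.uint8)
    pos = 0
    for s in sessions:
        starts[pos] = 1
        pos += s.n_trials
    return is_left, reward, starts


def _replay_arrays(is_left, reward, starts, params: ParamSet, q_init):
    return replay(
        is_left,
        reward,
        starts,
        params.alpha_pos,
        params.alpha_neg,
        params.beta,
        params.bias,
        params.gamma_win,
        params.gamma_lose,
        params.epsilon,
        params.rho,
        float(q_init[0]),
        float(q_init[1]),
    )


def loglik_from_arrays(is_left, reward, starts, params: ParamSet, q_init=(0.0, 0.0)):
    """Log-likelihood on pre-packed arrays (hot path used by the fitter)."""
    _, _, p_left = _replay_arrays(is_left, reward, starts, params, q_init)
    p_choice = np.where(is_left == 1, p_left, 1.0 - p_left)
    return float(np.sum(np.log(np.clip(p_choice, P_FLOOR, 1.0))))


def session_loglik(
    sessions: Sequence[Session] | Session,
    params: ParamSet,
    model: ModelSpec | None = None,
    q_init: tuple[float, float] = (0.0, 0.0),
) -> float:
    """Pooled log-likelihood of observed choices across sessions.

    Values are re-initialized at each session start, so the pooled
    log-likelihood is the sum of per-session log-likelihoods.  Probabilities
    are floored at ``P_FLOOR`` before the log.
    """
    if isinstance(sessions, Session):
        sessions = [sessions]
    if len(sessions) == 0:
        raise ValueError("session_loglik requires at least one session")
    if model is not None:
        model.validate_params(params)
    else:
        params.check_bounds()
    return loglik_from_arrays(*_pack(sessions), params, q_init)


def value_trajectory(
    session: Session,
    params: ParamSet,
    model: ModelSpec | None = None,
    q_init: tuple[float, float] = (0.0, 0.0),
) -> ValueTrajectory:
    """Replay a session's observed choices/rewards to get per-trial values."""
    if model is not None:
        model.validate_params(params)
    arr = session.arrays()
    starts = np.zeros(session.n_trials, dtype=np.uint8)
    starts[0] = 1
    ql, qr, pl = _replay_arrays(arr["is_left"], arr["reward"], starts, params, q_init)
    high_left = arr["high_is_left"].astype(bool)
    q_high = np.where(high_left, ql, qr)
    q_low = np.where(high_left, qr, ql)
    return ValueTrajectory(q_left=ql, q_right=qr, p_left=pl, q_high=q_high, q_low=q_low)
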