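"""Trial-by-trial learning and choice.

The model keeps one action value Q[k, i] per (attribute k, option i).
After each choice the chosen option's values move toward the subjective
reward r = N * x^gamma on every attribute, while every unchosen option's
values decay toward zero with the memory-dependent learning rate
alpha_u = alpha_c * Q^(mu - 1): strong memories decay fast, weak ones
barely move (a soft bound).  Choice is a softmax over the
attention-weighted overall values Q_i = sum_k w_k * Q[k, i].

Two engines run the trial loop: a numba kernel (fast path, used by the
fitting code) and a pure-Python reference with the identical operation
order (the oracle the tests compare against).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .attribute_space import AttentionWeights
from .exceptions import InvalidConfigError, InvalidInputError
from .sequence_metrics import ChoiceSequence

__all__ = [
    "ModelParams",
    "QTable",
    "Design",
    "SimulationResult",
    "subjective_reward",
    "unchosen_learning_rate",
    "update_q",
    "overall_values",
    "choice_probabilities",
    "simulate",
]

#: probability floor applied before the log in likelihood replay
LIKELIHOOD_FLOOR = 1e-12


@dataclass(frozen=True)
class ModelParams:
    """Model parameters and fixed numeric configuration.

    Free (fitted) parameters
    ------------------------
    alpha_c : learning rate of the chosen option, in [0, 1].
    mu : exponent of the memory-dependent unchosen learning rate
        alpha_u = alpha_c * Q^(mu - 1); mu = 1 recovers a constant decay
        rate, mu > 1 makes strong values decay faster.
    beta : softmax inverse temperature, >= 0.
    gamma : value-sensitivity exponent of the subjective reward
        r = N * x^gamma, > 0.

    Fixed configuration
    -------------------
    theta_threshold_deg : attention threshold angle, in (0, 90).
    q_init : "informed" (initial values equal the subjective rewards of
        the visible options; the default) or a nonnegative number.
    reward_norm : the normalizing constant N (> 0), the reward ceiling on
        the unit attribute scale.  Shared by generator and fitter; it is
        not absorbed by beta when mu != 1.  The default 0.28 is
        calibrated once so that, under the representative fitted
        parameter sets, simulated sequences show the reported bursty
        run structure and bias range (see docs/methods.md).
    q_floor : floor inside the power Q^(mu-1) (guards mu < 1 at Q -> 0).
    session_reset : reset Q to its initial table at session boundaries
        (default False: values carry over).
    """

    alpha_c: float
    mu: float
    beta: float
    gamma: float
    theta_threshold_deg: float = 30.0
    q_init: float | str = "informed"
    reward_norm: float = 0.28
    q_floor: float = 1e-8
    session_reset: bool = False

    def __post_init__(self):
        if not 0.0 <= self.alpha_c <= 1.0:
            raise InvalidConfigError(f"alpha_c must be in [0, 1]; got {self.alpha_c}")
        if self.mu <= 0 or self.gamma <= 0 or self.reward_norm <= 0:
            raise InvalidConfigError("mu, gamma and reward_norm must be positive")
        if self.beta < 0:
            raise InvalidConfigError(f"beta must be nonnegative; got {self.beta}")
        if isinstance(self.q_init, str) and self.q_init != "informed":
            raise InvalidConfigError("q_init must be 'informed' or a number")
        if not isinstance(self.q_init, str) and self.q_init < 0:
            raise InvalidConfigError("numeric q_init must be nonnegative")

    def replace(self, **kw) -> "ModelParams":
        return dataclasses.replace(self, **kw)

    def initial_q(self, x0: np.ndarray) -> np.ndarray:
        """Initial Q table for normalized first-session values ``x0``."""
        x0 = np.asarray(x0, float)
        if self.q_init == "informed":
            return subjective_reward(x0, self.gamma, self.reward_norm)
        return np.full_like(x0, float(self.q_init))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)


@dataclass(frozen=True)
class QTable:
    """Action values Q[k, i], one per (attribute k, option i)."""

    attributes: tuple
    options: tuple
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.shape != (len(self.attributes), len(self.options)):
            raise InvalidInputError("QTable values shape mismatch")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "attributes", tuple(self.attributes))
        object.__setattr__(self, "options", tuple(self.options))


def subjective_reward(x, gamma: float, n_const: float = 1.0):
    """Power-law subjective reward r = N * x^gamma of a normalized value."""
    x = np.asarray(x, float)
    if np.any(x <= 0):
        raise InvalidInputError("attribute value must be positive")
    if gamma <= 0 or n_const <= 0:
        raise InvalidInputError("gamma and n_const must be positive")
    out = n_const * x**gamma
    return float(out) if out.ndim == 0 else out


def unchosen_learning_rate(
    q: float, alpha_c: float, mu: float, q_floor: float = 1e-8
) -> float:
    """Memory-dependent decay rate alpha_u = alpha_c * Q^(mu-1), in [0, 1].

    mu = 1 returns alpha_c exactly for any value.  A zero value with
    mu > 1 returns 0 (an empty memory does not decay); the floor guards
    the diverging power only when mu < 1.
    """
    if mu == 1.0:
        return float(alpha_c)
    if q <= 0.0 and mu > 1.0:
        return 0.0
    return float(min(1.0, max(0.0, alpha_c * max(q, q_floor) ** (mu - 1.0))))


def update_q(
    q: QTable, chosen, rewards, params: ModelParams, update_unchosen: bool = True
) -> QTable:
    """One learning step; returns a new table (the input is unmodified).

    ``rewards`` maps every attribute to the chosen option's subjective
    reward on it (dict or array in attribute order).  The chosen option
    moves toward its reward, each unchosen option decays toward zero at
    its own memory-dependent rate, and all values are clamped at 0.
    """
    if chosen not in q.options:
        raise InvalidInputError(f"chosen option {chosen!r} not in option set")
    c = q.options.index(chosen)
    if isinstance(rewards, dict):
        missing = [a for a in q.attributes if a not in rewards]
        if missing:
            raise InvalidInputError(f"reward missing for attribute(s) {missing}")
        r = np.array([rewards[a] for a in q.attributes], float)
    else:
        r = np.asarray(rewards, float)
        if r.shape != (len(q.attributes),):
            raise InvalidInputError("rewards must cover every attribute")
    v = q.values.copy()
    v[:, c] += params.alpha_c * (r - v[:, c])
    if update_unchosen:
        for k in range(v.shape[0]):
            for i in range(v.shape[1]):
                if i == c:
                    continue
                au = unchosen_learning_rate(
                    v[k, i], params.alpha_c, params.mu, params.q_floor
                )
                v[k, i] += au * (0.0 - v[k, i])
    np.clip(v, 0.0, None, out=v)
    return QTable(q.attributes, q.options, v)


def overall_values(q: QTable, w) -> np.ndarray:
    """Attention-weighted overall value Q_i = sum_k w_k * Q[k, i]."""
    if isinstance(w, AttentionWeights):
        if tuple(w.attributes) != tuple(q.attributes):
            raise InvalidInputError("attention weights / Q table attribute mismatch")
        w = w.weights
    w = np.asarray(w, float)
    if w.shape != (len(q.attributes),):
        raise InvalidInputError("weights must cover every attribute")
    return w @ q.values


def choice_probabilities(values, beta: float) -> np.ndarray:
    """Softmax choice probabilities with max-subtraction for stability."""
    if beta < 0:
        raise InvalidInputError("beta must be nonnegative")
    v = np.asarray(values, float)
    if not np.all(np.isfinite(v)):
        raise InvalidInputError("values must be finite")
    e = np.exp(beta * (v - v.max()))
    return e / e.sum()


@dataclass(frozen=True)
class Design:
    """Per-session arrays a simulation or likelihood replay runs on.

    ``x`` holds normalized attribute values with shape
    (n_sessions, n_attributes, n_options); ``weights`` the per-session
    attention weights (n_sessions, n_attributes); ``session_of_trial``
    maps each trial to its session.
    """

    options: tuple
    attributes: tuple
    x: np.ndarray
    weights: np.ndarray
    session_of_trial: np.ndarray

    def __post_init__(self):
        x = np.ascontiguousarray(self.x, dtype=float)
        w = np.ascontiguousarray(self.weights, dtype=float)
        s = np.ascontiguousarray(self.session_of_trial, dtype=np.int64)
        if x.ndim != 3 or w.ndim != 2 or x.shape[:2] != w.shape:
            raise InvalidInputError("x and weights disagree on sessions/attributes")
        if s.max() >= x.shape[0] or s.min() < 0:
            raise InvalidInputError("session_of_trial indexes a missing session")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "session_of_trial", s)

    @property
    def n_trials(self) -> int:
        return int(self.session_of_trial.size)

    @property
    def session_breaks(self) -> tuple:
        s = self.session_of_trial
        return tuple(np.flatnonzero(s[1:] != s[:-1]) + 1)


def _as_design(spec, n_trials=None) -> Design:
    if isinstance(spec, Design):
        return spec
    if hasattr(spec, "design"):
        return spec.design(n_trials)
    raise InvalidInputError("expected a ConditionSpec or Design")


@dataclass(frozen=True)
class SimulationResult:
    """Full per-trial trace of one simulated subject."""

    design: Design
    params: ModelParams
    seed: int
    choices: np.ndarray
    probabilities: np.ndarray
    values: np.ndarray
    prediction_errors: np.ndarray
    engine: str

    @property
    def sequence(self) -> ChoiceSequence:
        labels = np.asarray(self.design.options)[self.choices]
        return ChoiceSequence(labels, self.design.session_breaks)


def _replay_py(choices, s_idx, x, w, q0, par, update_unchosen, p_floor):
    """Reference replay: same operation order as the numba kernel."""
    alpha_c, mu, beta, gamma, n_const, q_floor = (
        par.alpha_c, par.mu, par.beta, par.gamma, par.reward_norm, par.q_floor,
    )
    n_attr, n_opt = q0.shape
    Q = q0.copy()
    probs = np.empty((choices.size, n_opt))
    nll = 0.0
    v = np.empty(n_opt)
    for t in range(choices.size):
        s = s_idx[t]
        if par.session_reset and t > 0 and s != s_idx[t - 1]:
            Q = q0.copy()
        for i in range(n_opt):
            acc = 0.0
            for k in range(n_attr):
                acc += w[s, k] * Q[k, i]
            v[i] = acc
        vmax = v[0]
        for i in range(1, n_opt):
            if v[i] > vmax:
                vmax = v[i]
        z = 0.0
        for i in range(n_opt):
            v[i] = np.exp(beta * (v[i] - vmax))
            z += v[i]
        for i in range(n_opt):
            probs[t, i] = v[i] / z
        c = choices[t]
        nll -= np.log(max(probs[t, c], p_floor))
        for k in range(n_attr):
            r = n_const * x[s, k, c] ** gamma
            Q[k, c] = Q[k, c] + alpha_c * (r - Q[k, c])
            if Q[k, c] < 0.0:
                Q[k, c] = 0.0
            if update_unchosen:
                for i in range(n_opt):
                    if i == c:
                        continue
                    q = Q[k, i]
                    qf = q if q > q_floor else q_floor
                    au = min(1.0, max(0.0, alpha_c * qf ** (mu - 1.0)))
                    q = q + au * (0.0 - q)
                    Q[k, i] = q if q > 0.0 else 0.0
    return nll, probs


def replay(
    seq_choices: np.ndarray,
    design: Design,
    params: ModelParams,
    update_unchosen: bool = True,
    engine: str = "numba",
    p_floor: float = LIKELIHOOD_FLOOR,
):
    """Deterministic likelihood replay of an observed choice-index sequence.

    Returns ``(nll, probs)`` where ``probs[t]`` are the model's choice
    probabilities before observing trial t's choice.
    """
    choices = np.ascontiguousarray(seq_choices, dtype=np.int64)
    q0 = params.initial_q(design.x[0])
    if engine == "numba":
        probs = np.empty((choices.size, len(design.options)))
        nll = _kernels.replay_kernel(
            choices, design.session_of_trial, design.x, design.weights, q0,
            params.alpha_c, params.mu, params.beta, params.gamma,
            params.reward_norm, params.q_floor, p_floor,
            update_unchosen, params.session_reset, probs,
        )
        return float(nll), probs
    if engine == "reference":
        return _replay_py(
            choices, design.session_of_trial, design.x, design.weights, q0,
            params, update_unchosen, p_floor,
        )
    raise InvalidConfigError(f"unknown engine {engine!r}")


def _simulate_py(uniforms, s_idx, x, w, q0, par, update_unchosen):
    """Reference simulation mirroring the kernel's operation order."""
    alpha_c, mu, gamma, n_const, q_floor = (
        par.alpha_c, par.mu, par.gamma, par.reward_norm, par.q_floor,
    )
    beta = par.beta
    n_attr, n_opt = q0.shape
    T = uniforms.size
    Q = q0.copy()
    choices = np.empty(T, dtype=np.int64)
    probs = np.empty((T, n_opt))
    values = np.empty((T, n_opt))
    pe = np.empty((T, n_attr, n_opt))
    v = np.empty(n_opt)
    for t in range(T):
        s = s_idx[t]
        if par.session_reset and t > 0 and s != s_idx[t - 1]:
            Q = q0.copy()
        for i in range(n_opt):
            acc = 0.0
            for k in range(n_attr):
                acc += w[s, k] * Q[k, i]
            v[i] = acc
            values[t, i] = acc
        vmax = v[0]
        for i in range(1, n_opt):
            if v[i] > vmax:
                vmax = v[i]
        z = 0.0
        for i in range(n_opt):
            v[i] = np.exp(beta * (v[i] - vmax))
            z += v[i]
        for i in range(n_opt):
            v[i] = v[i] / z
        cum = 0.0
        c = n_opt - 1
        for i in range(n_opt):
            probs[t, i] = v[i]
            cum += v[i]
            if uniforms[t] < cum:
                c = i
                break
        for i in range(c + 1, n_opt):
            probs[t, i] = v[i]
        choices[t] = c
        for k in range(n_attr):
            r = n_const * x[s, k, c] ** gamma
            for i in range(n_opt):
                pe[t, k, i] = (r if i == c else 0.0) - Q[k, i]
            Q[k, c] = Q[k, c] + alpha_c * (r - Q[k, c])
            if Q[k, c] < 0.0:
                Q[k, c] = 0.0
            if update_unchosen:
                for i in range(n_opt):
                    if i == c:
                        continue
                    q = Q[k, i]
                    qf = q if q > q_floor else q_floor
                    au = min(1.0, max(0.0, alpha_c * qf ** (mu - 1.0)))
                    q = q + au * (0.0 - q)
                    Q[k, i] = q if q > 0.0 else 0.0
    return choices, probs, values, pe


def simulate(
    spec,
    params: ModelParams,
    n_trials: int | None = None,
    seed: int = 0,
    update_unchosen: bool = True,
    engine: str = "numba",
) -> SimulationResult:
    """Simulate a choice sequence trial by trial.

    ``spec`` is a ConditionSpec (anything with a ``design`` method) or a
    prepared :class:`Design`.  Each trial draws the choice from the
    softmax probabilities by inverse-CDF sampling with a seeded
    generator, then applies the learning update; attention weights are
    fixed per session.  The same seed reproduces the sequence exactly.
    """
    design = _as_design(spec, n_trials)
    if design.n_trials < 1:
        raise InvalidInputError("need at least one trial")
    q0 = params.initial_q(design.x[0])
    uniforms = np.random.default_rng(seed).random(design.n_trials)
    if engine == "numba":
        T, n_opt, n_attr = design.n_trials, len(design.options), len(design.attributes)
        choices = np.empty(T, dtype=np.int64)
        probs = np.empty((T, n_opt))
        values = np.empty((T, n_opt))
        pe = np.empty((T, n_attr, n_opt))
        _kernels.simulate_kernel(
            uniforms, design.session_of_trial, design.x, design.weights, q0,
            params.alpha_c, params.mu, params.beta, params.gamma,
            params.reward_norm, params.q_floor,
            update_unchosen, params.session_reset,
            choices, probs, values, pe,
        )
    elif engine == "reference":
        choices, probs, values, pe = _simulate_py(
            uniforms, design.session_of_trial, design.x, design.weights, q0,
            params, update_unchosen,
        )
    else:
        raise InvalidConfigError(f"unknown engine {engine!r}")
    return SimulationResult(design, params, seed, choices, probs, values, pe, engine)
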