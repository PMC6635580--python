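"""Scikit-learn style front end to the choice model.

`AttentionRLModel` wraps simulation, likelihood replay and maximum-
likelihood fitting behind the familiar estimator surface: constructor
parameters are the model's free parameters and fixed configuration,
``fit`` estimates the free parameters from a choice sequence, fitted
values land in trailing-underscore attributes, and ``sample`` runs the
generative model forward.  The estimator composes with
``sklearn.base.clone`` and ``get_params``/``set_params``; note that its
X is a :class:`~attnrl.sequence_metrics.ChoiceSequence` (or trial-log
DataFrame), not a feature matrix, so generic sklearn cross-validators
that split rows independently do not apply to this sequential model.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import model_fitting, rl_core
from .exceptions import InvalidInputError
from .rl_core import ModelParams
from .sequence_metrics import ChoiceSequence

__all__ = ["AttentionRLModel"]

_FREE = ("alpha_c", "mu", "beta", "gamma")
_CONFIG = ("theta_threshold_deg", "q_init", "reward_norm", "q_floor", "session_reset")


class AttentionRLModel(BaseEstimator):
    """Attention-gated multi-attribute reinforcement-learning choice model.

    Parameters
    ----------
    spec : ConditionSpec
        The choice context (options, attribute values, sessions).
    variant : "Q_c+u" or "Q_c"
        Whether unchosen options decay (4 free parameters) or only the
        chosen option learns (3).
    alpha_c, mu, beta, gamma : float
        Free parameters; used as the generative parameters by
        :meth:`sample` and replaced by estimates after :meth:`fit`.
    theta_threshold_deg, q_init, reward_norm, q_floor, session_reset
        Fixed configuration passed through to the model core.
    bounds : dict, optional
        Per-parameter (low, high) fitting bounds.
    n_restarts : int
        Latin-hypercube multi-start count for :meth:`fit`.
    random_state : int, optional
        Seed for restart placement; makes :meth:`fit` deterministic.

    Attributes
    ----------
    alpha_c_, mu_, beta_, gamma_ : fitted free parameters
    nll_, aic_, bic_, pseudo_r2_ : fit quality
    result_ : the full :class:`~attnrl.model_fitting.FitResult`
    """

    def __init__(
        self,
        spec=None,
        variant: str = "Q_c+u",
        alpha_c: float = 0.5,
        mu: float = 1.0,
        beta: float = 5.0,
        gamma: float = 1.0,
        theta_threshold_deg: float = 30.0,
        q_init="informed",
        reward_norm: float = 0.28,
        q_floor: float = 1e-8,
        session_reset: bool = False,
        bounds: dict | None = None,
        n_restarts: int = 10,
        random_state: int | None = None,
    ):
        self.spec = spec
        self.variant = variant
        self.alpha_c = alpha_c
        self.mu = mu
        self.beta = beta
        self.gamma = gamma
        self.theta_threshold_deg = theta_threshold_deg
        self.q_init = q_init
        self.reward_norm = reward_norm
        self.q_floor = q_floor
        self.session_reset = session_reset
        self.bounds = bounds
        self.n_restarts = n_restarts
        self.random_state = random_state

    # -- plumbing ----------------------------------------------------------
    def _model_params(self, fitted: bool = False) -> ModelParams:
        free = {
            p: getattr(self, p + "_" if fitted else p) for p in _FREE
        }
        if self.variant == "Q_c" and not fitted:
            free["mu"] = 1.0
        return ModelParams(**free, **{c: getattr(self, c) for c in _CONFIG})

    def _require_spec(self):
        if self.spec is None:
            raise InvalidInputError("this estimator needs a ConditionSpec (spec=...)")
        return self.spec

    @staticmethod
    def _as_sequence(X) -> ChoiceSequence:
        if isinstance(X, ChoiceSequence):
            return X
        from .task_library import sequence_from_log

        return sequence_from_log(X)

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y=None):
        """Maximum-likelihood fit of the free parameters to a sequence."""
        spec = self._require_spec()
        seq = self._as_sequence(X)
        result = model_fitting.fit(
            seq,
            spec,
            variant=self.variant,
            bounds=self.bounds,
            n_restarts=self.n_restarts,
            seed=self.random_state,
            base_params=self._model_params(),
        )
        for p in _FREE:
            setattr(self, p + "_", getattr(result.params, p))
        self.nll_ = result.nll
        self.aic_ = result.aic
        self.bic_ = result.bic
        self.pseudo_r2_ = result.pseudo_r2
        self.result_ = result
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-trial choice probabilities under the fitted parameters."""
        check_is_fitted(self, "result_")
        spec = self._require_spec()
        seq = self._as_sequence(X)
        design = spec.design(seq.n_trials)
        choices = model_fitting._encode(seq, spec)
        _, probs = rl_core.replay(
            choices, design, self._model_params(fitted=True),
            model_fitting._variant(self.variant).update_unchosen,
        )
        return probs

    def predict(self, X) -> np.ndarray:
        """Most probable option label at each trial."""
        probs = self.predict_proba(X)
        return np.asarray(self.spec.options)[probs.argmax(axis=1)]

    def score(self, X, y=None) -> float:
        """Mean per-trial log-likelihood (higher is better)."""
        spec = self._require_spec()
        seq = self._as_sequence(X)
        params = self._model_params(fitted=hasattr(self, "result_"))
        nll = model_fitting.negative_log_likelihood(seq, spec, params, self.variant)
        return -nll / seq.n_trials

    def sample(self, n_trials: int | None = None, random_state: int = 0):
        """Simulate a sequence from the current (unfitted) parameters."""
        spec = self._require_spec()
        return rl_core.simulate(
            spec,
            self._model_params(),
            n_trials=n_trials,
            seed=random_state,
            update_unchosen=model_fitting._variant(self.variant).update_unchosen,
        )
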