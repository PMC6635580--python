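"""Likelihood evaluation, bounded multi-start fitting, model comparison.

The likelihood of a choice sequence replays it deterministically: at
each trial the current softmax probabilities are evaluated at the
*observed* choice (floored at 1e-12 before the log), then the value
table is updated with that choice.  Two nested variants are compared:

* ``Q_c+u`` -- chosen updated, unchosen decayed (4 free parameters:
  alpha_c, mu, beta, gamma);
* ``Q_c``  -- chosen updated only (3 free parameters: alpha_c, beta,
  gamma; mu is inert without a decay process).

Fits minimize the negative log-likelihood with L-BFGS-B from seeded
Latin-hypercube start points.  Information criteria:
AIC = 2*NLL + 2k, BIC = 2*NLL + k*ln(n_trials), and the likelihood
pseudo-r^2 = 1 - NLL / (n_trials * ln(n_options)), i.e. improvement
over uniform random choice.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .exceptions import FitFailureError, InvalidInputError
from .rl_core import LIKELIHOOD_FLOOR, ModelParams, replay
from .sequence_metrics import ChoiceSequence

__all__ = [
    "VARIANTS",
    "ModelVariant",
    "FitResult",
    "ComparisonReport",
    "DEFAULT_BOUNDS",
    "negative_log_likelihood",
    "information_criteria",
    "fit",
    "compare_models",
]


@dataclass(frozen=True)
class ModelVariant:
    """A model variant: which options learn, and how many free parameters."""

    name: str
    free_params: tuple
    update_unchosen: bool

    @property
    def k_params(self) -> int:
        return len(self.free_params)


VARIANTS = {
    "Q_c+u": ModelVariant("Q_c+u", ("alpha_c", "mu", "beta", "gamma"), True),
    "Q_c": ModelVariant("Q_c", ("alpha_c", "beta", "gamma"), False),
}

DEFAULT_BOUNDS = {
    "alpha_c": (1e-3, 1.0),
    "mu": (0.1, 5.0),
    "beta": (0.0, 100.0),
    "gamma": (1e-3, 5.0),
}


def _variant(variant) -> ModelVariant:
    if isinstance(variant, ModelVariant):
        return variant
    if variant not in VARIANTS:
        raise InvalidInputError(f"unknown model variant {variant!r}")
    return VARIANTS[variant]


def _encode(seq: ChoiceSequence, spec) -> np.ndarray:
    lookup = {o: i for i, o in enumerate(spec.options)}
    try:
        return np.array([lookup[l] for l in seq.labels], dtype=np.int64)
    except KeyError as e:
        raise InvalidInputError(
            f"label {e.args[0]!r} is not in the spec's option set {spec.options}"
        ) from None


def negative_log_likelihood(
    seq: ChoiceSequence,
    spec,
    params: ModelParams,
    variant="Q_c+u",
    engine: str = "numba",
    p_floor: float = LIKELIHOOD_FLOOR,
) -> float:
    """Negative log-likelihood of *seq* under *params* (natural log)."""
    var = _variant(variant)
    design = spec.design(seq.n_trials)
    choices = _encode(seq, spec)
    nll, _ = replay(choices, design, params, var.update_unchosen, engine, p_floor)
    return nll


InformationCriteria = namedtuple("InformationCriteria", ["aic", "bic", "pseudo_r2"])


def information_criteria(
    nll: float, k_params: int, n_trials: int, n_options: int
) -> InformationCriteria:
    """AIC, BIC and likelihood pseudo-r^2 for a fitted sequence model."""
    if n_trials < 1:
        raise InvalidInputError("n_trials must be at least 1")
    aic = 2.0 * nll + 2.0 * k_params
    bic = 2.0 * nll + k_params * np.log(n_trials)
    pseudo_r2 = 1.0 - nll / (n_trials * np.log(n_options))
    return InformationCriteria(float(aic), float(bic), float(pseudo_r2))


@dataclass(frozen=True)
class FitResult:
    """Best optimum of a multi-start fit, with per-restart diagnostics."""

    params: ModelParams
    variant: str
    nll: float
    aic: float
    bic: float
    pseudo_r2: float
    n_trials: int
    k_params: int
    n_restarts: int
    converged: bool
    seed: int | None
    restarts: tuple = field(repr=False, default=())

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "params": {
                k: self.params.to_dict()[k] for k in ("alpha_c", "mu", "beta", "gamma")
            },
            "config": {
                k: v
                for k, v in self.params.to_dict().items()
                if k not in ("alpha_c", "mu", "beta", "gamma")
            },
            "nll": self.nll,
            "aic": self.aic,
            "bic": self.bic,
            "pseudo_r2": self.pseudo_r2,
            "n_trials": self.n_trials,
            "k_params": self.k_params,
            "n_restarts": self.n_restarts,
            "converged": self.converged,
            "seed": self.seed,
            "restarts": [dict(r) for r in self.restarts],
        }


def fit(
    seq: ChoiceSequence,
    spec,
    variant="Q_c+u",
    bounds: dict | None = None,
    n_restarts: int = 10,
    seed: int | None = None,
    base_params: ModelParams | None = None,
    engine: str = "numba",
) -> FitResult:
    """Bounded maximum-likelihood fit with Latin-hypercube restarts.

    Free parameters are the variant's (alpha_c, [mu,] beta, gamma);
    everything else (threshold angle, reward scale, initialization) is
    taken from *base_params* (default: the package defaults with the
    spec's threshold angle).  Deterministic given *seed*.
    """
    var = _variant(variant)
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    lo = np.array([bounds[p][0] for p in var.free_params])
    hi = np.array([bounds[p][1] for p in var.free_params])
    if np.any(lo >= hi):
        raise InvalidInputError("each bound must satisfy low < high")
    base = base_params or ModelParams(
        alpha_c=0.5, mu=1.0, beta=5.0, gamma=1.0,
        theta_threshold_deg=getattr(spec, "theta_threshold_deg", 30.0),
    )
    design = spec.design(seq.n_trials)
    choices = _encode(seq, spec)

    def objective(x):
        p = base.replace(**dict(zip(var.free_params, x)))
        nll, _ = replay(choices, design, p, var.update_unchosen, engine)
        return nll

    starts = lo + qmc.LatinHypercube(d=len(var.free_params), seed=seed).random(
        n_restarts
    ) * (hi - lo)
    restarts, best = [], None
    for x0 in starts:
        try:
            res = optimize.minimize(
                objective, x0, method="L-BFGS-B",
                bounds=list(zip(lo, hi)), options={"ftol": 1e-8, "maxiter": 500},
            )
        except FloatingPointError as e:  # pragma: no cover - diagnostic path
            restarts.append({"x0": x0.tolist(), "error": str(e)})
            continue
        restarts.append(
            {"x0": x0.tolist(), "x": res.x.tolist(), "nll": float(res.fun),
             "success": bool(res.success)}
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitFailureError("all optimizer restarts failed", restarts)
    fitted = base.replace(**dict(zip(var.free_params, best.x)))
    ic = information_criteria(best.fun, var.k_params, seq.n_trials, len(spec.options))
    return FitResult(
        params=fitted, variant=var.name, nll=float(best.fun),
        aic=ic.aic, bic=ic.bic, pseudo_r2=ic.pseudo_r2,
        n_trials=seq.n_trials, k_params=var.k_params, n_restarts=n_restarts,
        converged=any(r.get("success") for r in restarts), seed=seed,
        restarts=tuple(restarts),
    )


@dataclass(frozen=True)
class ComparisonReport:
    """Head-to-head comparison of the chosen-only vs chosen+unchosen model."""

    results: dict
    delta_aic: float
    delta_bic: float
    favored: str

    def to_dict(self) -> dict:
        return {
            "delta_aic": self.delta_aic,
            "delta_bic": self.delta_bic,
            "favored": self.favored,
            "results": {k: v.to_dict() for k, v in self.results.items()},
        }


def compare_models(
    seq: ChoiceSequence,
    spec,
    seed: int | None = None,
    n_restarts: int = 10,
    base_params: ModelParams | None = None,
    engine: str = "numba",
) -> ComparisonReport:
    """Fit both variants and report BIC-favored model and deltas.

    delta values are Q_c+u minus Q_c (negative favors Q_c+u).  Exact BIC
    ties go to the variant with fewer parameters.
    """
    results = {
        name: fit(seq, spec, name, n_restarts=n_restarts, seed=seed,
                  base_params=base_params, engine=engine)
        for name in VARIANTS
    }
    d_aic = results["Q_c+u"].aic - results["Q_c"].aic
    d_bic = results["Q_c+u"].bic - results["Q_c"].bic
    favored = "Q_c+u" if d_bic < 0 else "Q_c"
    return ComparisonReport(results, float(d_aic), float(d_bic), favored)
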