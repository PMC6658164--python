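"""Maximum-likelihood estimation of agent parameters, per animal per condition.

All of one animal's sessions under one drug condition are pooled: value state
re-initializes at each session boundary and the pooled log-likelihood is
maximized with bounded L-BFGS-B from multiple Latin-hypercube start points
(the likelihood surface over alpha x beta is routinely multimodal at this
data size).  Learning rates are fitted on their natural [0, 1] scale with box
constraints so reported values are directly comparable across conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .core_io import Session, SessionSet
from .rl_models import MODELS, ModelSpec, ParamSet, loglik_from_arrays, _pack

__all__ = ["FitConfig", "FitResult", "FitError", "fit_mle", "compare_models"]

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (0.0, 1.0),
    "alpha_pos": (0.0, 1.0),
    "alpha_neg": (0.0, 1.0),
    "beta": (0.0, 50.0),
    "bias": (-5.0, 5.0),
    "gamma_win": (-5.0, 5.0),
    "gamma_lose": (-5.0, 5.0),
    "epsilon": (0.0, 5.0),
    "rho": (-10.0, 10.0),
}


class FitError(RuntimeError):
    """No restart converged; carries per-restart diagnostics."""


@dataclass(frozen=True)
class FitConfig:
    """Multi-start optimization settings."""

    n_restarts: int = 20
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    tol: float = 1e-6
    seed: int = 0
    q_init: tuple[float, float] = (0.0, 0.0)
    #: a parameter within this fraction of its bound range from a bound is
    #: flagged as boundary-constrained
    boundary_rtol: float = 1e-3


@dataclass
class FitResult:
    """Best-of-restarts MLE fit for one (animal, condition) group."""

    model_id: int
    params: ParamSet
    nll: float
    n_trials: int
    n_sessions: int
    restart_nlls: np.ndarray
    converged: bool
    boundary_flags: dict[str, bool]
    mouse_id: str = ""
    treatment: str = ""

    @property
    def n_params(self) -> int:
        return MODELS[self.model_id].n_params

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params + 2.0 * self.nll

    @property
    def bic(self) -> float:
        return self.n_params * float(np.log(self.n_trials)) + 2.0 * self.nll


def _check_single_group(sessions: Sequence[Session]) -> tuple[str, str]:
    keys = {(s.mouse_id, s.treatment) for s in sessions}
    if len(keys) > 1:
        raise ValueError(
            f"fit_mle expects sessions from a single animal and condition, "
            f"got {sorted(keys)}"
        )
    return next(iter(keys))


def fit_mle(
    sessions: Sequence[Session],
    model: ModelSpec | int,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit one model to one animal-condition group of sessions by MLE.

    Deterministic given the restart seed.  Boundary flags mark parameters
    whose estimate sits at (or within tolerance of) a box bound.
    """
    if isinstance(model, int):
        model = MODELS[model]
    config = config or FitConfig()
    sessions = list(sessions)
    if not sessions or all(s.n_trials < 2 for s in sessions):
        raise ValueError("fit_mle needs at least one session with >= 2 trials")
    mouse_id, treatment = _check_single_group(sessions)

    is_left, reward, starts = _pack(sessions)
    n_trials = int(is_left.shape[0])
    lo = np.array([config.bounds[n][0] for n in model.free])
    hi = np.array([config.bounds[n][1] for n in model.free])

    def objective(x: np.ndarray) -> float:
        ps = model.paramset_from_vector(np.clip(x, lo, hi))
        return -loglik_from_arrays(is_left, reward, starts, ps, config.q_init)

    sampler = qmc.LatinHypercube(d=model.n_params, seed=config.seed)
    x0s = lo + sampler.random(config.n_restarts) * (hi - lo)

    best = None
    restart_nlls = np.full(config.n_restarts, np.nan)
    any_success = False
    messages = []
    for i in range(config.n_restarts):
        res = minimize(
            objective,
            x0s[i],
            method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"ftol": config.tol, "maxiter": 500},
        )
        restart_nlls[i] = res.fun
        any_success = any_success or bool(res.success)
        if not res.success:
            messages.append(str(res.message))
        if best is None or res.fun < best.fun:
            best = res
    if not any_success:
        raise FitError(
            f"no restart converged for {mouse_id}/{treatment}: "
            f"{sorted(set(messages))}"
        )

    x = np.clip(best.x, lo, hi)
    flags = {
        name: bool(
            x[i] - lo[i] <= config.boundary_rtol * (hi[i] - lo[i])
            or hi[i] - x[i] <= config.boundary_rtol * (hi[i] - lo[i])
        )
        for i, name in enumerate(model.free)
    }
    return FitResult(
        model_id=model.model_id,
        params=model.paramset_from_vector(x),
        nll=float(best.fun),
        n_trials=n_trials,
        n_sessions=len(sessions),
        restart_nlls=restart_nlls,
        converged=any_success,
        boundary_flags=flags,
        mouse_id=mouse_id,
        treatment=treatment,
    )


def fit_cohort(
    data: SessionSet,
    model: ModelSpec | int = 1,
    config: FitConfig | None = None,
) -> pd.DataFrame:
    """Fit every (animal, condition) group; tidy table of fitted parameters.

    Columns mirror the ground-truth schema (mouse_id, line, treatment, the
    eight parameters) plus nll/aic/bic/convergence and boundary columns, so
    the output joins directly onto a generator truth table.
    """
    rows = []
    for (mouse_id, treatment), sessions in sorted(
        data.groupby("mouse_id", "treatment").items()
    ):
        fit = fit_mle(sessions, model, config)
        rows.append(
            {
                "mouse_id": mouse_id,
                "line": sessions[0].line,
                "treatment": treatment,
                **fit.params.as_dict(),
                "model_id": fit.model_id,
                "nll": fit.nll,
                "n_trials": fit.n_trials,
                "n_sessions": fit.n_sessions,
                "aic": fit.aic,
                "bic": fit.bic,
                "converged": fit.converged,
                "at_boundary": ",".join(
                    sorted(k for k, v in fit.boundary_flags.items() if v)
                ),
            }
        )
    return pd.DataFrame(rows)


# nesting chains used to sanity-check fitted log-likelihoods
_NESTED_PAIRS = [(1, 2), (2, 3), (2, 4), (3, 5), (4, 5), (5, 6)]


def compare_models(
    data: SessionSet,
    models: Sequence[ModelSpec | int] | None = None,
    config: FitConfig | None = None,
) -> pd.DataFrame:
    """Fit several model variants to every animal-condition group.

    Returns a long table (mouse_id, treatment, model_id, nll, k, aic, bic)
    with per-model AIC/BIC win indicators.  Groups where a larger nested
    model fits worse than its submodel (an optimization failure) are refitted
    with doubled restarts.
    """
    config = config or FitConfig()
    models = [MODELS[m] if isinstance(m, int) else m for m in (models or MODELS)]
    by_id = {m.model_id: m for m in models}
    rows = []
    for (mouse_id, treatment), sessions in sorted(
        data.groupby("mouse_id", "treatment").items()
    ):
        fits = {m.model_id: fit_mle(sessions, m, config) for m in models}
        # refit any nested violation with a bigger restart budget
        for small, large in _NESTED_PAIRS:
            if small in fits and large in fits:
                if fits[large].nll > fits[small].nll + 10 * config.tol:
                    warnings.warn(
                        f"nested log-likelihood violation for {mouse_id}/"
                        f"{treatment} (model {large} vs {small}); refitting",
                        stacklevel=2,
                    )
                    bigger = FitConfig(
                        n_restarts=2 * config.n_restarts,
                        bounds=config.bounds,
                        tol=config.tol,
                        seed=config.seed + 1,
                        q_init=config.q_init,
                    )
                    refit = fit_mle(sessions, by_id[large], bigger)
                    if refit.nll < fits[large].nll:
                        fits[large] = refit
        for mid, fit in sorted(fits.items()):
            rows.append(
                {
                    "mouse_id": mouse_id,
                    "treatment": treatment,
                    "model_id": mid,
                    "nll": fit.nll,
                    "k": fit.n_params,
                    "n_trials": fit.n_trials,
                    "aic": fit.aic,
                    "bic": fit.bic,
                }
            )
    table = pd.DataFrame(rows)
    for crit in ("aic", "bic"):
        best = table.groupby(["mouse_id", "treatment"])[crit].transform("min")
        table[f"{crit}_win"] = table[crit] == best
    return table
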