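"""Cohort-level fitting harness: information criteria, likelihood-ratio
tests, variance explained, model comparison across the observer variants and
the linear model, and parameter-recovery studies on synthetic cohorts."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from .design import (Cohort, SamplingConfig, SessionDesign, generate_cohort,
                     simulate_cohort_responses)
from .linear import (LinearFitOptions, LinearParams, LinearResponseModel,
                     fit_linear, linear_nll, sequential_predict)
from .observer import (AdaptationParams, ObserverParams, ObserverResponseModel,
                       observer_nll, simulate_observer)

logger = logging.getLogger(__name__)

OBSERVER_MODEL_IDS = ("V1-CI", "V1-CV", "V2-CI", "V2-CV", "V5-CI", "V5-CV")


# ---------------------------------------------------------------------------
# criteria
# ---------------------------------------------------------------------------

def information_criteria(nll: float, n_params: int, n_obs: int) -> Tuple[float, float]:
    """(AIC, BIC) from a negative log-likelihood."""
    if n_obs < 1:
        raise ValueError("n_obs must be at least 1")
    aic = 2.0 * n_params + 2.0 * nll
    bic = n_params * np.log(n_obs) + 2.0 * nll
    return float(aic), float(bic)


def likelihood_ratio_test(nll_restricted: float, nll_full: float, df: int) -> float:
    """p-value of the chi-square LR test between nested fits.

    The statistic is 2*(nll_restricted - nll_full); a negative statistic
    (restricted model fitting better, an optimizer artefact) yields p = 1
    with a warning.
    """
    if df < 1:
        raise ValueError("df must be at least 1")
    stat = 2.0 * (nll_restricted - nll_full)
    if stat < 0:
        warnings.warn("restricted model beat the full model; returning p = 1")
        return 1.0
    return float(stats.chi2.sf(stat, df))


def adjusted_r2(predicted: np.ndarray, responses: np.ndarray, n_params: int) -> float:
    """Adjusted R^2 with R^2 the squared Pearson correlation between the
    predicted probabilities and the 0/1 responses; constant predictions give
    R^2 = 0."""
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(responses, dtype=float)
    if p.shape != r.shape:
        raise ValueError("predicted and responses must have equal length")
    n = p.size
    if n <= n_params + 1:
        raise ValueError("need n > n_params + 1 observations")
    if np.ptp(p) == 0 or np.ptp(r) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(p, r)[0, 1]) ** 2
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1))


def mcfadden_r2(nll: float, responses: np.ndarray) -> float:
    """McFadden pseudo-R^2 against the intercept-only Bernoulli model."""
    r = np.asarray(responses, dtype=float)
    pbar = float(np.clip(r.mean(), 1e-9, 1 - 1e-9))
    null_nll = -float(np.sum(r * np.log(pbar) + (1 - r) * np.log(1 - pbar)))
    return float(1.0 - nll / null_nll) if null_nll > 0 else 0.0


# ---------------------------------------------------------------------------
# fit results and observer fitting
# ---------------------------------------------------------------------------

@dataclass
class ModelFitResult:
    model_id: str
    nll: float
    n_params: int
    n_obs: int
    aic: float
    bic: float
    adj_r2: float
    mcfadden: float
    params: object
    converged: bool = True


def _cohort_responses(sessions: Cohort) -> np.ndarray:
    return np.array([ev.response for _, events in sessions
                     for ev in events if ev.is_test], dtype=float)


def _observer_predictions(sessions: Cohort, params: ObserverParams) -> np.ndarray:
    return np.concatenate([simulate_observer(events, profile, params)
                           for profile, events in sessions])


@dataclass
class ObserverFitOptions:
    n_starts: int = 2
    seed: int = 0
    maxiter: int = 60
    bounds: Dict[str, Tuple[float, float]] = field(default_factory=lambda: {
        "alpha": (0.0, 0.5), "beta": (0.0, 2.0), "tau": (0.0, 0.05),
        "omega": (1.0, 80.0), "w50": (0.01, 0.5), "eps_exp": (0.5, 5.0)})
    free_params: Optional[Tuple[str, ...]] = None  # default: all free for variant


def _observer_vector(params: ObserverParams, names: Sequence[str]) -> np.ndarray:
    vals = {"alpha": params.adaptation.alpha, "beta": params.adaptation.beta,
            "tau": params.adaptation.tau, "omega": params.adaptation.omega,
            "w50": params.contrast.w50, "eps_exp": params.contrast.eps_exp}
    return np.array([vals[n] for n in names])


def _observer_with(params: ObserverParams, names: Sequence[str],
                   x: np.ndarray) -> ObserverParams:
    upd = dict(zip(names, (float(v) for v in x)))
    ad = replace(params.adaptation,
                 **{k: v for k, v in upd.items()
                    if k in ("alpha", "beta", "tau", "omega")})
    cp = replace(params.contrast,
                 **{k: v for k, v in upd.items() if k in ("w50", "eps_exp")})
    return replace(params, adaptation=ad, contrast=cp)


def fit_observer(
    sessions: Cohort,
    init: ObserverParams,
    options: ObserverFitOptions = ObserverFitOptions(),
) -> ModelFitResult:
    """Bounded multi-start maximum-likelihood fit of the observer's free
    parameters (alpha, beta, tau, omega, plus w50/eps_exp in the CV variant,
    or any subset given in ``options.free_params``)."""
    if options.free_params is not None:
        names = tuple(options.free_params)
    elif init.contrast.contrast_variant == "CI":
        names = ("alpha", "beta", "tau", "omega")
    else:
        names = ("alpha", "beta", "tau", "omega", "w50", "eps_exp")
    bounds = [options.bounds[n] for n in names]
    rng = np.random.default_rng(options.seed)

    def objective(x):
        return observer_nll(sessions, _observer_with(init, names, x))

    starts = [_observer_vector(init, names)]
    for _ in range(max(0, options.n_starts - 1)):
        starts.append(np.array([rng.uniform(lo, hi) for lo, hi in bounds]))
    best_x, best_nll, ok = starts[0], np.inf, False
    for x0 in starts:
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": options.maxiter})
        logger.info("observer fit start: nll=%.3f ok=%s", res.fun, res.success)
        if res.fun < best_nll:
            best_x, best_nll, ok = res.x, float(res.fun), bool(res.success)

    fitted = _observer_with(init, names, best_x)
    resp = _cohort_responses(sessions)
    pred = _observer_predictions(sessions, fitted)
    n_params = fitted.n_free_params
    aic, bic = information_criteria(best_nll, n_params, resp.size)
    return ModelFitResult(
        model_id=f"{fitted.preset}-{fitted.contrast.contrast_variant}",
        nll=best_nll, n_params=n_params, n_obs=resp.size, aic=aic, bic=bic,
        adj_r2=adjusted_r2(pred, resp, n_params),
        mcfadden=mcfadden_r2(best_nll, resp), params=fitted, converged=ok)


def fit_linear_model(sessions: Cohort, init: Optional[LinearParams] = None,
                     options: LinearFitOptions = LinearFitOptions()) -> ModelFitResult:
    """Fit the linear model and wrap the result with comparison metrics."""
    res = fit_linear(sessions, init, options)
    resp = _cohort_responses(sessions)
    pred = np.concatenate([sequential_predict(events, profile, res.params)
                           for profile, events in sessions])
    aic, bic = information_criteria(res.nll, res.n_params, resp.size)
    return ModelFitResult(model_id="linear", nll=res.nll, n_params=res.n_params,
                          n_obs=resp.size, aic=aic, bic=bic,
                          adj_r2=adjusted_r2(pred, resp, res.n_params),
                          mcfadden=mcfadden_r2(res.nll, resp),
                          params=res.params, converged=res.converged)


def comparison_table(fits: Sequence[ModelFitResult]) -> pd.DataFrame:
    """Comparison table sorted by AIC, with deltas to the best model."""
    df = pd.DataFrame([{
        "model_id": f.model_id, "nll": f.nll, "n_params": f.n_params,
        "aic": f.aic, "bic": f.bic, "adj_r2": f.adj_r2, "mcfadden": f.mcfadden,
    } for f in fits])
    df["delta_aic"] = df["aic"] - df["aic"].min()
    df["delta_bic"] = df["bic"] - df["bic"].min()
    return df.sort_values("aic").reset_index(drop=True)


def compare_models(
    sessions: Cohort,
    model_ids: Sequence[str] = ("linear",) + OBSERVER_MODEL_IDS,
    linear_options: LinearFitOptions = LinearFitOptions(),
    observer_options: ObserverFitOptions = ObserverFitOptions(),
) -> pd.DataFrame:
    """Fit each requested model to the cohort and tabulate AIC/BIC/adj-R^2.

    Observer model ids are "<preset>-<variant>" (e.g. "V5-CV"); "linear" is
    the descriptive history model.
    """
    fits = []
    for mid in model_ids:
        if mid == "linear":
            fits.append(fit_linear_model(sessions, options=linear_options))
        else:
            preset, variant = mid.split("-")
            init = ObserverParams.from_preset(preset, variant)
            fits.append(fit_observer(sessions, init, observer_options))
        logger.info("fitted %s: nll=%.2f", mid, fits[-1].nll)
    return comparison_table(fits)


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    parameter: Dict[str, dict]
    n_reps: int
    n_failures: int


def recovery_study(
    true_params,
    group_sizes: Optional[dict] = None,
    design: SessionDesign = SessionDesign(),
    sampling: SamplingConfig = SamplingConfig(),
    n_reps: int = 10,
    seed: int = 0,
    linear_options: Optional[LinearFitOptions] = None,
    observer_options: Optional[ObserverFitOptions] = None,
) -> RecoveryReport:
    """Simulate-and-refit validation: generate cohorts whose responses come
    from ``true_params`` (a :class:`LinearParams` or :class:`ObserverParams`),
    refit, and summarise bias/RMSE per parameter over replicates.

    Deterministic given ``seed``; fit failures are counted, not dropped.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    root = np.random.default_rng(seed)
    is_linear = isinstance(true_params, LinearParams)
    values: Dict[str, List[float]] = {}
    failures = 0
    for rep in range(n_reps):
        s1, s2 = (int(v) for v in root.integers(0, 2**31 - 1, size=2))
        cohort = generate_cohort(group_sizes, design, sampling, seed=s1)
        if is_linear:
            model_for = lambda prof: LinearResponseModel(prof, true_params)
        else:
            model_for = lambda prof: ObserverResponseModel(prof, true_params)
        cohort = simulate_cohort_responses(cohort, model_for, seed=s2)
        if is_linear:
            opts = linear_options or LinearFitOptions(n_starts=1, m_sweeps=0,
                                                      seed=rep)
            # neutral start: zero weights at the true timescales, gamma = 1
            init = LinearParams.zeros(
                m=[c.m for c in true_params.components_high])
            init = LinearParams(init.components_high,
                                tuple(type(c)(0.0, c.m)
                                      for c in true_params.components_low), 1.0)
            fit = fit_linear(cohort, init=init, options=opts)
            rec = {"gamma": fit.params.gamma}
            for side in ("high", "low"):
                for j, c in enumerate(fit.params.components(side)):
                    rec[f"w_{side}{j + 1}"] = c.w
            ok = fit.converged
        else:
            opts = observer_options or ObserverFitOptions(
                n_starts=1, seed=rep, free_params=("alpha",))
            # neutral start: library-default dynamics, truth's structure
            init = replace(true_params, adaptation=AdaptationParams())
            fit = fit_observer(cohort, init, opts)
            names = opts.free_params or ("alpha", "beta", "tau", "omega")
            vec = _observer_vector(fit.params, names)
            rec = dict(zip(names, (float(v) for v in vec)))
            ok = fit.converged
        if not ok:
            failures += 1
        for k, v in rec.items():
            values.setdefault(k, []).append(float(v))
        logger.info("recovery rep %d/%d done", rep + 1, n_reps)

    truth: Dict[str, float] = {}
    if is_linear:
        truth["gamma"] = true_params.gamma
        for side in ("high", "low"):
            for j, c in enumerate(true_params.components(side)):
                truth[f"w_{side}{j + 1}"] = c.w
    else:
        for k in values:
            truth[k] = float(_observer_vector(true_params, (k,))[0])

    report = {}
    for k, vals in values.items():
        arr = np.array(vals)
        report[k] = {
            "true": truth[k], "median": float(np.median(arr)),
            "bias": float(arr.mean() - truth[k]),
            "rmse": float(np.sqrt(np.mean((arr - truth[k]) ** 2))),
            "values": [float(v) for v in arr],
        }
    return RecoveryReport(parameter=report, n_reps=n_reps, n_failures=failures)
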