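"""Descriptive linear history model of serial dependence.

The probability of judging a test counterclockwise ("orange") is a logistic
psychometric function whose midpoint is shifted by a weighted sum of past
stimuli.  Writing ``theta_t`` for stimulus orientations and ``c_t`` for the
(time-varying) psychometric midpoint, the shift applied when judging
stimulus ``s`` is

    shift_s = k_norm * sum_i  s_i * (c_{s-i} - theta_{s-i}) * F_i,

with ``k_norm = 2 ln(9) / k`` normalising across participants of different
sensitivity, ``s_i = 1`` for high-contrast past stimuli and ``1/gamma`` for
low-contrast ones (``gamma`` > 1 means low-contrast adaptors exert weaker
influence), and ``F`` a piecewise-linear influence function built from a
handful of decaying-ramp components:

    f_i = w * (1 - (i - 1) / m)   for 1 <= i <= m,   0 beyond m.

A component with negative ``w`` is repulsive (the midpoint moves toward the
adaptor, so subsequent percepts move away); positive ``w`` is attractive.
Separate component triplets apply depending on the *judged* test's contrast,
capturing the finding that repulsion is stronger on high-contrast tests and
attraction on low-contrast tests.  The free parameters (3 components x
(w, m) x 2 contrasts, plus gamma) number 13.

Midpoints are tracked causally: the history term for a past stimulus uses the
midpoint the model held at that stimulus's own presentation time, computed in
a single forward pass over the session (one pass per test-contrast level,
since the influence function differs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numba import njit
from scipy.optimize import minimize
from scipy.special import expit

from .design import Cohort, ParticipantProfile, ResponseModel, StimulusEvent

logger = logging.getLogger(__name__)

K_NORM_SCALE = 2.0 * np.log(9.0)
PROB_CLIP = 1e-9


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearComponent:
    """One decaying-ramp influence component: initial weight ``w`` of the
    one-back stimulus and the number of stimuli ``m`` it takes to reach 0."""

    w: float
    m: int

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be a positive integer")


@dataclass(frozen=True)
class LinearParams:
    """Full parameter set of the linear model (13 free parameters)."""

    components_high: Tuple[LinearComponent, ...]
    components_low: Tuple[LinearComponent, ...]
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        object.__setattr__(self, "components_high", tuple(self.components_high))
        object.__setattr__(self, "components_low", tuple(self.components_low))

    @property
    def n_params(self) -> int:
        return 2 * (len(self.components_high) + len(self.components_low)) + 1

    def components(self, contrast_level: str) -> Tuple[LinearComponent, ...]:
        if contrast_level == "high":
            return self.components_high
        if contrast_level == "low":
            return self.components_low
        raise ValueError(f"unknown contrast level {contrast_level!r}")

    @staticmethod
    def zeros(m: Sequence[int] = (2, 50, 300), gamma: float = 1.0) -> "LinearParams":
        comps = tuple(LinearComponent(0.0, int(mi)) for mi in m)
        return LinearParams(comps, comps, gamma)


def influence_function(
    params: LinearParams, test_contrast: str, n_lags: Optional[int] = None
) -> np.ndarray:
    """Influence weights F_1..F_S for the given judged-test contrast.

    The contrast of *past* stimuli is not applied here; it enters the shift
    as a separate per-stimulus multiplier (1 or 1/gamma).
    """
    comps = params.components(test_contrast)
    max_m = max((c.m for c in comps), default=1)
    S = int(n_lags) if n_lags is not None else max_m
    F = np.zeros(S)
    i = np.arange(1, S + 1, dtype=float)
    for c in comps:
        ramp = np.where(i <= c.m, c.w * (1.0 - (i - 1.0) / c.m), 0.0)
        F += ramp
    return F


# ---------------------------------------------------------------------------
# sequential midpoint tracking (numba core)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _shift_pass(theta, low_scale, c0, knorm, F):  # pragma: no cover - jitted
    """Forward pass over one session: midpoint shift at every stimulus.

    theta     (n,)  stimulus orientations
    low_scale (n,)  per-stimulus adaptor multiplier (1 or 1/gamma)
    c0, knorm       scalars for this participant/trajectory
    F         (L,)  influence weights for this test-contrast level
    returns   (n,)  shift_t such that the midpoint at t is c0 + shift_t

    The shift is clamped to +/-90 deg (one orientation period): the linear
    recursion can diverge for aggressive parameter values during fitting,
    and shifts beyond the period are meaningless.
    """
    n = theta.shape[0]
    L = F.shape[0]
    d = np.empty(n)
    shift = np.empty(n)
    for t in range(n):
        acc = 0.0
        kmax = t if t < L else L
        for i in range(1, kmax + 1):
            acc += d[t - i] * F[i - 1]
        sh = knorm * acc
        if sh > 90.0:
            sh = 90.0
        elif sh < -90.0:
            sh = -90.0
        shift[t] = sh
        d[t] = low_scale[t] * (c0 + sh - theta[t])
    return shift


def _session_arrays(events: Sequence[StimulusEvent]):
    theta = np.array([ev.orientation for ev in events])
    is_low = np.array([ev.contrast_level == "low" for ev in events])
    is_test = np.array([ev.is_test for ev in events])
    test_high = np.array([ev.contrast_level == "high" for ev in events if ev.is_test])
    return theta, is_low, is_test, test_high


def midpoint_shift(
    history: Sequence[Tuple[float, float, str]],
    params: LinearParams,
    test_contrast: str,
    k: float,
) -> float:
    """Shift (degrees) for a single judgement given an explicit history.

    ``history`` lists past stimuli oldest first as
    ``(orientation, midpoint_at_that_time, contrast_level)``.  Provided for
    unit-level reasoning; the sequential pass is the workhorse.
    """
    if not history:
        return 0.0
    F = influence_function(params, test_contrast, n_lags=len(history))
    knorm = K_NORM_SCALE / k
    acc = 0.0
    for lag, (th, c_at, lvl) in enumerate(reversed(history), start=1):
        s = 1.0 if lvl == "high" else 1.0 / params.gamma
        acc += s * (c_at - th) * F[lag - 1]
    return knorm * acc


def response_probability(
    theta: float, contrast: str, midpoint: float, profile: ParticipantProfile
) -> float:
    """Logistic P("orange") for a test at ``theta`` given the current midpoint."""
    k = profile.slope(contrast)
    return float(expit(k * (theta - midpoint)))


def sequential_predict(
    events: Sequence[StimulusEvent],
    profile: ParticipantProfile,
    params: LinearParams,
    return_midpoints: bool = False,
):
    """P("orange") for every test event of a session, in order.

    Runs one causal midpoint pass per test-contrast level (the influence
    function and k_norm differ between them) and reads off the logistic at
    each test.
    """
    idx = [ev.index for ev in events]
    if any(b <= a for a, b in zip(idx, idx[1:])):
        raise ValueError("events must be ordered by index")
    theta, is_low, is_test, test_high = _session_arrays(events)
    low_scale = np.where(is_low, 1.0 / params.gamma, 1.0)

    shifts = {}
    for level, k in (("high", profile.k_high), ("low", profile.k_low)):
        F = influence_function(params, level)
        shifts[level] = _shift_pass(theta, low_scale, profile.c0, K_NORM_SCALE / k, F)

    t_idx = np.flatnonzero(is_test)
    midpoints = np.where(test_high,
                         profile.c0 + shifts["high"][t_idx],
                         profile.c0 + shifts["low"][t_idx])
    k_test = np.where(test_high, profile.k_high, profile.k_low)
    probs = expit(k_test * (theta[t_idx] - midpoints))
    if return_midpoints:
        return probs, midpoints
    return probs


class LinearResponseModel:
    """Adapter exposing the response-model interface used by the generator."""

    def __init__(self, profile: ParticipantProfile, params: LinearParams):
        self.profile = profile
        self.params = params

    def test_probabilities(self, events: Sequence[StimulusEvent]) -> np.ndarray:
        return sequential_predict(events, self.profile, self.params)


# ---------------------------------------------------------------------------
# likelihood and fitting
# ---------------------------------------------------------------------------

def _cohort_data(sessions: Cohort):
    """Pre-extract arrays for repeated NLL evaluation."""
    data = []
    for profile, events in sessions:
        theta, is_low, is_test, test_high = _session_arrays(events)
        resp = [ev.response for ev in events if ev.is_test]
        if any(r is None for r in resp):
            raise ValueError(f"session {profile.participant_id}: test without response")
        data.append((profile, theta, is_low, np.flatnonzero(is_test),
                     test_high, np.array(resp, dtype=float)))
    return data


def _nll_from_data(data, params: LinearParams) -> float:
    nll = 0.0
    for profile, theta, is_low, t_idx, test_high, resp in data:
        low_scale = np.where(is_low, 1.0 / params.gamma, 1.0)
        probs = np.empty(len(t_idx))
        for level, k, mask in (("high", profile.k_high, test_high),
                               ("low", profile.k_low, ~test_high)):
            F = influence_function(params, level)
            sh = _shift_pass(theta, low_scale, profile.c0, K_NORM_SCALE / k, F)
            mid = profile.c0 + sh[t_idx[mask]]
            probs[mask] = expit(k * (theta[t_idx[mask]] - mid))
        p = np.clip(probs, PROB_CLIP, 1.0 - PROB_CLIP)
        nll -= float(np.sum(resp * np.log(p) + (1.0 - resp) * np.log(1.0 - p)))
    return nll


def linear_nll(sessions: Cohort, params: LinearParams) -> float:
    """Pooled negative log-likelihood of all responses in the cohort.

    Probabilities are clipped to [1e-9, 1 - 1e-9] to keep the sum finite.
    """
    return _nll_from_data(_cohort_data(sessions), params)


@dataclass
class LinearFitOptions:
    n_starts: int = 5
    m_candidates: Tuple[int, ...] = (1, 2, 3, 5, 10, 20, 50, 100, 200, 400)
    m_sweeps: int = 1          # coordinate-descent sweeps over the m's; 0 fixes m at init
    w_bound: float = 2.0
    gamma_bounds: Tuple[float, float] = (0.25, 16.0)
    seed: int = 0
    maxiter: int = 200


@dataclass
class LinearFitResult:
    params: LinearParams
    nll: float
    converged: bool
    n_params: int = 13


def _pack(params: LinearParams) -> np.ndarray:
    ws = [c.w for c in params.components_high] + [c.w for c in params.components_low]
    return np.array(ws + [np.log(params.gamma)])


def _unpack(x: np.ndarray, m_high: Sequence[int], m_low: Sequence[int]) -> LinearParams:
    nh, nl = len(m_high), len(m_low)
    ch = tuple(LinearComponent(float(w), int(m)) for w, m in zip(x[:nh], m_high))
    cl = tuple(LinearComponent(float(w), int(m)) for w, m in zip(x[nh:nh + nl], m_low))
    return LinearParams(ch, cl, float(np.exp(x[nh + nl])))


def fit_linear(
    sessions: Cohort,
    init: Optional[LinearParams] = None,
    options: LinearFitOptions = LinearFitOptions(),
) -> LinearFitResult:
    """Pooled maximum-likelihood fit of the linear model.

    Continuous parameters (component weights and log-gamma) are optimised
    with bounded L-BFGS-B from multiple starts; the integer component
    timescales ``m`` are handled by nested coordinate descent over
    ``options.m_candidates`` (``m_sweeps=0`` keeps them at their initial
    values).  Ties between m values are broken toward the smaller m.
    """
    data = _cohort_data(sessions)
    init = init or LinearParams.zeros()
    rng = np.random.default_rng(options.seed)
    m_high = [c.m for c in init.components_high]
    m_low = [c.m for c in init.components_low]
    nh, nl = len(m_high), len(m_low)
    bounds = [(-options.w_bound, options.w_bound)] * (nh + nl)
    bounds.append(tuple(np.log(options.gamma_bounds)))

    def objective(x, mh, ml):
        return _nll_from_data(data, _unpack(x, mh, ml))

    def local_fit(x0, mh, ml):
        res = minimize(objective, x0, args=(mh, ml), method="L-BFGS-B",
                       bounds=bounds, options={"maxiter": options.maxiter})
        return res.x, float(res.fun), bool(res.success)

    # multi-start on the continuous parameters at the initial m's
    starts = [_pack(init)]
    for _ in range(max(0, options.n_starts - 1)):
        x = rng.uniform(-0.3, 0.3, size=nh + nl + 1)
        x[-1] = rng.uniform(*np.log(options.gamma_bounds))
        starts.append(x)
    best_x, best_nll, best_ok = None, np.inf, False
    for x0 in starts:
        x, nll, ok = local_fit(x0, m_high, m_low)
        logger.info("linear fit start: nll=%.3f ok=%s", nll, ok)
        if nll < best_nll:
            best_x, best_nll, best_ok = x, nll, ok

    # nested coordinate descent on the integer timescales
    for _ in range(options.m_sweeps):
        for side, ms in (("high", m_high), ("low", m_low)):
            for j in range(len(ms)):
                cur = ms[j]
                for cand in options.m_candidates:
                    if cand == cur:
                        continue
                    trial = list(ms)
                    trial[j] = cand
                    mh = trial if side == "high" else m_high
                    ml = trial if side == "low" else m_low
                    x, nll, ok = local_fit(best_x, mh, ml)
                    better = nll < best_nll - 1e-6 or (
                        abs(nll - best_nll) <= 1e-6 and cand < cur)
                    if better:
                        best_x, best_nll, best_ok, ms[j], cur = x, nll, ok, cand, cand
                logger.info("m-search %s[%d] -> m=%d nll=%.3f", side, j, ms[j], best_nll)

    params = _unpack(best_x, m_high, m_low)
    init_nll = _nll_from_data(data, init)
    if best_nll > init_nll:     # guard: never worse than the initial point
        params, best_nll = init, init_nll
    if not best_ok:
        logger.warning("linear fit did not fully converge; returning best-so-far")
    return LinearFitResult(params=params, nll=best_nll, converged=best_ok,
                           n_params=params.n_params)
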