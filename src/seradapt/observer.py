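"""Bayesian observer with adapting orientation channels.

Mechanistic counterpart of the linear history model.  Orientation is encoded
by a bank of N von Mises tuned channels (180-deg periodic, handled in
double-angle space).  Each presentation:

1. gains recover toward 1 at rate ``beta`` over the blank since the previous
   stimulus offset;
2. the channels respond; the response amplitude saturates with contrast
   (Naka-Rushton, semi-saturation ``c50``, exponent ``c_exp``) and, in the
   contrast-variant (CV) flavour, the tuning concentration also saturates
   with contrast (``w50``, ``eps_exp``);
3. the orientation likelihood is decoded as
   log L(theta) = omega_s * sum_i m_i n_i log phi_i(theta),
   with ``omega_s`` an accumulation factor proportional to stimulus duration
   and ``m_i`` the current gains — a reduced, asymmetric gain profile skews
   the likelihood *away* from recent adaptors (repulsion);
4. the likelihood is multiplied with a slowly-learned prior over orientation
   to give the posterior (attraction toward the session statistics);
5. for tests, P("orange") is the probability that a draw from the posterior
   is counterclockwise of a draw from the observer's noisy reference
   representation (an AUC between the two distributions);
6. the presentation reduces gains, m_i <- m_i (1 - alpha n_i);
7. the prior is nudged toward the posterior, p <- (1 - tau) p + tau post.

Repulsion therefore scales *up* with test contrast (stronger responses read
out through the distorted gain profile) while prior attraction scales *down*
(narrow likelihoods resist the prior) — the contrast/sign interaction the
model exists to capture.

Channel constants per cortical-area preset (V1/V2/V5) are loaded from a JSON
config of placeholder values; the free parameters are (alpha, beta, tau,
omega) plus (w50, eps_exp) in the CV variant.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import i0

from .design import Cohort, ParticipantProfile, StimulusEvent

logger = logging.getLogger(__name__)

ORIENTATION_PERIOD = 180.0
BASE_DURATION = 0.300   # seconds; omega is defined per 300 ms presentation
PROB_CLIP = 1e-9


# ---------------------------------------------------------------------------
# grid and distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrientationGrid:
    """Even discretisation of one 180-deg orientation period (PSE-relative
    degrees in [-90, 90)); all distributions are probability masses on it."""

    resolution: float = 0.25

    def __post_init__(self) -> None:
        n = ORIENTATION_PERIOD / self.resolution
        if abs(n - round(n)) > 1e-9:
            raise ValueError("resolution must divide the 180-deg period evenly")

    @property
    def values(self) -> np.ndarray:
        return np.arange(-90.0, 90.0, self.resolution)

    @property
    def size(self) -> int:
        return int(round(ORIENTATION_PERIOD / self.resolution))

    @property
    def double_angle(self) -> np.ndarray:
        """Grid in double-angle radians, z = 2*theta (period 2*pi)."""
        return np.deg2rad(2.0 * self.values)


def vm_logpdf(z: np.ndarray, mu_z: float, kappa: float) -> np.ndarray:
    """log von Mises density at double-angle z (radians)."""
    return kappa * np.cos(z - mu_z) - np.log(2.0 * np.pi * i0(kappa))


def vm_pmf(grid: OrientationGrid, mu_deg: float, kappa: float) -> np.ndarray:
    """Normalised von Mises probability mass on the grid (mean in degrees,
    concentration in double-angle units)."""
    lp = vm_logpdf(grid.double_angle, np.deg2rad(2.0 * mu_deg), kappa)
    p = np.exp(lp - lp.max())
    return p / p.sum()


def normalize(mass: np.ndarray) -> np.ndarray:
    mass = np.asarray(mass, dtype=float)
    if np.any(mass < 0):
        raise ValueError("probability mass must be non-negative")
    total = mass.sum()
    if total <= 0:
        raise ValueError("probability mass sums to zero")
    return mass / total


def circular_mean_deg(grid: OrientationGrid, mass: np.ndarray) -> float:
    """Circular mean orientation (degrees) of a mass on the grid."""
    z = grid.double_angle
    c = float(np.sum(mass * np.cos(z)))
    s = float(np.sum(mass * np.sin(z)))
    return float(np.rad2deg(np.arctan2(s, c)) / 2.0)


# ---------------------------------------------------------------------------
# channel bank and contrast transduction
# ---------------------------------------------------------------------------

@dataclass
class ChannelBank:
    """Bank of von Mises orientation channels with adaptable gains."""

    n_channels: int = 60
    kappa_phi: float = 1.2
    grid: OrientationGrid = field(default_factory=OrientationGrid)
    gains: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.gains is None:
            self.gains = np.ones(self.n_channels)
        self.gains = np.asarray(self.gains, dtype=float)
        if self.gains.shape != (self.n_channels,):
            raise ValueError("gains shape mismatch")
        if np.any(self.gains <= 0) or np.any(self.gains > 1):
            raise ValueError("gains must lie in (0, 1]")

    @property
    def preferred(self) -> np.ndarray:
        """Preferred orientations, equally spread over the period (degrees)."""
        step = ORIENTATION_PERIOD / self.n_channels
        return -90.0 + step * np.arange(self.n_channels)

    @property
    def log_tuning(self) -> np.ndarray:
        """(N, G) log tuning curves at maximum contrast on the grid."""
        if not hasattr(self, "_log_tuning"):
            z = self.grid.double_angle[None, :]
            mu = np.deg2rad(2.0 * self.preferred)[:, None]
            object.__setattr__(self, "_log_tuning",
                               vm_logpdf(z, mu, self.kappa_phi))
        return self._log_tuning

    def reset(self) -> None:
        self.gains = np.ones(self.n_channels)


@dataclass(frozen=True)
class ContrastParams:
    """Contrast transduction constants.

    Response gain follows a Naka-Rushton saturation c^c_exp / (c50^c_exp +
    c^c_exp); in the CV variant the tuning concentration saturates the same
    way with (w50, eps_exp).  Both are rescaled to equal their nominal
    maximum-contrast values exactly at c = 1.
    """

    c50: float = 0.10
    c_exp: float = 2.0
    w50: float = 0.09
    eps_exp: float = 2.3
    contrast_variant: str = "CV"

    def __post_init__(self) -> None:
        if min(self.c50, self.c_exp, self.w50, self.eps_exp) <= 0:
            raise ValueError("contrast constants must be positive")
        if self.contrast_variant not in ("CI", "CV"):
            raise ValueError("contrast_variant must be 'CI' or 'CV'")

    def gain(self, contrast: float) -> float:
        """Response amplitude in (0, asymptote], normalised to 1 at c=1."""
        c = np.asarray(contrast, dtype=float)
        raw = c**self.c_exp / (self.c50**self.c_exp + c**self.c_exp)
        at1 = 1.0 / (self.c50**self.c_exp + 1.0)
        return raw / at1

    def kappa_c(self, contrast: float, kappa_phi: float) -> float:
        """Tuning concentration at this contrast (CV), or kappa_phi (CI)."""
        if self.contrast_variant == "CI":
            return kappa_phi
        c = np.asarray(contrast, dtype=float)
        raw = c**self.eps_exp / (self.w50**self.eps_exp + c**self.eps_exp)
        at1 = 1.0 / (self.w50**self.eps_exp + 1.0)
        return kappa_phi * raw / at1


@dataclass(frozen=True)
class AdaptationParams:
    """Dynamics: gain-reduction rate ``alpha`` (per presentation, scaled by
    channel activation), recovery rate ``beta`` (1/s), prior integration rate
    ``tau`` (per presentation), response accumulation ``omega`` (per 300 ms)."""

    alpha: float = 0.08
    beta: float = 0.10
    tau: float = 0.005
    omega: float = 15.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must lie in [0, 1)")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must lie in [0, 1]")
        if self.omega <= 0:
            raise ValueError("omega must be positive")


def load_presets() -> dict:
    """Channel-constant presets per cortical area (synthetic placeholders)."""
    with resources.files("seradapt.presets").joinpath(
            "channel_presets_synthetic.json").open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class ObserverParams:
    """Everything needed to run the observer on a session."""

    adaptation: AdaptationParams = field(default_factory=AdaptationParams)
    contrast: ContrastParams = field(default_factory=ContrastParams)
    n_channels: int = 60
    kappa_phi: float = 1.2
    preset: str = "custom"
    grid_resolution: float = 0.25

    @property
    def n_free_params(self) -> int:
        """4 in the CI variant (alpha, beta, tau, omega); 6 in CV (+w50, eps)."""
        return 4 if self.contrast.contrast_variant == "CI" else 6

    @staticmethod
    def from_preset(preset: str, variant: str = "CV",
                    adaptation: Optional[AdaptationParams] = None,
                    w50: float = 0.09, eps_exp: float = 2.3,
                    grid_resolution: float = 0.25) -> "ObserverParams":
        presets = load_presets()
        if preset not in presets:
            raise KeyError(f"unknown preset {preset!r}; have {sorted(presets)}")
        p = presets[preset]
        cp = ContrastParams(c50=p["c50"], c_exp=p["c_exp"], w50=w50,
                            eps_exp=eps_exp, contrast_variant=variant)
        return ObserverParams(adaptation=adaptation or AdaptationParams(),
                              contrast=cp, kappa_phi=p["kappa_phi"],
                              preset=preset, grid_resolution=grid_resolution)

    def make_bank(self) -> ChannelBank:
        return ChannelBank(n_channels=self.n_channels, kappa_phi=self.kappa_phi,
                           grid=OrientationGrid(self.grid_resolution))


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def channel_response(theta: float, contrast: float, bank: ChannelBank,
                     cp: ContrastParams) -> np.ndarray:
    """Per-channel response in [0, asymptote]: contrast gain times the
    peak-normalised tuning curve evaluated at the stimulus orientation."""
    if contrast <= 0:
        raise ValueError("contrast must be positive")
    kappa = cp.kappa_c(contrast, bank.kappa_phi)
    dz = np.deg2rad(2.0 * (theta - bank.preferred))
    tuning = np.exp(kappa * (np.cos(dz) - 1.0))   # peak-normalised von Mises
    return cp.gain(contrast) * tuning


def encode_likelihood(responses: np.ndarray, bank: ChannelBank,
                      omega_s: float) -> np.ndarray:
    """Decode the orientation likelihood from channel responses.

    log-mass = omega_s * sum_i gains_i * responses_i * log phi_i(grid),
    exponentiated and normalised.  All-zero drive yields a uniform mass.
    """
    weights = omega_s * bank.gains * np.asarray(responses, dtype=float)
    logmass = weights @ bank.log_tuning
    logmass -= logmass.max()
    return normalize(np.exp(logmass))


def apply_adaptation(bank: ChannelBank, responses: np.ndarray,
                     alpha: float) -> np.ndarray:
    """Reduce gains in place: m_i <- m_i (1 - alpha n_i); returns the gains."""
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must lie in [0, 1)")
    bank.gains = bank.gains * (1.0 - alpha * np.asarray(responses, dtype=float))
    return bank.gains

def recover_gains(bank: ChannelBank, beta: float, dt: float) -> np.ndarray:
    """Relax gains toward 1: m_i <- m_i (1 - r) + r with r = min(beta*dt, 1)."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    r = min(beta * dt, 1.0)
    bank.gains = bank.gains * (1.0 - r) + r
    return bank.gains


def update_prior(prior: np.ndarray, posterior: np.ndarray, tau: float) -> np.ndarray:
    """Convex step of the prior toward the current posterior."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    return normalize((1.0 - tau) * prior + tau * posterior)


def compute_posterior(likelihood: np.ndarray, prior: np.ndarray) -> np.ndarray:
    """Pointwise product of likelihood and prior, renormalised."""
    return normalize(likelihood * prior)


def decision_weights(grid: OrientationGrid, reference: np.ndarray,
                     mu_ref: float) -> np.ndarray:
    """Per-gridpoint weight W(x) = P(ref < x) + 0.5 P(ref = x), with the
    circular grid linearised around the reference mean so that
    'counterclockwise of the reference' is well defined."""
    lin = np.mod(grid.values - mu_ref + 90.0, ORIENTATION_PERIOD)
    order = np.argsort(lin, kind="stable")
    ref_sorted = reference[order]
    below = np.concatenate(([0.0], np.cumsum(ref_sorted)[:-1]))
    w_sorted = below + 0.5 * ref_sorted
    W = np.empty_like(w_sorted)
    W[order] = w_sorted
    return W


def decision_probability(posterior: np.ndarray, reference: np.ndarray,
                         grid: OrientationGrid, mu_ref: float = 0.0) -> float:
    """P("orange") = P(posterior draw CCW of reference draw), the AUC between
    the two distributions; identical distributions give exactly 0.5."""
    if posterior.shape != reference.shape:
        raise ValueError("posterior and reference must share the grid")
    return float(np.sum(posterior * decision_weights(grid, reference, mu_ref)))


# ---------------------------------------------------------------------------
# full sequential observer
# ---------------------------------------------------------------------------

@dataclass
class ObserverTrace:
    """Optional per-stimulus state snapshots from a simulation run."""

    gains: List[np.ndarray] = field(default_factory=list)
    prior_mean: List[float] = field(default_factory=list)
    likelihood_mean: List[float] = field(default_factory=list)


def simulate_observer(
    events: Sequence[StimulusEvent],
    profile: ParticipantProfile,
    params: ObserverParams,
    trace: bool = False,
):
    """Run the observer over an ordered session; P("orange") per test event.

    Per stimulus: recover gains over the preceding blank, respond, decode the
    likelihood with current gains, combine with the prior, decide if it is a
    test, then adapt the gains and update the prior.  The prior starts
    uniform; the reference distribution is fixed for the whole session.
    """
    idx = [ev.index for ev in events]
    if any(b <= a for a, b in zip(idx, idx[1:])):
        raise ValueError("events must be ordered by index")
    onsets = [ev.onset for ev in events]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("onsets must be strictly increasing")

    ad, cp = params.adaptation, params.contrast
    bank = params.make_bank()
    grid = bank.grid
    prior = np.full(grid.size, 1.0 / grid.size)
    reference = vm_pmf(grid, profile.mu_ref, profile.kappa_ref)
    ref_weights = decision_weights(grid, reference, profile.mu_ref)

    probs: List[float] = []
    traces = ObserverTrace() if trace else None
    prev_offset = None
    for ev in events:
        if prev_offset is not None:
            recover_gains(bank, ad.beta, ev.onset - prev_offset)
        responses = channel_response(ev.orientation, ev.contrast, bank, cp)
        omega_s = ad.omega * ev.duration / BASE_DURATION
        likelihood = encode_likelihood(responses, bank, omega_s)
        posterior = compute_posterior(likelihood, prior)
        if ev.is_test:
            probs.append(float(np.sum(posterior * ref_weights)))
        apply_adaptation(bank, responses, ad.alpha)
        prior = update_prior(prior, posterior, ad.tau)
        prev_offset = ev.onset + ev.duration
        if traces is not None:
            traces.gains.append(bank.gains.copy())
            traces.prior_mean.append(circular_mean_deg(grid, prior))
            traces.likelihood_mean.append(circular_mean_deg(grid, likelihood))

    out = np.array(probs)
    return (out, traces) if trace else out


class ObserverResponseModel:
    """Response-model adapter for the session generator."""

    def __init__(self, profile: ParticipantProfile, params: ObserverParams):
        self.profile = profile
        self.params = params

    def test_probabilities(self, events: Sequence[StimulusEvent]) -> np.ndarray:
        return simulate_observer(events, self.profile, self.params)


def observer_nll(sessions: Cohort, params: ObserverParams) -> float:
    """Pooled negative log-likelihood of the cohort's responses under the
    observer; same clipping convention as the linear model."""
    nll = 0.0
    for profile, events in sessions:
        resp = [ev.response for ev in events if ev.is_test]
        if any(r is None for r in resp):
            raise ValueError(f"session {profile.participant_id}: test without response")
        p = np.clip(simulate_observer(events, profile, params),
                    PROB_CLIP, 1.0 - PROB_CLIP)
        r = np.array(resp, dtype=float)
        nll -= float(np.sum(r * np.log(p) + (1.0 - r) * np.log(1.0 - p)))
    return nll


def equivalent_duration(c_low: float, c_high: float, cp: ContrastParams,
                        base: float = BASE_DURATION) -> float:
    """Duration at contrast ``c_high`` whose accumulated drive matches a
    ``base``-long presentation at ``c_low`` (exact for the CI variant, where
    only the response amplitude depends on contrast)."""
    return base * float(cp.gain(c_low)) / float(cp.gain(c_high))
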