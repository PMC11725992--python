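"""Synthetic three-group adaptor/test sessions for serial-dependence experiments.

A session is an ordered stream of oriented Gabor presentations.  Most stimuli
are *adaptors* the observer merely watches; at cued positions the last shown
stimulus is a *test* that must be judged counterclockwise ("orange", coded 1)
or clockwise ("blue", coded 0) of a static reference.  Orientations are stored
in degrees relative to each participant's point of subjective equality (PSE),
with counterclockwise positive.

The session is split into three equal blocks.  Block i draws adaptors from a
unimodal Gaussian centred on the PSE; block iii from a balanced bimodal
mixture with modes at +/-15 deg.  Block ii differs per group:

* group A — balanced bimodal (baseline);
* group B — unbalanced bimodal, the counterclockwise mode three times more
  likely than the clockwise one;
* group C — balanced bimodal, but every clockwise adaptor is shown at low
  contrast.

Tests appear at +/-3 deg from the PSE at high or low contrast (four types:
HC+, LC+, HC-, LC-), once at the end of every 12-stimulus cycle plus once at
a random position inside the cycle, balanced so that every 240-trial span
holds 10 tests of each type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import List, Optional, Protocol, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

GROUPS = ("A", "B", "C")
TEST_TYPES = ("HC+", "LC+", "HC-", "LC-")

#: interval between stimulus offset and the next onset, seconds
DEFAULT_ISI = 0.900
#: stimulus presentation time, seconds
DEFAULT_DURATION = 0.300


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParticipantProfile:
    """Baseline psychometrics of one synthetic participant.

    ``c0`` is the baseline psychometric midpoint in PSE-relative degrees
    (near zero: it absorbs the measurement error of the preliminary
    staircases).  ``k_high``/``k_low`` are logistic slopes (1/deg) at the two
    contrast levels.  ``mu_ref``/``kappa_ref`` describe the observer's noisy
    internal representation of the reference orientation (kappa in
    double-angle radian units).
    """

    participant_id: str
    group: str
    c0: float
    k_high: float
    k_low: float
    mu_ref: float
    kappa_ref: float
    low_contrast: float = 0.08
    high_contrast: float = 0.50

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if not (self.k_high > 0 and self.k_low > 0):
            raise ValueError("logistic slopes must be positive")
        if not (0 < self.low_contrast < self.high_contrast <= 1):
            raise ValueError("need 0 < low_contrast < high_contrast <= 1")
        if self.kappa_ref <= 0:
            raise ValueError("kappa_ref must be positive")

    def slope(self, contrast_level: str) -> float:
        if contrast_level == "high":
            return self.k_high
        if contrast_level == "low":
            return self.k_low
        raise ValueError(f"unknown contrast level {contrast_level!r}")


@dataclass(frozen=True)
class StimulusEvent:
    """One Gabor presentation within a session stream."""

    index: int
    orientation: float          # deg relative to the PSE, CCW positive
    contrast: float             # Michelson, (0, 1]
    duration: float             # seconds
    onset: float                # seconds from session start
    role: str                   # "adaptor" | "test"
    test_type: str = "none"     # "none" | "HC+" | "LC+" | "HC-" | "LC-"
    response: Optional[int] = None  # None | 0 ("blue") | 1 ("orange")

    def __post_init__(self) -> None:
        if self.role not in ("adaptor", "test"):
            raise ValueError(f"bad role {self.role!r}")
        if (self.role == "test") != (self.test_type != "none"):
            raise ValueError("role=test iff test_type != none")
        if self.response is not None and self.role != "test":
            raise ValueError("response allowed only on test events")
        if not 0 < self.contrast <= 1:
            raise ValueError("contrast must lie in (0, 1]")

    @property
    def is_test(self) -> bool:
        return self.role == "test"

    @property
    def contrast_level(self) -> str:
        """'high' or 'low' by test type for tests; by threshold for adaptors."""
        if self.is_test:
            return "high" if self.test_type.startswith("HC") else "low"
        return "high" if self.contrast >= 0.25 else "low"


@dataclass(frozen=True)
class SessionDesign:
    """Counts, offsets and timing of one session.

    Defaults reproduce the published design: 2160 stimuli in three equal
    blocks, a response cue every 12 stimuli plus one at a random position in
    each cycle (360 responses in total), 40 tests per 240-trial span balanced
    over the four test types.
    """

    n_stimuli: int = 2160
    cue_period: int = 12
    responses_per_set: int = 40
    adaptor_sd: float = 3.0
    bimodal_offset: float = 15.0
    test_offset: float = 3.0
    groupB_ratio: float = 3.0
    duration: float = DEFAULT_DURATION
    isi: float = DEFAULT_ISI
    response_pause: float = 1.5

    def __post_init__(self) -> None:
        if self.n_stimuli % 3:
            raise ValueError("n_stimuli must split into three equal blocks")
        if self.responses_per_set % 4:
            raise ValueError("responses_per_set must balance the 4 test types")
        if self.n_stimuli % self.cue_period:
            raise ValueError("n_stimuli must be a multiple of cue_period")
        if self.n_stimuli % self.set_length:
            raise ValueError("n_stimuli must be a multiple of the test-type span")

    @property
    def set_length(self) -> int:
        """Trials per balanced test-type span (240 under the defaults)."""
        return (self.responses_per_set // 2) * self.cue_period

    @property
    def block_boundaries(self) -> Tuple[int, int]:
        third = self.n_stimuli // 3
        return third, 2 * third

    @property
    def n_tests(self) -> int:
        return 2 * self.n_stimuli // self.cue_period

    def block_of(self, index: int) -> int:
        """0-based block (0=i, 1=ii, 2=iii) of a stimulus index."""
        b1, b2 = self.block_boundaries
        return 0 if index < b1 else (1 if index < b2 else 2)


@dataclass(frozen=True)
class SamplingConfig:
    """Ranges for drawing participant profiles (stand-in for the staircase
    phase, which only ever supplies these five numbers).

    The defaults emulate practised observers: high-contrast slopes near
    1 /deg (75%-correct threshold ~1.1 deg), low-contrast slopes near
    0.4 /deg, midpoint jitter ~1 deg, and a reference representation with
    ~2 deg circular spread.  Roughly 3 of 8 participants run the low-contrast
    condition at 10% instead of 8% contrast.
    """

    c0_mean: float = 0.0
    c0_sd: float = 1.0
    k_high_log_mean: float = 0.0      # ln(1.0 /deg)
    k_high_log_sd: float = 0.25
    k_low_log_mean: float = -0.9163   # ln(0.4 /deg)
    k_low_log_sd: float = 0.25
    mu_ref_sd: float = 1.0
    kappa_ref_log_mean: float = 5.3   # ln(200): ~2 deg reference spread
    kappa_ref_log_sd: float = 0.3
    p_low_contrast_10pct: float = 9.0 / 24.0
    high_contrast: float = 0.50


# ---------------------------------------------------------------------------
# participant and session generation
# ---------------------------------------------------------------------------

def sample_participant(
    group: str,
    design: SessionDesign = SessionDesign(),
    seed: int = 0,
    sampling: SamplingConfig = SamplingConfig(),
    participant_id: Optional[str] = None,
) -> ParticipantProfile:
    """Draw one participant profile; deterministic given ``seed``.

    Guarantees ``k_high >= k_low`` (the low-contrast psychometric function is
    never steeper than the high-contrast one).
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    rng = np.random.default_rng(seed)
    c0 = rng.normal(sampling.c0_mean, sampling.c0_sd)
    k_high = float(np.exp(rng.normal(sampling.k_high_log_mean, sampling.k_high_log_sd)))
    k_low = float(np.exp(rng.normal(sampling.k_low_log_mean, sampling.k_low_log_sd)))
    k_low = min(k_low, k_high)
    mu_ref = rng.normal(0.0, sampling.mu_ref_sd)
    kappa_ref = float(np.exp(rng.normal(sampling.kappa_ref_log_mean, sampling.kappa_ref_log_sd)))
    low_contrast = 0.10 if rng.random() < sampling.p_low_contrast_10pct else 0.08
    return ParticipantProfile(
        participant_id=participant_id or f"{group}{seed:04d}",
        group=group,
        c0=float(c0),
        k_high=k_high,
        k_low=k_low,
        mu_ref=float(mu_ref),
        kappa_ref=kappa_ref,
        low_contrast=low_contrast,
        high_contrast=sampling.high_contrast,
    )


def _test_positions(design: SessionDesign, rng: np.random.Generator) -> np.ndarray:
    """Cue positions: the last stimulus of each cycle plus one drawn uniformly
    from the ``cue_period - 1`` positions strictly before it."""
    n_cycles = design.n_stimuli // design.cue_period
    pos = np.empty(2 * n_cycles, dtype=np.int64)
    for k in range(n_cycles):
        base = k * design.cue_period
        pos[2 * k] = base + rng.integers(0, design.cue_period - 1)
        pos[2 * k + 1] = base + design.cue_period - 1
    return pos


def _adaptor_orientation(
    block: int, group: str, design: SessionDesign, c0: float, rng: np.random.Generator
) -> float:
    """Draw one adaptor orientation per the block/group distribution."""
    if block == 0:
        return c0 + rng.normal(0.0, design.adaptor_sd)
    if block == 1 and group == "B":
        p_ccw = design.groupB_ratio / (design.groupB_ratio + 1.0)
    else:
        p_ccw = 0.5
    mode = design.bimodal_offset if rng.random() < p_ccw else -design.bimodal_offset
    return c0 + mode + rng.normal(0.0, design.adaptor_sd)


def generate_session(
    profile: ParticipantProfile,
    design: SessionDesign = SessionDesign(),
    seed: int = 0,
) -> List[StimulusEvent]:
    """Generate one full ordered session for ``profile``.

    Deterministic given ``(profile, design, seed)``.  Test events carry no
    response yet (see :func:`simulate_responses`).  Tests are substituted
    into the stream, so they also act as adaptors for subsequent history.
    """
    rng = np.random.default_rng(seed)
    n = design.n_stimuli
    test_pos = _test_positions(design, rng)

    # balanced randomised test types within every set_length-trial span
    types_per_span = design.responses_per_set // 4
    type_of_pos = {}
    per_span = design.responses_per_set
    for s in range(n // design.set_length):
        labels = np.repeat(np.array(TEST_TYPES, dtype=object), types_per_span)
        rng.shuffle(labels)
        span_positions = test_pos[s * per_span:(s + 1) * per_span]
        for p, lab in zip(span_positions, labels):
            type_of_pos[int(p)] = str(lab)

    events: List[StimulusEvent] = []
    onset = 0.0
    for i in range(n):
        block = design.block_of(i)
        if i in type_of_pos:
            tt = type_of_pos[i]
            orientation = profile.c0 + (design.test_offset if tt.endswith("+") else -design.test_offset)
            contrast = profile.high_contrast if tt.startswith("HC") else profile.low_contrast
            ev = StimulusEvent(i, float(orientation), contrast, design.duration,
                               onset, "test", tt)
        else:
            orientation = _adaptor_orientation(block, profile.group, design, profile.c0, rng)
            contrast = profile.high_contrast
            if profile.group == "C" and block == 1 and orientation < profile.c0:
                contrast = profile.low_contrast
            ev = StimulusEvent(i, float(orientation), contrast, design.duration,
                               onset, "adaptor")
        events.append(ev)
        onset += design.duration + design.isi
        if ev.is_test:
            onset += design.response_pause
    return events


# ---------------------------------------------------------------------------
# response simulation
# ---------------------------------------------------------------------------

class ResponseModel(Protocol):
    """Anything that can assign a P("orange") to each test of a session."""

    def test_probabilities(self, events: Sequence[StimulusEvent]) -> np.ndarray:
        """Return one probability per test event, in stream order."""
        ...


def simulate_responses(
    events: Sequence[StimulusEvent],
    model: ResponseModel,
    seed: int = 0,
) -> List[StimulusEvent]:
    """Fill in Bernoulli responses on the test events of a session.

    Adaptor events are returned unchanged.  Raises if the model produces a
    probability outside [0, 1].
    """
    rng = np.random.default_rng(seed)
    probs = np.asarray(model.test_probabilities(events), dtype=float)
    n_tests = sum(ev.is_test for ev in events)
    if probs.shape != (n_tests,):
        raise ValueError(f"model returned {probs.shape} probabilities for {n_tests} tests")
    if np.any(~np.isfinite(probs)) or np.any(probs < 0) or np.any(probs > 1):
        raise ValueError("model produced probabilities outside [0, 1]")
    out: List[StimulusEvent] = []
    j = 0
    for ev in events:
        if ev.is_test:
            out.append(replace(ev, response=int(rng.random() < probs[j])))
            j += 1
        else:
            out.append(ev)
    return out


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

Cohort = List[Tuple[ParticipantProfile, List[StimulusEvent]]]


def generate_cohort(
    group_sizes: dict | None = None,
    design: SessionDesign = SessionDesign(),
    sampling: SamplingConfig = SamplingConfig(),
    seed: int = 0,
) -> Cohort:
    """Generate profiles and (response-free) sessions for a whole cohort.

    ``group_sizes`` defaults to 8 participants per group (24 total).  Every
    participant gets an independent child seed, so the cohort is
    deterministic given ``seed`` alone.
    """
    group_sizes = group_sizes or {"A": 8, "B": 8, "C": 8}
    root = np.random.default_rng(seed)
    cohort: Cohort = []
    idx = 0
    for group in GROUPS:
        for _ in range(int(group_sizes.get(group, 0))):
            s_prof, s_sess = root.integers(0, 2**31 - 1, size=2)
            profile = sample_participant(
                group, design, int(s_prof), sampling,
                participant_id=f"P{idx:02d}{group}",
            )
            cohort.append((profile, generate_session(profile, design, int(s_sess))))
            idx += 1
    return cohort


def simulate_cohort_responses(cohort: Cohort, model_for, seed: int = 0) -> Cohort:
    """Simulate responses for every session; ``model_for(profile)`` builds the
    per-participant response model."""
    root = np.random.default_rng(seed)
    out: Cohort = []
    for profile, events in cohort:
        s = int(root.integers(0, 2**31 - 1))
        out.append((profile, simulate_responses(events, model_for(profile), s)))
    return out
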