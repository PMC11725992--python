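"""Session CSV / parameter JSON readers and writers, run manifests, and
deterministic test fixtures.

The session dialect is one CSV row per stimulus with columns
``participant_id, group, index, onset_s, orientation_deg, contrast,
duration_s, role, test_type, response`` (UTF-8, header required, empty
``response`` for adaptors and unanswered tests), plus a ``profiles.json``
sidecar holding the participant psychometrics.  Degrees everywhere in files;
double-angle radians are an internal detail of the observer.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .design import (Cohort, ParticipantProfile, SamplingConfig, SessionDesign,
                     StimulusEvent)

logger = logging.getLogger(__name__)

SESSION_COLUMNS = ["participant_id", "group", "index", "onset_s",
                   "orientation_deg", "contrast", "duration_s", "role",
                   "test_type", "response"]
FIXTURE_SCENARIOS = ("toy-20-trials", "groupB-mini", "groupC-mini", "null-model")


def _sig6(x: float) -> float:
    """Round to 6 significant digits (file format for orientations etc.)."""
    return float(f"{x:.6g}")


# ---------------------------------------------------------------------------
# session CSV + profile sidecar
# ---------------------------------------------------------------------------

def cohort_frame(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for profile, events in cohort:
        for ev in events:
            rows.append({
                "participant_id": profile.participant_id,
                "group": profile.group,
                "index": ev.index,
                "onset_s": _sig6(ev.onset),
                "orientation_deg": _sig6(ev.orientation),
                "contrast": _sig6(ev.contrast),
                "duration_s": _sig6(ev.duration),
                "role": ev.role,
                "test_type": ev.test_type,
                "response": "" if ev.response is None else ev.response,
            })
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)


def write_sessions(cohort: Cohort, out_dir: str | Path) -> Tuple[Path, Path]:
    """Write ``sessions.csv`` and ``profiles.json`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "sessions.csv"
    cohort_frame(cohort).to_csv(csv_path, index=False)
    profiles = {p.participant_id: dataclasses.asdict(p) for p, _ in cohort}
    json_path = out / "profiles.json"
    json_path.write_text(json.dumps(profiles, indent=1, sort_keys=True))
    logger.info("wrote %d sessions to %s", len(cohort), out)
    return csv_path, json_path


def read_sessions(path: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_sessions`.

    ``path`` may be the directory or the ``sessions.csv`` file (with
    ``profiles.json`` alongside).  Validates column presence, per-participant
    ordering and strictly increasing onsets, and that responses appear only
    on test rows (errors name the offending row).
    """
    path = Path(path)
    csv_path = path / "sessions.csv" if path.is_dir() else path
    json_path = csv_path.with_name("profiles.json")
    df = pd.read_csv(csv_path, dtype={"response": "Int64"})
    if df.empty:
        warnings.warn(f"{csv_path}: empty session file")
        return []
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{csv_path}: missing columns {missing}")
    profiles_raw = json.loads(json_path.read_text())
    cohort: Cohort = []
    for pid, sub in df.groupby("participant_id", sort=False):
        if pid not in profiles_raw:
            raise ValueError(f"no profile for participant {pid!r}")
        profile = ParticipantProfile(**profiles_raw[pid])
        sub = sub.sort_values("index")
        onsets = sub["onset_s"].to_numpy()
        if np.any(np.diff(onsets) <= 0):
            bad = int(sub.index[np.argmax(np.diff(onsets) <= 0) + 1])
            raise ValueError(f"{csv_path}: non-monotone onset at row {bad}")
        events: List[StimulusEvent] = []
        for row_i, row in sub.iterrows():
            resp = None if pd.isna(row["response"]) else int(row["response"])
            if resp is not None and row["role"] != "test":
                raise ValueError(f"{csv_path}: response on adaptor row {row_i}")
            events.append(StimulusEvent(
                index=int(row["index"]), orientation=float(row["orientation_deg"]),
                contrast=float(row["contrast"]), duration=float(row["duration_s"]),
                onset=float(row["onset_s"]), role=str(row["role"]),
                test_type=str(row["test_type"]), response=resp))
        cohort.append((profile, events))
    return cohort


# ---------------------------------------------------------------------------
# configs, parameter files, manifests
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    cfg = json.loads(Path(path).read_text())
    cfg.setdefault("design", {})
    cfg.setdefault("cohort", {"A": 8, "B": 8, "C": 8})
    cfg.setdefault("sampling", {})
    return cfg


def design_from_config(cfg: dict) -> SessionDesign:
    return SessionDesign(**cfg.get("design", {}))


def sampling_from_config(cfg: dict) -> SamplingConfig:
    return SamplingConfig(**cfg.get("sampling", {}))


def write_linear_params(result, path: str | Path) -> None:
    """Serialise a linear fit: component arrays, gamma, nll, bookkeeping."""
    p = result.params
    payload = {
        "components_high": [{"w": c.w, "m": c.m} for c in p.components_high],
        "components_low": [{"w": c.w, "m": c.m} for c in p.components_low],
        "gamma": p.gamma, "nll": result.nll, "n_params": result.n_params,
        "converged": result.converged,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_linear_params(path: str | Path):
    from .linear import LinearComponent, LinearParams
    d = json.loads(Path(path).read_text())
    return LinearParams(
        tuple(LinearComponent(c["w"], c["m"]) for c in d["components_high"]),
        tuple(LinearComponent(c["w"], c["m"]) for c in d["components_low"]),
        d["gamma"])


@dataclasses.dataclass
class RunManifest:
    """Provenance record written next to every CLI output."""

    command: str
    config_hash: str
    seed: Optional[int]
    version: str = __version__
    elapsed_s: float = 0.0
    outputs: List[str] = dataclasses.field(default_factory=list)

    @staticmethod
    def hash_config(obj) -> str:
        blob = json.dumps(obj, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def _toy_profile(group: str = "A", c0: float = 0.0) -> ParticipantProfile:
    return ParticipantProfile(participant_id=f"toy{group}", group=group, c0=c0,
                              k_high=1.0, k_low=0.4, mu_ref=0.0, kappa_ref=200.0)


def _toy_events(rng: np.random.Generator, n: int = 20, cue: int = 5,
                test_offset: float = 3.0, c0: float = 0.0,
                with_responses: bool = True) -> List[StimulusEvent]:
    """Small hand-rolled stream: a test at the end of every ``cue`` stimuli."""
    events = []
    onset = 0.0
    for i in range(n):
        if (i + 1) % cue == 0:
            tt = ["HC+", "LC+", "HC-", "LC-"][((i + 1) // cue - 1) % 4]
            orientation = c0 + (test_offset if tt.endswith("+") else -test_offset)
            contrast = 0.5 if tt.startswith("HC") else 0.08
            resp = int(rng.random() < 0.5) if with_responses else None
            events.append(StimulusEvent(i, orientation, contrast, 0.3, onset,
                                        "test", tt, resp))
            onset += 1.2 + 1.5
        else:
            events.append(StimulusEvent(i, float(rng.normal(c0, 3.0)), 0.5,
                                        0.3, onset, "adaptor"))
            onset += 1.2
    return events


def make_fixture(name: str, seed: int = 0) -> Tuple[Cohort, Dict]:
    """Deterministic small cohorts with closed-form expected values.

    Scenarios: ``toy-20-trials`` (20 events, 4 tests), ``groupB-mini`` /
    ``groupC-mini`` (720-stimulus single sessions), ``null-model`` (tests at
    the midpoint with coin-flip responses; a zero-weight linear model has
    NLL exactly R*ln 2).
    """
    from .design import generate_session, sample_participant
    rng = np.random.default_rng(seed)
    if name == "toy-20-trials":
        profile = _toy_profile()
        events = _toy_events(rng)
        expected = {"n_events": 20, "n_tests": 4}
        return [(profile, events)], expected
    if name in ("groupB-mini", "groupC-mini"):
        group = "B" if name == "groupB-mini" else "C"
        design = SessionDesign(n_stimuli=720)
        profile = sample_participant(group, design, seed)
        events = generate_session(profile, design, seed + 1)
        expected = {"n_events": 720, "n_tests": 120}
        return [(profile, events)], expected
    if name == "null-model":
        profile = _toy_profile()
        events = _toy_events(rng, test_offset=0.0)
        n_tests = sum(ev.is_test for ev in events)
        expected = {"n_tests": n_tests,
                    "nll_zero_weights": n_tests * float(np.log(2.0))}
        return [(profile, events)], expected
    raise ValueError(f"unknown fixture scenario {name!r}; "
                     f"have {FIXTURE_SCENARIOS}")
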