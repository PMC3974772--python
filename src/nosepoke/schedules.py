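"""Assay schedules: session sequences and operant trial sequences.

Habituation-family assays present a series of one-minute stimulus windows
(air or odor) at a fixed onset-to-onset spacing of four minutes; the long
inter-stimulus gap keeps peripheral sensory adaptation from accumulating.
Operant assays (two-choice, go/no-go) instead present a pseudorandom trial
sequence with balanced odor counts and a bounded run length so no block of
same-side trials can be solved positionally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusSession",
    "AssaySchedule",
    "Trial",
    "TrialSequence",
    "build_cross_habituation",
    "build_threshold_series",
    "build_two_choice_session",
    "build_gonogo_session",
    "DEFAULT_STIM_DURATION_MS",
    "DEFAULT_INTER_ONSET_MS",
]

DEFAULT_STIM_DURATION_MS = 60_000  # one-minute stimulus window
DEFAULT_INTER_ONSET_MS = 240_000  # four-minute onset-to-onset spacing
AIR = "air"


@dataclass(frozen=True)
class StimulusSession:
    """One stimulus presentation window within an assay."""

    stimulus: str  # "air"/"MO" or odor name
    concentration_sv: float  # saturated-vapor fraction; 0 for air/solvent
    onset_ms: int
    duration_ms: int = DEFAULT_STIM_DURATION_MS
    index: int = 0

    def __post_init__(self):
        if self.duration_ms <= 0:
            raise ValueError(f"duration_ms must be > 0, got {self.duration_ms}")
        if self.concentration_sv < 0:
            raise ValueError(f"concentration_sv must be >= 0, got {self.concentration_sv}")

    @property
    def offset_ms(self) -> int:
        return self.onset_ms + self.duration_ms

    @property
    def window(self) -> tuple[int, int]:
        return (self.onset_ms, self.offset_ms)


@dataclass
class AssaySchedule:
    """An ordered, non-overlapping sequence of stimulus sessions."""

    sessions: list[StimulusSession]
    paradigm: str = "custom"
    inter_onset_ms: int = DEFAULT_INTER_ONSET_MS

    def __post_init__(self):
        for prev, cur in zip(self.sessions, self.sessions[1:]):
            if cur.onset_ms <= prev.onset_ms:
                raise ValueError("session onsets must be strictly increasing")
            if cur.onset_ms < prev.offset_ms:
                raise ValueError(
                    f"sessions overlap: {prev.stimulus}@{prev.onset_ms} runs to "
                    f"{prev.offset_ms} but {cur.stimulus} starts at {cur.onset_ms}"
                )

    def __len__(self) -> int:
        return len(self.sessions)

    def __iter__(self):
        return iter(self.sessions)

    @property
    def end_ms(self) -> int:
        return self.sessions[-1].offset_ms if self.sessions else 0

    def baseline_sessions(self) -> list[StimulusSession]:
        """Background (zero-concentration) sessions used for basal activity."""
        return [s for s in self.sessions if s.concentration_sv == 0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "paradigm": self.paradigm,
                "inter_onset_ms": self.inter_onset_ms,
                "sessions": [
                    {
                        "stimulus": s.stimulus,
                        "concentration_sv": s.concentration_sv,
                        "onset_ms": s.onset_ms,
                        "duration_ms": s.duration_ms,
                        "index": s.index,
                    }
                    for s in self.sessions
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "AssaySchedule":
        d = json.loads(text)
        return cls(
            sessions=[StimulusSession(**s) for s in d["sessions"]],
            paradigm=d.get("paradigm", "custom"),
            inter_onset_ms=d.get("inter_onset_ms", DEFAULT_INTER_ONSET_MS),
        )


def _sessions_from_blocks(
    blocks: list[tuple[str, float, int]],
    duration_ms: int,
    inter_onset_ms: int,
) -> list[StimulusSession]:
    """Expand (stimulus, concentration, count) blocks into timed sessions."""
    sessions = []
    idx = 0
    for stimulus, conc, count in blocks:
        for _ in range(count):
            sessions.append(
                StimulusSession(
                    stimulus=stimulus,
                    concentration_sv=conc,
                    onset_ms=idx * inter_onset_ms,
                    duration_ms=duration_ms,
                    index=idx,
                )
            )
            idx += 1
    return sessions


def build_cross_habituation(
    s1: str,
    s2: str | None = None,
    n_air: int = 8,
    n_s1: int = 5,
    n_s2: int = 5,
    conc_s1: float = 2.5e-4,
    conc_s2: float = 2.5e-4,
    duration_ms: int = DEFAULT_STIM_DURATION_MS,
    inter_onset_ms: int = DEFAULT_INTER_ONSET_MS,
) -> AssaySchedule:
    """Cross-habituation assay: an air block, then repeated S1, then S2.

    The default concentration corresponds to a 1:1000 liquid dilution
    delivered at 100/400 ml/min (2.5e-4 s.v.).  ``s2=None`` builds the
    plain habituation/dis-habituation variant (air then S1 only).
    """
    if n_air < 0 or n_s1 < 1 or (s2 is not None and n_s2 < 1):
        raise ValueError("need n_air >= 0 and at least one session per odor block")
    blocks = [(AIR, 0.0, n_air), (s1, conc_s1, n_s1)]
    if s2 is not None:
        blocks.append((s2, conc_s2, n_s2))
    return AssaySchedule(
        sessions=_sessions_from_blocks(blocks, duration_ms, inter_onset_ms),
        paradigm="cross_habituation",
        inter_onset_ms=inter_onset_ms,
    )


def build_threshold_series(
    odor: str,
    concentrations: list[float],
    n_air: int = 8,
    reps_per_conc: int = 1,
    duration_ms: int = DEFAULT_STIM_DURATION_MS,
    inter_onset_ms: int = DEFAULT_INTER_ONSET_MS,
) -> AssaySchedule:
    """Detection-threshold series: air block, then ascending concentration blocks."""
    concentrations = list(concentrations)
    if any(c <= 0 for c in concentrations):
        raise ValueError("concentrations must be > 0")
    if any(b <= a for a, b in zip(concentrations, concentrations[1:])):
        raise ValueError("concentrations must be strictly increasing")
    if reps_per_conc < 1:
        raise ValueError("reps_per_conc must be >= 1")
    blocks = [(AIR, 0.0, n_air)] + [(odor, c, reps_per_conc) for c in concentrations]
    return AssaySchedule(
        sessions=_sessions_from_blocks(blocks, duration_ms, inter_onset_ms),
        paradigm="threshold",
        inter_onset_ms=inter_onset_ms,
    )


@dataclass(frozen=True)
class Trial:
    """One operant trial: the odor presented and the correct response."""

    odor: str
    correct_response: str  # "L" | "R" (two-choice) or "go" | "no_go"


@dataclass
class TrialSequence:
    """A pseudorandom operant trial sequence with balanced odor counts."""

    trials: list[Trial]
    reward_volume_ul: float = 5.0
    paradigm: str = "two_choice"

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.trials:
            out[t.odor] = out.get(t.odor, 0) + 1
        return out

    def max_run(self) -> int:
        longest = run = 0
        prev = None
        for t in self.trials:
            run = run + 1 if t.odor == prev else 1
            prev = t.odor
            longest = max(longest, run)
        return longest

    def to_json(self) -> str:
        return json.dumps(
            {
                "paradigm": self.paradigm,
                "reward_volume_ul": self.reward_volume_ul,
                "trials": [
                    {"odor": t.odor, "correct_response": t.correct_response}
                    for t in self.trials
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "TrialSequence":
        d = json.loads(text)
        return cls(
            trials=[Trial(**t) for t in d["trials"]],
            reward_volume_ul=d.get("reward_volume_ul", 5.0),
            paradigm=d.get("paradigm", "two_choice"),
        )


def _balanced_order(
    odor_a: str, odor_b: str, n_per_odor: int, seed, max_run: int
) -> list[str]:
    """Random balanced order with no run longer than ``max_run`` (rejection sampling)."""
    rng = np.random.default_rng(seed)
    arr = np.array([odor_a] * n_per_odor + [odor_b] * n_per_odor)
    if n_per_odor <= max_run:
        rng.shuffle(arr)
        return list(arr)
    for _ in range(100_000):
        rng.shuffle(arr)
        longest = run = 1
        for i in range(1, len(arr)):
            run = run + 1 if arr[i] == arr[i - 1] else 1
            longest = max(longest, run)
        if longest <= max_run:
            return list(arr)
    raise RuntimeError("could not satisfy the maximum-run constraint")  # pragma: no cover


def build_two_choice_session(
    odor_a: str,
    odor_b: str,
    n_per_odor: int = 30,
    seed=None,
    max_run: int = 3,
    reward_volume_ul: float = 5.0,
) -> TrialSequence:
    """Two-choice session: ``odor_a`` maps to the left port, ``odor_b`` to the right."""
    if n_per_odor < 1:
        raise ValueError("n_per_odor must be >= 1")
    order = _balanced_order(odor_a, odor_b, n_per_odor, seed, max_run)
    trials = [Trial(o, "L" if o == odor_a else "R") for o in order]
    return TrialSequence(trials, reward_volume_ul, paradigm="two_choice")


def build_gonogo_session(
    cs_plus: str,
    cs_minus: str,
    n_per_odor: int = 30,
    seed=None,
    max_run: int = 3,
    reward_volume_ul: float = 5.0,
) -> TrialSequence:
    """Go/no-go session: licking after CS+ is rewarded, after CS- is not."""
    if n_per_odor < 1:
        raise ValueError("n_per_odor must be >= 1")
    order = _balanced_order(cs_plus, cs_minus, n_per_odor, seed, max_run)
    trials = [Trial(o, "go" if o == cs_plus else "no_go") for o in order]
    return TrialSequence(trials, reward_volume_ul, paradigm="gonogo")
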