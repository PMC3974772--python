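"""Behavioral statistics computed from event logs and assay schedules.

The central quantity is per-session *investigation*: total nose-poke time
inside a stimulus window.  Because animals differ widely in baseline port
seeking, each session is normalized to the animal's own basal activity
(mean investigation across the background air/solvent sessions), giving
the normalized port investigation

    NPI = 100 x investigation / basal        [percent]

so the mean NPI over the background block is 100% by construction.  The
successive difference dNPI = NPI[i] - NPI[i-1] measures dis-habituation:
~0 for a repeated, habituated stimulus, positive when a perceptibly novel
stimulus restores investigation.  On top of these the module provides
operant success rates, innate-preference indices, and a just-noticeable-
difference style detection threshold from a concentration series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnimalExcludedError, MetricUndefinedError
from .events import EventInterval, EventLog, pair_events
from .schedules import AssaySchedule

__all__ = [
    "SessionMetrics",
    "ChoiceCounts",
    "GoNoGoCounts",
    "PreferenceIndices",
    "investigation_duration",
    "basal_activity",
    "npi",
    "delta_npi",
    "compute_session_metrics",
    "session_metrics_frame",
    "write_metrics_table",
    "success_rate_two_choice",
    "success_rate_gonogo",
    "attraction_index",
    "aversion_index",
    "three_chamber_indices",
    "jnd_threshold",
    "POKE_LOCATION",
]

#: Device channel registering odor-port nose pokes.
POKE_LOCATION = "odor_port_ir"


@dataclass
class SessionMetrics:
    """Per-session investigation and normalized scores."""

    session_index: int
    stimulus: str
    concentration_sv: float
    investigation_ms: float
    npi_percent: float
    delta_npi_percent: float | None  # None for the first session


@dataclass(frozen=True)
class ChoiceCounts:
    """Two-choice poke counts: correct pokes per odor and total pokes."""

    p_aa: int  # pokes into port A upon odor A
    p_bb: int  # pokes into port B upon odor B
    p_total: int  # all water-port pokes

    def __post_init__(self):
        if min(self.p_aa, self.p_bb, self.p_total) < 0:
            raise ValueError("counts must be >= 0")
        if self.p_aa + self.p_bb > self.p_total:
            raise ValueError("correct pokes exceed total pokes")


@dataclass(frozen=True)
class GoNoGoCounts:
    """Go/no-go lick counts for CS+ and CS- trials."""

    p_cs_plus: int  # licks on CS+ (hits)
    np_cs_plus: int  # no-licks on CS+ (misses)
    p_cs_minus: int  # licks on CS- (false alarms)
    np_cs_minus: int  # no-licks on CS- (correct rejections)

    def __post_init__(self):
        if min(self.p_cs_plus, self.np_cs_plus, self.p_cs_minus, self.np_cs_minus) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def n_trials(self) -> int:
        return self.p_cs_plus + self.np_cs_plus + self.p_cs_minus + self.np_cs_minus


@dataclass(frozen=True)
class PreferenceIndices:
    """Innate-preference readouts; both are positive-going effect sizes."""

    attraction: float
    aversion: float


def investigation_duration(
    pokes: Sequence[EventInterval], window: tuple[int, int]
) -> int:
    """Total poke time (ms) inside a half-open window [onset, offset).

    Pokes straddling the window edges contribute only their overlap.
    """
    onset, offset = window
    if offset < onset:
        raise ValueError(f"invalid window {window}")
    total = 0
    for p in pokes:
        total += max(0, min(p.end_ms, offset) - max(p.start_ms, onset))
    return total


def basal_activity(air_session_durations: Sequence[float]) -> float:
    """Mean investigation over the background (air/solvent) sessions."""
    if len(air_session_durations) == 0:
        raise ValueError("basal activity requires at least one background session")
    return float(np.mean(air_session_durations))


def npi(duration_ms: float, basal_ms: float) -> float:
    """Normalized port investigation (percent of basal activity)."""
    if basal_ms <= 0:
        raise AnimalExcludedError(
            "animal never investigated during background sessions; NPI undefined"
        )
    return 100.0 * duration_ms / basal_ms


def delta_npi(npi_sequence: Sequence[float]) -> np.ndarray:
    """Successive NPI differences: dNPI[i] = NPI[i+1] - NPI[i]."""
    if len(npi_sequence) < 2:
        raise ValueError("dNPI requires at least 2 sessions")
    return np.diff(np.asarray(npi_sequence, dtype=float))


def compute_session_metrics(
    log: EventLog,
    schedule: AssaySchedule,
    poke_location: str = POKE_LOCATION,
    basal_last_k: int | None = None,
) -> list[SessionMetrics]:
    """Per-session investigation, NPI and dNPI for one animal.

    Basal activity is the mean over all zero-concentration sessions;
    ``basal_last_k`` restricts it to the last *k* of them.
    """
    pokes = pair_events(log, poke_location).intervals
    durations = [investigation_duration(pokes, s.window) for s in schedule]
    baseline_idx = [i for i, s in enumerate(schedule) if s.concentration_sv == 0]
    if not baseline_idx:
        raise ValueError("schedule has no background (zero-concentration) sessions")
    if basal_last_k is not None:
        baseline_idx = baseline_idx[-basal_last_k:]
    basal = basal_activity([durations[i] for i in baseline_idx])
    npis = [npi(d, basal) for d in durations]
    out = []
    for i, s in enumerate(schedule):
        out.append(
            SessionMetrics(
                session_index=s.index,
                stimulus=s.stimulus,
                concentration_sv=s.concentration_sv,
                investigation_ms=durations[i],
                npi_percent=npis[i],
                delta_npi_percent=None if i == 0 else npis[i] - npis[i - 1],
            )
        )
    return out


def session_metrics_frame(metrics: list[SessionMetrics]) -> pd.DataFrame:
    """Session metrics as a tidy table."""
    return pd.DataFrame(
        {
            "session_index": [m.session_index for m in metrics],
            "stimulus": [m.stimulus for m in metrics],
            "concentration_sv": [m.concentration_sv for m in metrics],
            "investigation_ms": [m.investigation_ms for m in metrics],
            "npi_percent": [m.npi_percent for m in metrics],
            "delta_npi_percent": [m.delta_npi_percent for m in metrics],
        }
    )


def write_metrics_table(metrics: list[SessionMetrics], path) -> None:
    """Write the per-animal metrics table as TSV."""
    session_metrics_frame(metrics).to_csv(path, sep="\t", index=False)


def success_rate_two_choice(c: ChoiceCounts) -> float:
    """SR = (P_AA + P_BB) / P_total; chance is 0.5 with balanced odors."""
    if c.p_total == 0:
        raise MetricUndefinedError("success rate undefined with zero pokes")
    return (c.p_aa + c.p_bb) / c.p_total


def success_rate_gonogo(c: GoNoGoCounts) -> float:
    """SR = (hits + correct rejections) / all trials; chance is 0.5."""
    if c.n_trials == 0:
        raise MetricUndefinedError("success rate undefined with zero trials")
    return (c.p_cs_plus + c.np_cs_minus) / c.n_trials


def attraction_index(
    npi_series: Sequence[float], first_odor_session_idx: int
) -> float:
    """NPI of the first odor session minus NPI of the last solvent session.

    Positive when the first odor presentation drives investigation above
    the solvent baseline (innate attraction).
    """
    if first_odor_session_idx < 1:
        raise ValueError("at least one solvent session must precede the odor block")
    series = list(npi_series)
    return series[first_odor_session_idx] - series[first_odor_session_idx - 1]


def aversion_index(
    npi_series: Sequence[float], second_odor_session_idx: int
) -> float:
    """NPI of the last solvent session minus NPI of the second odor session.

    Aversion shows from the second odor presentation onward, when the
    animal suppresses port approach below its solvent baseline; the sign
    convention makes stronger aversion more positive.
    """
    if second_odor_session_idx < 2:
        raise ValueError("need a solvent session and >= 2 odor sessions")
    series = list(npi_series)
    return series[second_odor_session_idx - 2] - series[second_odor_session_idx]


def three_chamber_indices(
    time_test_zone_s: float, time_control_zone_s: float
) -> PreferenceIndices:
    """Zone-time preference indices for a classic three-chamber arena.

    attraction = (test - control) / control, aversion its negative.  An
    animal that never entered the control zone cannot be normalized.
    """
    if time_control_zone_s <= 0:
        raise AnimalExcludedError(
            "animal spent no time in the control chamber; ratio undefined"
        )
    attraction = (time_test_zone_s - time_control_zone_s) / time_control_zone_s
    return PreferenceIndices(attraction=attraction, aversion=-attraction)


def _one_sample_p(column: np.ndarray) -> float:
    """Paired-t p-value of a dNPI column against 0, with degenerate handling."""
    if np.ptp(column) == 0:
        return 1.0 if column[0] == 0 else 0.0
    return float(stats.ttest_1samp(column, popmean=0.0).pvalue)


def jnd_threshold(
    delta_npi_matrix,
    concentrations: Sequence[float],
    alpha: float = 0.05,
    correction: str = "holm",
) -> float | None:
    """Just-noticeable-difference style threshold from a concentration series.

    ``delta_npi_matrix`` is (animals x concentrations): each column holds
    the across-animal dis-habituation scores (odor-probe NPI minus the
    preceding session's NPI) at one concentration.  Each column is tested
    against 0 with a paired t-test; ``correction`` ("holm" or "none")
    controls the familywise error over the concentration series.  Returns
    the smallest concentration significant at ``alpha``, or None.
    """
    m = np.asarray(delta_npi_matrix, dtype=float)
    concentrations = np.asarray(concentrations, dtype=float)
    if m.ndim != 2 or m.shape[1] != len(concentrations):
        raise ValueError("matrix must be (n_animals, n_concentrations)")
    if m.shape[0] < 2:
        raise ValueError("need at least 2 animals for a paired t-test")
    if np.any(np.diff(concentrations) <= 0):
        raise ValueError("concentrations must be strictly ascending")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    pvals = np.array([_one_sample_p(m[:, j]) for j in range(m.shape[1])])
    if correction == "holm":
        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    elif correction == "none":
        reject = pvals <= alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    hits = np.nonzero(reject)[0]
    return float(concentrations[hits[0]]) if hits.size else None
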