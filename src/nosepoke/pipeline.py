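"""End-to-end analysis pipelines: cohort tables, dis-habituation matrices,
and detection-threshold estimation.

The detection-threshold pipeline mirrors the bench workflow: habituate to
air, probe an ascending concentration series, score each probe's
dis-habituation, and fit a Weibull psychometric (floor g = 0) whose ``a``
parameter is the threshold.  Two dis-habituation scores serve two jobs:

* the psychometric *fit* scores each probe against the animal's
  *habituated* air floor (mean NPI over the last air sessions, where the
  chamber-novelty transient has decayed), so an undetected probe scores 0
  and the g = 0 floor of the Weibull is honest; each concentration's
  across-animal mean is weighted by its standard error, so animals whose
  basal happened to be poorly estimated cannot steer the curve;
* the *JND* t-tests use the successive difference NPI[i] - NPI[i-1],
  which is exactly mean-zero for an undetected stimulus and therefore the
  correct paired statistic for significance testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import EventLog
from .metrics import (
    compute_session_metrics,
    jnd_threshold,
    session_metrics_frame,
    success_rate_gonogo,
)
from .psychometrics import PsychometricFit, fit_psychometric
from .schedules import AssaySchedule, build_gonogo_session, build_threshold_series
from .simulate import VirtualMouseParams, simulate_cohort, simulate_gonogo

__all__ = [
    "analyze_cohort",
    "probe_delta_npi_matrix",
    "ThresholdEstimate",
    "estimate_detection_threshold",
    "run_threshold_experiment",
    "run_gonogo_threshold_experiment",
]


def analyze_cohort(
    logs: list[EventLog], schedule: AssaySchedule, **metrics_kwargs
) -> pd.DataFrame:
    """Per-session metrics for every animal, stacked in one tidy table."""
    frames = []
    for i, log in enumerate(logs):
        df = session_metrics_frame(compute_session_metrics(log, schedule, **metrics_kwargs))
        df.insert(0, "animal", log.meta.get("animal", f"animal{i:03d}"))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def probe_delta_npi_matrix(
    logs: list[EventLog],
    schedule: AssaySchedule,
    comparator: str = "previous",
    n_floor_sessions: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Dis-habituation scores at each concentration, per animal.

    For each concentration in a threshold schedule the *probe* is its
    first session.  The score compares the probe's NPI against

    * ``"previous"`` — the immediately preceding session's NPI (the
      classic successive difference);
    * ``"air_floor"`` — the mean NPI over the last ``n_floor_sessions``
      air sessions, i.e. the habituated background level;
    * ``"baseline"`` — the 100% normalization constant.

    Returns ``(matrix with shape (n_animals, n_concentrations),
    ascending concentrations)``.
    """
    if comparator not in ("previous", "air_floor", "baseline"):
        raise ValueError(f"unknown comparator {comparator!r}")
    sessions = list(schedule)
    concs: list[float] = []
    probe_idx: list[int] = []
    air_idx = [i for i, s in enumerate(sessions) if s.concentration_sv == 0]
    for i, s in enumerate(sessions):
        if s.concentration_sv > 0 and s.concentration_sv not in concs:
            concs.append(s.concentration_sv)
            probe_idx.append(i)
    if any(b <= a for a, b in zip(concs, concs[1:])):
        raise ValueError("schedule concentrations must ascend for a threshold series")
    rows = []
    for log in logs:
        npis = [m.npi_percent for m in compute_session_metrics(log, schedule)]
        if comparator == "previous":
            rows.append([npis[i] - npis[i - 1] for i in probe_idx])
        elif comparator == "air_floor":
            floor = float(np.mean([npis[i] for i in air_idx[-n_floor_sessions:]]))
            rows.append([npis[i] - floor for i in probe_idx])
        else:
            rows.append([npis[i] - 100.0 for i in probe_idx])
    return np.asarray(rows, dtype=float), np.asarray(concs, dtype=float)


@dataclass
class ThresholdEstimate:
    """Cohort-level detection-threshold readout."""

    fit: PsychometricFit
    jnd_concentration: float | None
    mean_delta_npi: np.ndarray
    concentrations: np.ndarray
    n_animals: int

    @property
    def threshold(self) -> float:
        return self.fit.threshold


def estimate_detection_threshold(
    logs: list[EventLog],
    schedule: AssaySchedule,
    g_fixed: float = 0.0,
    fit_comparator: str = "air_floor",
    jnd_comparator: str = "previous",
    alpha: float = 0.05,
) -> ThresholdEstimate:
    """Full habituation/dis-habituation threshold analysis for a cohort."""
    matrix, concs = probe_delta_npi_matrix(logs, schedule, comparator=fit_comparator)
    mean_dnpi = matrix.mean(axis=0)
    if matrix.shape[0] >= 2:
        sem = matrix.std(axis=0, ddof=1) / np.sqrt(matrix.shape[0])
    else:
        sem = None
    fit = fit_psychometric(concs, mean_dnpi, g_fixed=g_fixed, sigma=sem)
    if matrix.shape[0] >= 2:
        jnd_matrix, _ = probe_delta_npi_matrix(logs, schedule, comparator=jnd_comparator)
        jnd = jnd_threshold(jnd_matrix, concs, alpha=alpha)
    else:
        jnd = None
    return ThresholdEstimate(
        fit=fit,
        jnd_concentration=jnd,
        mean_delta_npi=mean_dnpi,
        concentrations=concs,
        n_animals=matrix.shape[0],
    )


def run_threshold_experiment(
    n_animals: int = 12,
    concentrations=None,
    base_params: VirtualMouseParams | None = None,
    odor: str = "AA",
    reps_per_conc: int = 1,
    seed: int | None = None,
    alpha: float = 0.05,
) -> ThresholdEstimate:
    """Simulate a threshold cohort and analyze it end to end.

    Defaults probe 7 log-spaced concentrations at 0.4-decade steps
    centered on the virtual mouse's ground-truth threshold — the standard
    psychophysical design of concentrating probes around the expected
    threshold, where they carry information about it.
    """
    base_params = base_params or VirtualMouseParams()
    if concentrations is None:
        a_star = base_params.detect.a
        concentrations = a_star * np.logspace(-1.2, 1.2, 7)
    schedule = build_threshold_series(odor, list(concentrations), reps_per_conc=reps_per_conc)
    logs = simulate_cohort(n_animals, schedule, base_params=base_params, seed=seed)
    return estimate_detection_threshold(logs, schedule, g_fixed=0.0, alpha=alpha)


def run_gonogo_threshold_experiment(
    n_animals: int = 12,
    concentrations=None,
    base_params: VirtualMouseParams | None = None,
    cs_plus: str = "AA",
    cs_minus: str = "MO",
    n_per_odor: int = 30,
    n_training_trials: int = 300,
    seed: int | None = None,
) -> PsychometricFit:
    """Trained go/no-go agents tested across concentrations; Weibull fit (g=0.5).

    Each animal runs one session per concentration starting
    ``n_training_trials`` deep into its learning curve; the mean success
    rate across animals at each concentration is fit with the chance
    floor fixed at 50%.
    """
    base_params = base_params or VirtualMouseParams()
    if concentrations is None:
        a_star = base_params.detect.a
        concentrations = a_star * np.logspace(-1.2, 1.2, 7)
    concentrations = np.asarray(list(concentrations), dtype=float)
    children = np.random.SeedSequence(seed).spawn(n_animals)
    sr = np.zeros((n_animals, len(concentrations)))
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        for j, c in enumerate(concentrations):
            trials = build_gonogo_session(
                cs_plus, cs_minus, n_per_odor=n_per_odor, seed=rng.integers(2**31)
            )
            counts = simulate_gonogo(
                base_params, trials, c, rng=rng, n_prior_trials=n_training_trials
            )
            sr[i, j] = success_rate_gonogo(counts)
    return fit_psychometric(concentrations, sr.mean(axis=0), g_fixed=0.5)
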