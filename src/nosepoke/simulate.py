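"""Virtual mouse: a generative model of odor-port behavior.

The simulator emits event logs with the statistical structure the analysis
pipeline assumes, so every metric can be validated end-to-end against a
known ground truth without animals.

Investigation is modelled as a session-level Poisson bout process.  During
a stimulus session the animal emits nose-poke bouts at rate (bouts/min)

    lambda = lambda_base * (1 + eta * (nu_chamber + nu_stim)) * aversion

* ``nu_chamber`` is the novelty of the port/chamber itself: 1 on the first
  session and decaying by ``rho`` each session, which produces the
  characteristic habituation of the initial air block.
* ``nu_stim`` is stimulus-bound novelty.  On the first exposure to a
  stimulus it equals ``p_detect(c) * D(new, habituated)`` — the ground-
  truth detection probability (a Weibull psychometric with threshold
  ``a``) times the perceptual distinctness ``D`` from the stimulus the
  animal last habituated to (0 = indistinguishable, so habituation
  transfers fully and no dis-habituation occurs).  It decays by ``rho``
  on each repeat; dis-habituation is therefore exactly what the dNPI
  analysis reads out.
* Valence modulates the response: the first exposure to a valenced odor is
  amplified by (1 + |v|); from the second exposure on an aversive odor
  (v < 0) multiplies the whole rate by (1 + v), suppressing investigation
  below baseline (the animal avoids the port).

Bout durations are exponential; all times are written at 1-ms resolution.
Distinct concentrations of one odor are treated as distinct stimuli
(steps in a threshold series are a decade apart, well above intensity
discrimination limits).

Operant behavior uses a saturating learning curve: trial-t accuracy
``acc_t = 0.5 + (asymptote - 0.5)(1 - exp(-t/tau))``, degraded toward
chance by detectability, ``p_correct = 0.5 + (acc_t - 0.5) p_detect(c)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .events import Event, EventLog
from .metrics import POKE_LOCATION, ChoiceCounts, GoNoGoCounts
from .psychometrics import PsychometricParams, weibull
from .schedules import AssaySchedule, TrialSequence

__all__ = [
    "VirtualMouseParams",
    "simulate_habituation_assay",
    "simulate_two_choice",
    "simulate_gonogo",
    "simulate_cohort",
    "default_params_sampler",
]

ODOR_VALVE_LOCATION = "odor_valve_1"
TTL_LOCATION = "ttl_out"


def _default_detect() -> PsychometricParams:
    return PsychometricParams(A=1.0, b=1.5, a=2e-6, g=0.0)


@dataclass
class VirtualMouseParams:
    """Generative parameters of one synthetic animal.

    Rates and durations are plausibility defaults for a mouse freely
    investigating an odor port; they are configuration, not claims about
    any particular animal.
    """

    lambda_base: float = 4.0  # poke bouts/min at baseline
    bout_mean_ms: float = 800.0  # mean bout duration
    rho: float = 0.3  # per-session habituation multiplier in (0, 1]
    eta: float = 3.0  # novelty gain (>= 0)
    detect: PsychometricParams = field(default_factory=_default_detect)
    valence: dict[str, float] = field(default_factory=dict)  # odor -> v in [-1, 1]
    similarity: dict[frozenset, float] = field(default_factory=dict)  # {o1,o2} -> D
    learn_tau: float = 30.0  # trials to ~63% of asymptotic learning
    learn_asymptote: float = 0.95  # asymptotic operant accuracy in (0.5, 1]
    seed: int | None = None

    def __post_init__(self):
        if self.lambda_base <= 0 or self.bout_mean_ms <= 0:
            raise ValueError("rates and durations must be > 0")
        if not 0 < self.rho <= 1:
            raise ValueError(f"rho must be in (0, 1], got {self.rho}")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        for o, v in self.valence.items():
            if not -1 <= v <= 1:
                raise ValueError(f"valence[{o!r}] must be in [-1, 1], got {v}")
        for pair, d in self.similarity.items():
            if not 0 <= d <= 1:
                raise ValueError(f"similarity D must be in [0, 1], got {d}")
        if not 0.5 < self.learn_asymptote <= 1:
            raise ValueError("learn_asymptote must be in (0.5, 1]")
        if self.learn_tau <= 0:
            raise ValueError("learn_tau must be > 0")

    def distinctness(self, stim_a: str, stim_b: str | None) -> float:
        """Perceptual distinctness D between two odor names (1 = fully novel)."""
        if stim_b is None:
            return 1.0
        if stim_a == stim_b:
            return 0.0
        return self.similarity.get(frozenset((stim_a, stim_b)), 1.0)

    def key_distinctness(
        self, key_a: tuple[str, float], key_b: tuple[str, float] | None
    ) -> float:
        """Distinctness between (stimulus, concentration) pairs.

        Same odor at different concentrations counts as fully distinct:
        threshold-series steps are a decade apart, far beyond intensity
        discrimination limits.
        """
        if key_b is None:
            return 1.0
        if key_a == key_b:
            return 0.0
        if key_a[0] == key_b[0]:
            return 1.0
        return self.distinctness(key_a[0], key_b[0])

    def p_detect(self, concentration_sv: float) -> float:
        return 0.0 if concentration_sv <= 0 else float(weibull(concentration_sv, self.detect))


def session_rate_bouts_per_min(
    params: VirtualMouseParams,
    nu_chamber: float,
    nu_stim: float,
    valence: float,
    first_exposure: bool,
) -> float:
    """Expected bout rate for one session (the simulator's closed-form core)."""
    boost = (1.0 + abs(valence)) if first_exposure else 1.0
    rate = params.lambda_base * (1.0 + params.eta * (nu_chamber + nu_stim * boost))
    if not first_exposure and valence < 0:
        rate *= 1.0 + valence
    return max(rate, 0.0)


def _merge_bouts(bouts: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of bout intervals: the IR beam cannot re-break while broken."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(bouts):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def simulate_habituation_assay(
    params: VirtualMouseParams,
    schedule: AssaySchedule,
    rng: np.random.Generator | None = None,
) -> EventLog:
    """Run one animal through a habituation-family schedule; returns its event log."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    stim_novelty: dict[tuple[str, float], float] = {}  # base novelty per stimulus
    exposures: dict[tuple[str, float], int] = {}
    prev_key: tuple[str, float] | None = None
    nu_chamber = 1.0
    bouts: list[tuple[int, int]] = []
    events: list[Event] = []
    for session in schedule:
        key = (session.stimulus, session.concentration_sv)
        if key not in stim_novelty:
            p = params.p_detect(session.concentration_sv)
            stim_novelty[key] = p * params.key_distinctness(key, prev_key)
            exposures[key] = 0
        first = exposures[key] == 0
        nu_stim = stim_novelty[key] * params.rho ** exposures[key]
        v = params.valence.get(session.stimulus, 0.0)
        rate = session_rate_bouts_per_min(params, nu_chamber, nu_stim, v, first)
        duration_min = session.duration_ms / 60_000.0
        n_bouts = rng.poisson(rate * duration_min)
        starts = session.onset_ms + rng.uniform(0, session.duration_ms, size=n_bouts)
        lengths = rng.exponential(params.bout_mean_ms, size=n_bouts)
        for s, d in zip(starts, lengths):
            s_ms = min(int(round(s)), session.offset_ms - 1)
            e_ms = min(s_ms + max(1, int(round(d))), session.offset_ms)
            bouts.append((s_ms, e_ms))
        # valve + TTL markers for odor sessions
        if session.concentration_sv > 0:
            events.append(Event(session.onset_ms, "on", ODOR_VALVE_LOCATION, 100.0))
            events.append(Event(session.offset_ms, "off", ODOR_VALVE_LOCATION, 100.0))
        events.append(Event(session.onset_ms, "on", TTL_LOCATION, 1.0))
        events.append(Event(session.offset_ms, "off", TTL_LOCATION, 1.0))
        exposures[key] += 1
        nu_chamber *= params.rho
        prev_key = key
    for s_ms, e_ms in _merge_bouts(bouts):
        events.append(Event(s_ms, "on", POKE_LOCATION, 1.0))
        events.append(Event(e_ms, "off", POKE_LOCATION, 1.0))
    meta = {"assay": schedule.paradigm, "generator": "virtual-mouse"}
    if params.seed is not None:
        meta["seed"] = str(params.seed)
    return EventLog(events=events, meta=meta)


def _operant_correct(
    params: VirtualMouseParams,
    concentration_sv: float,
    trial_index: int,
    rng: np.random.Generator,
) -> bool:
    acc = 0.5 + (params.learn_asymptote - 0.5) * (
        -np.expm1(-trial_index / params.learn_tau)
    )
    p_correct = 0.5 + (acc - 0.5) * params.p_detect(concentration_sv)
    return bool(rng.random() < p_correct)


def simulate_two_choice(
    params: VirtualMouseParams,
    trials: TrialSequence,
    concentration_sv: float,
    rng: np.random.Generator | None = None,
    n_prior_trials: int = 0,
) -> ChoiceCounts:
    """Simulate a two-choice session; ``n_prior_trials`` positions the agent
    on its learning curve (0 = naive)."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    odors = sorted({t.odor for t in trials})
    p_aa = p_bb = 0
    for i, trial in enumerate(trials):
        correct = _operant_correct(params, concentration_sv, n_prior_trials + i, rng)
        if correct:
            if trial.odor == odors[0]:
                p_aa += 1
            else:
                p_bb += 1
    return ChoiceCounts(p_aa=p_aa, p_bb=p_bb, p_total=len(trials))


def simulate_gonogo(
    params: VirtualMouseParams,
    trials: TrialSequence,
    concentration_sv: float,
    rng: np.random.Generator | None = None,
    n_prior_trials: int = 0,
) -> GoNoGoCounts:
    """Simulate a go/no-go session with the same learning/detection structure."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    hits = misses = false_alarms = correct_rejections = 0
    for i, trial in enumerate(trials):
        correct = _operant_correct(params, concentration_sv, n_prior_trials + i, rng)
        if trial.correct_response == "go":
            if correct:
                hits += 1
            else:
                misses += 1
        else:
            if correct:
                correct_rejections += 1
            else:
                false_alarms += 1
    return GoNoGoCounts(
        p_cs_plus=hits,
        np_cs_plus=misses,
        p_cs_minus=false_alarms,
        np_cs_minus=correct_rejections,
    )


def default_params_sampler(
    rng: np.random.Generator, base: VirtualMouseParams
) -> VirtualMouseParams:
    """Animal-to-animal variability: lognormal spread on baseline rate and
    bout duration (individual basal activity differs; habituation behavior
    is shared)."""
    return replace(
        base,
        lambda_base=base.lambda_base * rng.lognormal(0.0, 0.3),
        bout_mean_ms=base.bout_mean_ms * rng.lognormal(0.0, 0.2),
        seed=None,
    )


def simulate_cohort(
    n_animals: int,
    schedule: AssaySchedule,
    base_params: VirtualMouseParams | None = None,
    params_sampler=default_params_sampler,
    seed: int | None = None,
) -> list[EventLog]:
    """Simulate independent animals on one schedule, reproducibly.

    Per-animal random streams are spawned from the master seed, so the
    same master seed always yields identical logs and enlarging the
    cohort leaves earlier animals' data unchanged.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    base_params = base_params or VirtualMouseParams()
    children = np.random.SeedSequence(seed).spawn(n_animals)
    logs = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        params = params_sampler(rng, base_params) if params_sampler else base_params
        log = simulate_habituation_assay(params, schedule, rng)
        log.meta["animal"] = f"vm{i:03d}"
        logs.append(log)
    return logs
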