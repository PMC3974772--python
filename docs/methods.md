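# Methods

This note documents the models implemented in `nosepoke`, the defaults
and why they were chosen, and what the synthetic-data validation does and
does not establish about real data.

## Event model

Hardware events are integer milliseconds from log start (1-ms
quantization); wall-clock dates live in the `#`-prefixed metadata header,
never in the event stream. At identical timestamps `off` sorts before
`on` so that zero-length gaps between bouts are representable.

Pairing `on`/`off` into bouts is a per-location state machine: each `on`
matches the next `off`. A second `on` while the beam is already broken is
physically impossible and treated as a glitch — discarded with a warning.
An `off` with no open bout is likewise discarded. A trailing open `on` is
closed at the last event time of the log (recording stopped with the
animal in the port). Pairing is cross-checked in the tests against an
independent brute-force oracle and, by construction, never produces
overlapping bouts.

The CSV dialect (`time_ms,event_type,location,magnitude`, UTF-8, LF,
magnitudes at ≤ 6 significant digits) is this package's own fixed
re-encoding of the four conventional columns; parse∘write is the identity
on valid logs.

## Olfactometer model

Vial headspace is assumed ideal (Raoult): a liquid dilution *d* emits
*d* × saturated vapor, so the delivered concentration is d·f/F for odor
flow f and total flow F. The instrument geometry defaults to two banks of
four vials (16 binary mixtures), a 100 ml/min fixed line, 1–99 ml/min
variable lines (198 ml/min maximal combined bank flow), and a 1000 ml/min
total setpoint with the constant-total-flow rule.

The synthesized PID trace is a per-odor first-order system: exponential
rise toward `gain × c_sv` while the valve is open with τ_rise = 0.2 s
(rise is fast and treated as odor-independent), and exponential clearance
after close with

```
τ_clear = 8.0 / vapor_pressure_mmHg, clipped to [0.2 s, 2.1 s]
```

More volatile odors clear faster; the coefficient gives amyl acetate
(4 mmHg) τ ≈ 2.0 s, and the 2.1 s ceiling guarantees the trace falls
below 1% of plateau within 10 s of valve close (e^(−10/2.1) ≈ 0.9%) for
any odorant. Overlapping odors superpose linearly; no vial depletion is
modelled (repeated pulses produce equal plateaus), and per-odor PID
gains are free parameters defaulting to 1 — photo-ionization efficiency
is not modelled. Not modelled at all: tubing dead volume, fluid
dynamics, pressure transients (the constant-flow rule removes the
mechanical artifact by construction).

## Schedules

Habituation-family assays use 60-s stimulus windows at 240-s
onset-to-onset spacing ("one-minute stimulus at four-minute intervals"
read as onset spacing; both are configurable). Cross-habituation defaults
to 8 air sessions, then 5 of the first odor, then 5 of the second. The
threshold series is an air block followed by ascending concentration
blocks, one session per concentration by default.

Operant sessions are balanced pseudorandom sequences (default 30 trials
per odor) drawn by seeded rejection sampling under a maximum run length
of 3, which prevents degenerate same-side blocks while keeping the
sequence distribution uniform over admissible orders.

## Behavioral statistics

Basal activity is the arithmetic mean of investigation over *all*
zero-concentration sessions (a last-*k* option exists). NPI = 100 ×
investigation / basal; the air-block mean NPI is therefore exactly 100%.
Windows are half-open `[onset, offset)` and straddling pokes are clipped,
not counted whole. A basal of zero (the animal never investigated during
background) raises `AnimalExcludedError` rather than producing infinities;
the same policy covers a three-chamber animal that never entered the
control zone.

Success rates: two-choice SR = (P_AA + P_BB)/P_total; go/no-go SR =
(hits + correct rejections)/total, the only combination of the four
counts with a 50% chance floor. The attraction index is NPI(first odor
session) − NPI(last solvent session); the aversion index is NPI(last
solvent session) − NPI(second odor session), signed so that stronger
aversion is more positive (aversion expresses itself from the second
presentation onward, when the animal starts avoiding the port).

The JND threshold tests each concentration's across-animal ΔNPI (probe
minus immediately preceding session) against zero with a paired t-test
and reports the smallest significant concentration. The tests are
Holm-corrected across the concentration series by default, so `alpha` is
a familywise error rate: without correction, screening 7 concentrations
at α = 0.05 would false-alarm on ~30% of null cohorts, which would make
the procedure's "no detectable concentration" answer meaningless. A
zero-variance column is handled outside the t-machinery: exactly-zero
scores give p = 1, an exactly reproduced nonzero effect gives p = 0.

## Psychometric fitting

ψ(x) = g + (A − g)(1 − exp(−(x/a)^b)) with g fixed by paradigm. The fit
estimates (A, log b, log a) by least squares (`scipy.optimize.
least_squares`, tolerances 1e-14). Working in log-parameters keeps b and
a positive and makes the fit exactly equivariant under rescaling of the
concentration axis. Initialization is deterministic: A₀ = max(y), a₀ at
the half-rise by log-interpolation, plus a coarse grid of starts over
b ∈ {0.75, 1.5, 3} and a over every other sampled concentration; the
best optimum wins. Optional per-point `sigma` (e.g. across-animal SEM)
weights the residuals.

Honesty of the `converged` flag: a flat response profile, a fitted
threshold more than three decades outside the sampled range, or A ≤ g is
reported as non-converged with a diagnostic message — never silently
replaced by a fallback value.

## Virtual mouse

Session-level Poisson bout process: during a session the animal emits
poke bouts at rate (bouts/min)

```
λ = λ_base · (1 + η·(ν_chamber + ν_stim·first-exposure boost)) · aversion factor
```

with exponential bout durations (clipped to the session window, merged
when overlapping). `ν_chamber` starts at 1 and decays by ρ per session —
the habituation of the initial air block. `ν_stim` on first exposure is
`p_detect(c) · D(new, habituated)`: the ground-truth Weibull detection
probability times perceptual distinctness from the stimulus the animal
last habituated to (D = 0 means habituation transfers fully — no
dis-habituation; that is exactly what makes ΔNPI a similarity readout).
It decays by ρ on repeats. Valence v amplifies the first exposure by
(1 + |v|) (salient odors draw investigation regardless of sign) and
multiplies subsequent sessions of aversive odors by (1 + v) < 1,
pushing investigation below baseline. Distinct concentrations of one
odor are distinct stimuli: series steps are a decade (or 0.4 decade)
apart, beyond intensity-discrimination limits — a deliberate
simplification.

Operant behavior: trial-t accuracy follows a saturating learning curve
acc_t = 0.5 + (asymptote − 0.5)(1 − e^(−t/τ_learn)), degraded toward
chance by detectability: p(correct) = 0.5 + (acc_t − 0.5)·p_detect(c).

Defaults (configuration, not claims about any particular animal):
λ_base = 4 bouts/min and mean bout 800 ms — a few seconds of
investigation per one-minute session, the order seen in odor-port
assays; ρ = 0.3, strong per-repeat habituation, because interest in a
repeated stimulus collapses to background after the first repetition;
η = 3, so a fully detected novel odor roughly quadruples the poke rate;
ground-truth detection (A = 1, b = 1.5, a = 2×10⁻⁶, g = 0);
τ_learn = 30 trials, asymptote 0.95, matching >90% success after a few
hundred training trials. Animal-to-animal variability is a lognormal
spread (σ = 0.3) on λ_base and (σ = 0.2) on bout duration: individuals
differ in basal activity, habituation dynamics are shared.

Cohorts derive per-animal streams by `SeedSequence.spawn`, so one master
seed reproduces every log byte-for-byte and enlarging a cohort leaves
existing animals unchanged.

## Threshold pipeline design

Two dis-habituation scores serve two jobs, and the distinction matters:

* The **psychometric fit** scores each probe as NPI(probe) − mean NPI of
  the last 4 air sessions (the habituated floor, where the chamber-
  novelty transient has decayed). Against this floor an undetected probe
  scores 0 in expectation, so fixing g = 0 is honest. Scoring against the
  whole-air-block 100% instead would inherit the air block's early
  novelty transient as a negative offset that a g = 0 Weibull cannot
  represent. The across-animal mean at each concentration is fitted with
  its SEM as weight: an animal whose basal happened to be estimated from
  a few unusually quiet sessions inflates its entire NPI curve, and the
  weights stop such cohort outliers from steering the fit.
* The **JND t-tests** use the successive difference NPI[i] − NPI[i−1],
  which is exactly mean-zero under no detection and is the natural
  paired statistic.

The default probe design places 7 concentrations at 0.4-decade steps
centered on the expected threshold — the standard psychophysical practice
of concentrating samples where they carry information about `a`. With the
default noise model, 12 animals and this design, the end-to-end pipeline
recovers the ground-truth threshold with a geometric-mean error of a few
percent and lands within ±50% in ≈9 of 10 replicate cohorts; the
go/no-go route (success rates of trained agents, g = 0.5) is
considerably more precise because binomial trial noise is far smaller
than session-level bout noise.

## Problem sizes used in validation

The shipped tests run cohorts of 1–12 animals, 150–400 replicate
single-animal simulations for phenomenon-level means, 200 replicate
12-animal cohorts for the null calibration of the JND procedure, and
1000 random logs for the pairing oracle — sizes at which the checked
means are several standard errors away from their failure bounds.

## What passing tests do and do not show

The generator reproduces the statistical *structure* the analyses assume:
habituating baselines, detection-gated novelty responses, valence
effects, learning curves, and per-animal basal variability. It does not
emulate within-session dynamics (bout clustering, sniffing bouts),
circadian or motivational drift, sensory adaptation at short intervals,
odor-specific investigation styles, or correlations between basal
activity and odor sensitivity. Passing recovery tests therefore shows the
*pipeline* is correct and well-calibrated under these assumptions — not
that any particular real animal meets them. Thresholds measured on real
animals also depend on paradigm (trained assays read out decision
confidence as well as detection), which is precisely why the
habituation-based and go/no-go routes are both provided.

## Known limitations

* The headspace model ignores activity coefficients; strongly non-ideal
  odorant/solvent pairs deviate from d × saturated vapor.
* PID amplitudes are in arbitrary units with per-odor gain 1; only
  relative and temporal structure is meaningful.
* The JND procedure inherits the t-test's small-sample behavior; with
  very few animals the Holm-corrected screen is conservative.
* `three_chamber_indices` consumes zone times; extracting zone times
  from video/coordinates is out of scope.
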