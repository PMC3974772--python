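# nosepoke

Automated olfactory-behavior assays for rodents, simulated and analyzed:
a virtual olfactometer, a 1-ms nose-poke event-log data model, schedule
builders for habituation-family and operant paradigms, the behavioral
statistics built on them, Weibull psychometric threshold fitting, and a
generative virtual mouse that lets the whole pipeline be validated
end-to-end against a known ground truth — no animals, no downloads.

## Who this is for

Olfactory psychophysics labs that score odor-port investigation from
time-stamped event logs (IR beam breaks, valve openings, licks, TTLs),
and anyone who wants to prototype or power-analyze habituation/
dis-habituation, two-choice, or go/no-go experiments before running them.

## The quantities at the core

**Flow dilution.** An odorant at liquid volume fraction *d* in solvent,
carried by an odor line at flow *f* into total flow *F*, arrives at the
animal at concentration (fraction of saturated vapor)

```
c_sv = d · f / F
```

A constant-total-flow rule drops the carrier by exactly the open odor-line
flow during a pulse, so odor onset carries no mechanical artifact.

**Normalized port investigation.** With per-session investigation time
*I_s* and basal activity *B* (mean investigation over the background
air/solvent sessions),

```
NPI_s = 100 · I_s / B        ΔNPI_s = NPI_s − NPI_{s−1}
```

The air-block mean NPI is 100% by construction; ΔNPI ≈ 0 for a repeated
habituated stimulus and jumps for a perceptibly novel one, making it a
training-free readout of detection and discrimination.

**Operant success rates.** Two-choice: SR = (P_AA + P_BB) / P_total.
Go/no-go: SR = (hits + correct rejections) / all trials; chance is 50%.

**Psychometric threshold.** Response versus concentration *x* is fit with
the Weibull psychometric function

```
ψ(x) = g + (A − g)·(1 − exp(−(x/a)^b))
```

with the floor *g* fixed by paradigm (0.5 for go/no-go, 0 for
dis-habituation scores); the fitted *a* is the detection threshold. A
complementary just-noticeable-difference (JND) estimate takes the
smallest concentration whose ΔNPI differs from zero by paired t-test
across animals (Holm-corrected over the concentration series).

## Worked example

Simulate a 12-mouse detection-threshold cohort (ground-truth threshold
2×10⁻⁶ s.v.), analyze the event logs, and fit the psychometric curve:

```
$ nosepoke simulate --n-animals 12 --seed 0 --out-dir demo/cohort
wrote 12 event logs to demo/cohort

$ nosepoke analyze --log-dir demo/cohort \
    --schedule demo/cohort/schedule.json --out-dir demo/tables
analyzed 12 animals -> demo/tables

$ nosepoke fit-threshold --matrix demo/tables/delta_npi_fit_matrix.tsv \
    --jnd-matrix demo/tables/delta_npi_matrix.tsv --out demo/fit.json
threshold a = 1.74e-06 s.v. (converged=True), JND = 2e-06

$ nosepoke report --fit demo/fit.json
Weibull psychometric fit
  A (max response) : 178.6
  b (steepness)    : 2.151
  a (threshold)    : 1.736e-06 s.v.
  g (fixed floor)  : 0
  RSS / n          : 568.4 / 7
  converged        : True
  JND threshold    : 2e-06 s.v.
```

Reading the numbers: the virtual mice were probed at seven log-spaced
concentrations around their built-in threshold of 2×10⁻⁶; the fitted
threshold *a* = 1.74×10⁻⁶ recovers it to within 13%, and the JND
procedure flags 2×10⁻⁶ as the lowest statistically detectable
concentration. `cohort_metrics.tsv` holds the per-session investigation,
NPI and ΔNPI for every animal; each animal's air-block NPI averages
exactly 100%.

The same works in Python:

```python
import nosepoke as nk

est = nk.run_threshold_experiment(n_animals=12, seed=0)
print(est.threshold, est.jnd_concentration, est.fit.converged)
```

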