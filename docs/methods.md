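# Methods

## System and measurement model

The instrument is an office chair carrying eight analog tactile pressure
sensors (ATS): channels 1–4 on the seat, 5–8 on the backrest, sampled at
45 Hz. Each sensor has an inverted, nonlinear load response — maximum
output voltage `V_zero` with no load, dropping toward a minimum
`V_maxload` when fully pressed — and every physical sensor settles at
its own pair of levels, which also vary with the person seated. The
analysis therefore uses the sensors strictly as switches: a channel is
*active* (pressed) while its filtered voltage is below a per-test,
per-channel threshold. No continuous load information is extracted, and
dynamic parameters (center of pressure, sway) are out of scope.

## Calibration and activation

Before each test two calibration acquisitions are made: the empty chair
(per-channel mean = `V_zero`) and the participant fully seated in the
reference posture P1 with every sensor pressed (per-channel mean =
`V_maxload`). The activation threshold is the midpoint of the range,

    thr = V_maxload + 0.5 (V_zero − V_maxload).

Numerical choices:

* `V_maxload` is the *mean* over the seated segment, not the per-sample
  minimum — the loaded-state level is what the threshold needs, and a
  minimum would be biased low by noise.
* Calibration segments must be at least 0.5 s; the simulator emits 2 s
  segments by default (configurable).
* Activation uses strict `<` at the threshold; a value exactly at the
  threshold counts as inactive. Under any noise this is a measure-zero
  event; the choice is conservative.
* Signals are low-pass filtered before thresholding with a centered
  moving average. The window length comes from the −3 dB criterion
  `N = round(0.443 · fs / f_c)`, giving N = 20 samples at fs = 45 Hz for
  the 1 Hz design cutoff; its measured gain at 1 Hz equals the Dirichlet
  closed form `|sin(π f N / fs)/(N sin(π f / fs))| ≈ 0.706`. The window
  is centered (zero phase, appropriate for offline analysis) and shrinks
  at the trace edges so input and output lengths match.

## Posture taxonomy

Eight postures P1–P8 are defined by exact 8-bit activation patterns
(seat bits first). Two corrections to the tabulated patterns were design
decisions:

* As tabulated, P7 ("front of the seat, not leaning on the backrest")
  and P8 ("front of the seat plus upper backrest") share the pattern
  `(1,1,0,0,0,0,1,1)`, which contradicts P7's description and makes the
  lookup non-injective. The default lookup assigns P7 the
  description-consistent pattern `(1,1,0,0,0,0,0,0)` and keeps the
  tabulated pattern for P8. The as-tabulated table can be constructed
  but refuses to build a lookup.
* P4 and P5 ("right/left leg crossed, off the backrest") carry seat
  patterns mirrored relative to P2/P3's halves. The default reproduces
  the tabulated patterns; a `swap_p4_p5` flag applies the
  description-consistent variant.

Any other pattern maps to UNRECOGNIZED.

## Interval aggregation and quality control

The Stroop schedule defines three half-open analysis windows in seconds
from test start: TI1 (reading + congruent slides, 31 s), TI2
(incongruent slides with 3–6 words, 26 s), TI3 (incongruent slides with
9–12 words, 28 s). Instruction screens default to 0 s and shift window
offsets only. The stated protocol reports a single sensor combination
per interval but no aggregation rule; this package uses the **modal
per-sample pattern** within the window, with ties broken by earliest
occurrence — deterministic and robust to brief transients.

Quality control excludes a participant listwise when any channel has
missing samples in the test segment, leaves the supply range, or shows
zero variance over the whole recording (a working channel must move
between its no-load and loaded levels across the calibration segments);
a modal pattern outside the taxonomy in any interval likewise excludes
the participant. This mirrors the reference study's accounting
(114 recorded → 92 after sensor QC → 83 fully classified).

## Transition statistics

For each interval pair (TI1–TI2, TI2–TI3) an 8×8 contingency table
counts participants by (earlier, later) posture. Pairwise tests use the
continuity-corrected McNemar chi-square

    chi² = (|b − c| − 1)² / (b + c),  df = 1,

**without clamping** the corrected difference at zero, so b = c gives
chi² = 1/(b + c). This variant uniquely reproduces all nine reference
p-values from the reference tables; uncorrected and exact-binomial
variants are available behind a flag. The eligibility ("McNemar")
condition is min(b, c) ≥ 1 — exactly the pairs tested in the reference
analysis, which excluded one-sided flows even when b + c > 2.

Bowker's global symmetry statistic sums the *uncorrected* pairwise
statistics over pairs with b + c > 0, with df = the number of included
pairs (the standard convention). On the reference tables this gives
chi² = 19.93, df = 15, p = 0.174 (TI1–TI2) and chi² = 30.88, df = 16,
p = 0.014 (TI2–TI3). The reference report quotes global p-values of
0.083 and 0.0002 for these tables; those values are not recoverable
from the printed counts under any consistent df convention we could
identify, so the package documents the discrepancy rather than tuning
the df rule to match, and the global p-values are not asserted anywhere.

Posture triples (TI1, TI2, TI3) are classed as NO_TRANSITION (all
equal), NON_MONOTONIC (return to the departed starting posture, e.g.
P1→P6→P1), or MONOTONIC otherwise.

### Display rounding

p-values are displayed to three decimals (four below 0.001). Rounding is
two-stage: first to four decimals, then to three with an exact trailing
5 dropped rather than rounded up. This half-down convention is what the
reference tables print — e.g. chi² = 0.5 has p = 0.47950, shown as
0.479 — whereas plain round-half-up would print 0.480. Raw p-values are
always carried alongside the display values.

## Synthetic-data generator

The generator emulates the recordings the hardware would produce:

* **Two-level response.** A loaded channel sits at `v_maxload`, an
  unloaded one at `v_zero`; the analysis treats sensors as switches, so
  no continuous load-response curve is modeled.
* **Defaults** (package parameters, not measured facts): per-channel
  `v_zero ~ U(2.8, 3.3) V`, `v_maxload ~ U(0.8, 1.3) V` (mimicking
  sensor-to-sensor spread), supply rail 3.3 V with clipping (clipped
  fraction reported in trace metadata), Gaussian noise sd 0.02 V,
  linear drift available but 0 V/s by default so the noiseless
  round trip is exact, 2 s calibration segments, instantaneous posture
  changes at segment boundaries (a ramp option exists, off by default).
* **Failure injection**: stuck-at-no-load, stuck-at-loaded, and sample
  dropout, for exercising quality control.
* **Exact-margin cohorts.** Given two 8×8 transition tables with
  consistent margins (columns of the first = rows of the second),
  `generate_fixture_cohort` builds the cohort of posture triples whose
  (TI1,TI2) and (TI2,TI3) pair counts reproduce both tables
  cell-for-cell: participants are enumerated over the first table in
  row-major order, then each TI2 group receives its TI3 postures by
  dealing the matching row of the second table in participant-id order.
  The construction is deterministic; TI3 couples to TI1 only through
  TI2, so the three-way joint distribution is one representative of the
  many consistent with the two pairwise tables (the reference data
  constrain only the pairwise margins). Triple-class counts computed on
  fixture cohorts therefore need not match any particular three-way
  account.

What the generator does *not* emulate: the duty-cycled single-ADC
multiplexing electronics, battery/wireless behavior, gradual postural
shifts within an interval, and participant-specific pressure styles.
Passing tests on synthetic cohorts show the pipeline's correctness and
noise robustness under the stated signal model, not classifier accuracy
on real sitters.

## Problem sizes and determinism

The test suite and the acceptance script run the full pipeline on
83-participant cohorts (each recording: 89 s × 45 Hz × 8 channels).
Noise-robustness checks use ten seeded cohorts at noise sd = 5% of the
per-channel voltage range and require ≥ 99% of interval postures
recovered; the noiseless round trip must recover 100%. All randomness
flows from explicit seeds through `numpy.random.Generator`; identical
seeds give bit-identical traces and byte-identical reports.

## Known limitations

* The modal-pattern aggregation rule and the P7 correction are this
  package's design decisions; other reconstructions of the reference
  pipeline are conceivable.
* The reference global symmetry p-values could not be reproduced from
  the published tables (see above).
* One published interval share (59% in P1 during TI1) is inconsistent
  with the published TI1 margin (48/83 ≈ 58%); the package reports the
  margin-derived value.
* Sensor physics is binary by design; postures outside the eight-pattern
  taxonomy are rejected, not approximated.
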