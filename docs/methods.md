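# Methods

## The measurement being modelled

A liquid microjunction surface-sampling probe (LMJ-SSP) extracts analytes
wherever its solvent dome touches a surface and feeds them to a mass
spectrometer acquiring full-scan centroid spectra at a fixed cadence. Two
signals are recorded against a common clock: the spectrum stream (mzML)
and a conductance trace from the contact sensor. Analysis must answer, per
sampling spot: *which spectra were acquired while this spot's extract was
reaching the detector* (registration), *how much analyte was there*
(heatmap), and *at what height did contact occur* (surface profile).

## Contact sensing

The sample bed is biased at `supply_voltage` (default 5 V) and measured
through an ADC of `adc_bits` (default 10, full scale 1023 counts):

    sensorValue        = round(v / supply × 1023), clamped to [0, 1023]
    relativeConductance = 1023 − sensorValue

Rounding is half-away-from-zero, so the quantization error is at most half
an LSB (2.44 mV on the 5 V scale). When the grounded probe touches a
conductive region, the bed voltage collapses and relativeConductance jumps
from 0 toward 1023. Contact is declared strictly above a user threshold
(default 100 counts); the strictness is deliberate so a threshold equal to
the reading never triggers, and a `>=` variant is a one-line change.

The approach controller descends in steps of `step_distance` (default
0.05 mm), with one ADC read after each step (and one before the first, so
a probe already in contact triggers immediately). The contact height is
the z *after* the triggering step — no back-off or sub-step interpolation
— so the recorded height underestimates the true surface by at most one
step. Reaching the descent floor `z_min` without a trigger records a
*miss* (a normal outcome, e.g. a non-conductive patch) and the run
continues; a failed read raises a hardware error, which is a different
condition than a miss. Descent rungs are computed as `start_z − k·step`
(not accumulated) and rounded to 1 nm so exact-multiple surfaces behave
predictably; commanded positions are G-code text with 0.001 mm
resolution anyway.

## Motion

Spots lie at `origin + i·pitch`, endpoints inclusive, enumerated row by
row; serpentine order (default) reverses alternate rows to minimise
travel. Per spot the planned primitives are: lateral move at travel
height, descent, sample for `sampling_time`, retract, dwell for
`dwell_time`. The retract after sampling doubles as the travel raise for
the next spot. The travel height is `travel_clearance` (default 2 mm)
above the highest contact seen so far, never below the run-start height.
In conductance mode the plan contains the full step/read ladder down to
`z_min`, since the plan cannot know where contact will occur; execution
stops the ladder at the first trigger, so executed times can only be
earlier than planned. G-code is Marlin-style absolute positioning
(`G90`/`G1`/`G4`, coordinates in mm to three decimals, dwells in
milliseconds), kept in a module-level dialect table.

Timing defaults are `sampling_time = 3 s` and `dwell_time = 5 s`. The
dwell was chosen so a complete spot cycle (~8.5 s with typical descent
depths) exceeds the 8 s extraction window; consecutive spot windows then
do not overlap and each averaged spectrum reflects one spot. Shorter
dwells work but trigger an overlap warning during extraction.

## The virtual rig

The simulator exists so the controller and the analysis pipeline can be
exercised end to end with known ground truth. It emulates:

* **gantry** — a G-code interpreter with instantaneous-position kinematics;
  the clock advances by distance/feed on moves and by the dwell time on
  `G4`. No acceleration model: all analysis is driven by recorded
  timestamps, not motion physics.
* **surface** — `z(x, y) = a·x + b·y + c + Σ Gaussian bumps`, in probe
  coordinates (z = 0 at run start, specimens at negative z, relief up to
  several mm like real unleveled tissue); a binary conductive mask; and
  per-analyte concentration fields `c(x, y) ≥ 0`.
* **ADC** — grounded (0 V) when the tip is at or below the conductive
  surface, full supply otherwise, plus optional Gaussian noise applied in
  the count domain (`noise_sd` counts) before clamping. An optional
  `dome_offset` models early contact through the solvent dome
  (default 0).
* **MS stream** — centroid spectra on one fixed m/z grid every
  `scan_period` (default 0.5 s). A solvent background is always present.
  Each contact adds `response_gain × c(x, y)` at each analyte's m/z
  starting `t_offset_true` (default 2 s) after contact, holds it during
  sampling, then decays it exponentially with `washout_tau` (default
  3 s). Multiplicative Gaussian noise of relative width
  `intensity_noise_cv` applies per centroid, clipped at zero. The stream
  defaults were chosen together so a ±4 s window captures one sampling
  event cleanly. Analyte or solvent m/z values closer than one grid bin
  (0.1) are rejected at configuration time rather than silently merged.

All randomness (ADC counts, intensity noise) comes from two seeded
generators (surface seed, stream seed); fixed seeds reproduce every
artifact bit for bit.

What the rig deliberately does **not** model: liquid-junction fluidics,
ion-source physics, isotope patterns, profile-mode peak shapes, m/z axis
jitter between scans, chromatographic tailing beyond the single
exponential, and electrical impedance beyond the binary mask. Passing
tests therefore demonstrate the correctness of the control logic and the
registration/mapping arithmetic under the stated signal model — not
robustness to every artefact of real spectra. The exponential washout in
particular is a stand-in: real carryover kinetics are not characterised.

## Registration

Two routes identify the spectra of interest:

* **TIC route**: peaks of the total ion current (default m/z range
  150–500). The picker subtracts nothing; it finds local maxima with
  scipy prominence at least `5% × (global max − global baseline)`, where
  the baseline is a centred rolling 20th percentile (25-scan window), and
  additionally requires the peak to clear its local baseline by the same
  margin. Ties — flat plateau samples, or candidates within one scan
  period — resolve to the **earliest** time, so a reported peak marks the
  detection onset. Onset anchoring keeps the two routes consistent and
  the delay estimator unbiased; a plateau-centre convention would shift
  windows by half the sampling time exactly on flat-topped (isolated,
  noiseless) events.
* **Conductance route**: rising edges of `relativeConductance >
  threshold` give contact onsets regardless of signal strength; each
  window is anchored at `contact + t_offset`. `t_offset` can be supplied
  or estimated as the median lag from each contact to the earliest TIC
  peak at or after it (contacts with no following peak are ignored). The
  estimator is upward-biased by scan quantization, bounded by one
  scan period.

Events map to spots by plan order with missed spots skipped; the trace's
recorded (x, y) provide a nearest-spot cross-check that warns on
disagreement. All spectra with scan time in the closed window
`anchor ± half_window` (default 4 s) are averaged: point-wise when scans
share an m/z axis (always true for rig data), otherwise accumulated into
fixed-width m/z bins (default 0.1, intensity-weighted bin centres) and
divided by the member count, so the average stays linear in intensity. An
empty window yields a spot flagged empty rather than being dropped.

The `align_by_tic_vs_conductance` report compares the two routes: equal
event counts and per-spot window-centre differences within one scan
period mean agreement; a count mismatch is exactly the weak-signal
situation the conductance route exists for.

## Maps

A heatmap cell is the XIC (inclusive closed window, e.g. 858.6 ± 1) of the
spot's averaged spectrum; a height-profile cell is the contact z. Missed
spots stay missing (NaN) — interpolation is a rendering option, off by
default. The CSV matrix writes row 0 = smallest y with an explicit header
to avoid the image-versus-plot flip; PNG rendering uses a perceptually
uniform colormap with missing cells in a distinct grey, scale limits at
data min/max unless fixed for cross-run comparison.

## Numerical and design notes

* m/z window bounds are inclusive on both ends ("±1" read as a closed
  interval); intensities are summed, not maxed, within windows.
* The mzML layer is intentionally minimal: MS1 centroid spectra with scan
  start times, 64-bit uncompressed arrays on write; 32/64-bit, zlib or
  plain, indexed or not on read. Round trips are cross-checked against an
  independent reader (Bioconductor `mzR`) in the test suite. MSn scans
  are skipped with a warning.
* Grid endpoints are inclusive, so a 15 × 11 mm area at 1 mm pitch plans
  (15+1)×(11+1) = 192 spots. (Published spot counts for comparable areas
  sometimes differ because real layouts are masked to the specimen
  outline; the planner makes no such mask — missed spots handle
  non-conductive surroundings at run time.)
* Exactness fixtures (e.g. the two-region heatmap partition test) use a
  fast washout (`washout_tau = 0.01 s`) and scan-aligned contact cadence:
  with the default 3 s washout, every later window contains a
  mathematically nonzero carryover from earlier spots, so cells of one
  region can never be float-identical. The fast-washout regime isolates
  spatial assignment, which is what those tests verify; carryover
  behaviour itself is tested separately via the e-folding check.
* Test problem sizes (15-spot lines, 3×3/4×4 grids, 50 four-spot runs for
  delay recovery, 100 single-spot approaches for localization) were
  chosen as the smallest sizes that still exercise every code path and
  statistical claim; all scale linearly if enlarged.

## Known limitations

* The conductance trace is sampled once per descent step, not
  continuously; contact times are exact at the trigger read but the trace
  between spots is sparse.
* Event-to-spot mapping assumes the run visited spots in plan order;
  aborted-and-resumed runs need manual alignment.
* The t_offset estimator needs at least one TIC peak; runs whose analytes
  all fall outside the TIC m/z range require an explicit `--t-offset` or
  a wider `--tic-range`.
* Static mode trusts `static_z`; no safeguard exists against commanding
  the probe into the sample.
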