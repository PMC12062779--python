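# probemap

Control, simulation, and analysis software for mass-spectrometry imaging
with a **liquid microjunction surface-sampling probe (LMJ-SSP)** mounted on
a converted 3-axis 3D-printer gantry.

The probe is a pair of concentric open tubes that hold a solvent dome at
the tip; touching the dome to a surface extracts analytes and carries them
to a mass spectrometer. Imaging a specimen means visiting a rectangular
grid of spots and, at each spot, bringing the probe into contact with a
surface whose height is unknown and may vary by millimetres. `probemap`
implements the whole desk-side stack:

* **motion** — raster grid planning and Marlin-style G-code emission for
  static (fixed z) and conductance (feedback-guided descent) sampling;
* **conductance** — the contact-sensing feedback loop: the sample bed is
  biased at 5 V and read through a 10-bit ADC as `sensorValue`
  (0–1023); the controller works with
  `relativeConductance = 1023 − sensorValue`, which is 0 in air and jumps
  toward full scale when the grounded probe touches the sample. Descent
  proceeds in steps (default 50 µm) until `relativeConductance` exceeds a
  threshold, which both stops the probe and records the surface height;
* **rig** — a fully virtual instrument (G-code-interpreting printer,
  parametric surface, ADC with noise, simulated MS stream with
  contact-to-detection delay and exponential washout) so everything is
  testable without hardware;
* **msio** — mzML read/write and TIC/XIC chronograms;
* **registration** — identifying the spectra acquired during sample
  contact, either from TIC peaks or — robust to weak signal — from the
  conductance trace plus the contact-to-detection delay `t_offset`, then
  averaging all spectra in a ±4 s window into one spectrum per spot;
* **imaging** — per-spot XIC heatmaps (analyte distribution) and z-height
  surface profiles (specimen topography), as PNG + gridded CSV.

Intended users: labs building or operating automated surface-sampling MS
platforms, and anyone who needs a reference implementation of
conductance-triggered contact sensing and contact-time-based spectrum
registration.

## Worked example

A 10 × 4 mm area at 1 mm pitch over a tilted synthetic surface carrying a
phosphocholine-like analyte (m/z 858.6) at concentration 10 in one region
and 1 elsewhere:

```bash
cat > surface.yaml <<'EOF'
plane: [0.08, 0.04, -2.2]
bumps:
  - {amplitude: 0.6, x: 7.0, y: 2.0, sigma: 3.0}
analytes:
  - mz: 858.6
    concentration:
      rects:
        - {rect: [5.5, 10.0, 0.0, 4.0], value: 10.0}
      default: 1.0
EOF

probemap plan --extent 10 4 --pitch 1 --out plan.yaml
probemap simulate --plan plan.yaml --surface surface.yaml --outdir run --seed 1
probemap register --mzml run/run.mzML --trace run/trace.csv --plan plan.yaml \
                  --tic-range 150 900 --out-prefix spots
probemap map --spots spots.mzML --spot-table spots.csv --plan plan.yaml \
             --mz 858.6 --tol 1 --out lipid
probemap map --height --trace run/trace.csv --plan plan.yaml --out height
```

prints

```
55 spots (11 x 5) -> plan.yaml
55 spots, 0 missed; wrote run/run.mzML, run/trace.csv
55 spots registered (t_offset=2.31 s) -> spots.mzML, spots.csv
wrote lipid.png, lipid.csv
relief = 1.250 mm
wrote height.png, height.csv
```

Reading the numbers: every one of the 55 planned spots produced a contact
event (`0 missed`); the estimated contact-to-detection delay of 2.31 s is
the simulated 2 s delay plus scan-time quantization (one spectrum every
0.5 s); the recovered relief of 1.250 mm is the true height range of the
tilted-plane-plus-bump surface sampled on the grid, quantized by the
50 µm descent step. The first row of `lipid.csv` shows the two
concentration regions directly — cells jump from ≈ 0.7 to ≈ 7.0 at the
region boundary (averaged-window XIC is proportional to concentration,
scaled by the fraction of window scans acquired during sampling):

```
# XIC m/z 858.6 +- 1; origin=(0,0) mm; pitch=1 mm; row 0 = smallest y
0.595,0.700,0.712,0.712,0.710,0.709,5.012,6.872,6.973,6.974,6.973
```

The same workflow is available as library calls (`plan_grid`,
`run_virtual_experiment`, `assign_events_to_spots`, `extract_spot_spectra`,
`build_heatmap`, `build_height_profile`); the CLI is a thin wrapper. With
real hardware, `run/run.mzML` and `run/trace.csv` are replaced by the
instrument's converted mzML and the controller's exported conductance
trace — the analysis path is identical.

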