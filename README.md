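# speedpeaks

Extraction and statistics of hidden speed micro-fluctuations (**s-Peaks**)
in 3D reaching movements, and the **R-parameter** — a scalar biomarker
measuring how far the within-cycle inter-peak intervals depart from a fully
random (exponential) law.

The pipeline:

1. **I/O** — a minimal CSV kinematics format (`time,x,y,z`, SI units,
   240 Hz default) with strict uniform-grid validation.
2. **Preprocess** — central-difference component velocities, triangular
   FIR smoothing (default 25-tap; the exact discrete response at 240 Hz is
   about −44.6 dB at both 20 Hz and 60 Hz), speed = norm of the smoothed
   components.
3. **Segmentation** — screen-touch detection from the screen-normal
   position (mean + 1 SD height rule, ≥ 300-frame separation), cycle
   start/stop selection from screen-axis velocity reversals (≥ 100 frames
   from the touch, near the rest posture, below-average speed, nearest to
   the touch), and outlier removal (> 600-frame or < 0.2 m/s cycles).
4. **Fluctuations** — strict local speed maxima inside cycles (plateaus
   count once, at their first frame), raster matrices (touch-aligned
   ±400 frames or mean-cycle-length aligned), within-cycle inter-peak
   intervals binned at 2 frames, an exponential fit to the ≤ 10-frame
   bins, and `R = Σ n_out_j·v_j² / Σ n_i·v_i` over the residual bins.
5. **Simulator** — asymmetric minimum-jerk bell strokes
   `v = (4τ(1−τ))²` with rest gaps and additive white Gaussian noise at
   controlled SNR, plus a 3D-position variant with full ground truth so
   segmentation is testable end-to-end.
6. **Classification** — unregularized maximum-likelihood logistic model on
   R with decision boundary and a repeated 70/30 split evaluation.

## CLI

A single entry point with subcommands:

```sh
# simulated speed session (CSV) or 3D recording
speedpeaks simulate --n-cycles 300 --snr-db 10 --seed 1 --out speed.csv
speedpeaks simulate --n-cycles 20 --recording --out rec.csv

# R versus SNR sweep (tidy CSV: snr_db, seed, R)
speedpeaks sweep --snr-db 0 --snr-db 10 --snr-db 15 --n-seeds 20 --out sweep.csv

# full analysis of a recording: cycle table, s-IPI histogram + fit,
# raster CSV (and PNG with --plots), R in summary.json
speedpeaks analyze rec.csv --out-dir out/ --plots

# raster export only
speedpeaks raster rec.csv --out-dir raster/

# logistic model on a subject_id,R,label table
speedpeaks classify rvalues.csv --out-dir cls/
```

Every run writes a `manifest.json` (config snapshot, inputs, seeds,
outputs) sufficient to reproduce it; identical manifests give
byte-identical CSVs. `--verbose` adds per-cycle diagnostics on stderr.
Config files are YAML key/value mirrors of `PipelineConfig`; CLI flags
override file values.

## Library use

```python
from speedpeaks import (SimConfig, synth_recording, analyze_recording)

rec, truth = synth_recording(SimConfig(n_cycles=50, snr_db=10, seed=1))
report = analyze_recording(rec)
print(report.r_value, report.cycles.n_cycles)
```
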