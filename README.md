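# drivehull

Quantifying upper-limb movement during naturalistic driving from paired
wrist-worn and vehicle-mounted triaxial accelerometers.

Clinicians and rehabilitation researchers need objective, scalable measures
of how much a driver actually moves their arm in real traffic — for example
when judging readiness to return to driving after upper-limb injury or
surgery. `drivehull` implements a full analysis pipeline for that question:

1. **Drive detection** — active driving periods are found on the
   vehicle-mounted logger: the per-axis median (gravity) is removed, the
   amplitude envelope of the longitudinal axis is computed as the smoothed
   modulus of the analytic signal (Hilbert transform), and sustained
   supra-threshold envelope runs become candidate drives. A candidate is
   retained as active driving if it contains a longitudinal acceleration
   event ≥ 0.35 g, a braking event ≥ 0.45 g, or a lateral event with
   |a| ≥ 0.5 g — thresholds established in naturalistic-driving research.
2. **Movement volume** — for each retained drive, the time-matched wrist
   samples form a cloud of points in 3-D acceleration space. After a
   per-axis 1st–99th centile trim, the cloud is summarised by the volume of
   its convex hull (in g³): the smallest polyhedron enclosing the
   trajectory, a scalar descriptor of the spatial envelope the wrist
   explored. The same volume computed from the vehicle logger serves as a
   vehicle-induced-motion reference.
3. **Cohort report** — per-participant volumes are summarised (mean,
   median, SD, quartiles, IQR), atypically high movers are flagged with the
   Tukey upper fence Q3 + 1.5·IQR, and normality is assessed
   (Shapiro–Wilk, sample skewness) with a log₁₀-transform comparison.

Because raw study recordings of this kind are typically restricted, the
package ships a first-class **synthetic generator** (`drivehull.synthetic`)
that produces paired wrist/vehicle recordings with scripted ground-truth
drives and events, and a log-normal spread of voluntary wrist amplitude
that reproduces the right-skewed cohort distribution the analysis is built
to describe.

## Worked example

```bash
drivehull run-all --input-dir cohort_in --output-dir cohort_out \
    --seed 1 --n-participants 89
```

simulates an 89-participant cohort, detects drives, computes movement
volumes and writes `cohort_out/cohort_report.json` plus CSV tables
(`segments.csv`, `volumes.csv`, `evolution.csv`, `cohort_report.csv`).
The same run from Python:

```python
from drivehull import PipelineConfig, SimulationParams, run_all

cfg = PipelineConfig(sim=SimulationParams(seed=1, n_participants=89),
                     input_dir="cohort_in", output_dir="cohort_out")
report = run_all(cfg)
w = report["summaries"]["wrist"]
print(w["mean"], w["median"], w["skewness"], w["pct_outliers"])
# 1.997142336347906 0.2612932362883228 6.127132891014145 10.11
```

Reading the numbers: the mean wrist movement volume (≈ 2.0 g³) sits far
above the median (≈ 0.26 g³) because the simulated cohort — like real
movement-volume cohorts — is strongly right-skewed (sample skewness ≈ 6.1);
10.11 % of participants exceed the Tukey upper fence and are flagged as
atypically high movers. The corresponding vehicle-volume summary in the
same report is two to three orders of magnitude smaller, confirming that
the wrist volumes reflect voluntary limb motion rather than vehicle motion.

Per-participant aggregation defaults to the hull of all retained drives
pooled (`--aggregation mean_per_drive` averages per-drive volumes instead);
`--retain-all-active` keeps every active period regardless of event peaks;
`--no-trim` disables the centile trim.

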