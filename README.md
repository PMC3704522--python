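# mitocal

Quantification of excitation-driven mitochondrial remodelling in cultured
myotubes: caffeine-evoked calcium-transient kinetics from Fluo-4
fluorescence traces, mitochondrial morphometry and SR–mitochondrion
contact-site frequency from images or EM-style measurement tables,
dual-channel line-scan colocalization, and the group-comparison statistics
that tie them together. A synthetic-data layer generates traces, object
tables and two-channel image fields with known ground truth, so the whole
pipeline is testable without microscope data.

Intended users: muscle/calcium-signalling labs quantifying
caffeine-response experiments and mitochondria–SR architecture, and anyone
who needs a reproducible, scriptable version of measurements that are
often done by hand.

## The measurements

A transient is modelled as baseline F₀, onset latency after caffeine
application, a linear rise of slope s for duration d (amplitude A = s·d),
and single-exponential recovery with time constant τ:

- caffeine response time (onset latency), time to peak (onset → peak),
- amplitude A (fau) and maximal rise rate ΔF/ΔT = s (fau/s),
- clearance times t_q = τ·ln(1/(1−q)) for q = 25/50/90 %, right-censored
  when the recording ends first.

Morphometry follows the EM caliper convention: 2-D size = length × width
(minimum-area enclosing rectangle on segmented objects); SR contact ⇔
distance ≤ 30 nm (configurable); contact frequency = contacts /
mitochondria. Group comparisons use Student's t (2 groups), one-way ANOVA
(≥ 3) and two-sided Fisher's exact tests for binary outcomes, reported as
mean ± SE with raw p-values. See `docs/methods.md` for the full account.

## Worked example

```python
from mitocal import simulate
from mitocal.kinetics import analyze_transient

params = simulate.TraceParams(
    baseline_f0=100, t_app=30, latency=14, rise_slope=245,
    rise_duration=10, decay_tau=60, duration=400, dt=0.5, noise_sd=0,
)
m = analyze_transient(simulate.simulate_trace(params))
print(f"response time {m.response_time:.1f} s, time to peak "
      f"{m.time_to_peak:.1f} s, amplitude {m.amplitude:.0f} fau,"
      f" dF/dT {m.max_rate:.0f} fau/s")
print(f"t25 {m.t25:.1f} s, t50 {m.t50:.1f} s, t90 {m.t90:.1f} s")
```

prints

```
response time 14.5 s, time to peak 9.5 s, amplitude 2450 fau, dF/dT 245 fau/s
t25 17.3 s, t50 41.6 s, t90 138.2 s
```

Onset is detected one sample (0.5 s) after the true rise begins — the
threshold rule needs a supra-threshold sample — so response time reads
14.5 s for a 14 s latency and time to peak 9.5 s for a 10 s rise. The
clearance times are the analytic τ·ln(4/3), τ·ln 2, τ·ln 10 for τ = 60 s,
recovered by interpolation to within a fraction of a sample.

The numbered drivers under `analysis/` run the full synthetic study
(simulate a cohort → transient kinetics → EM morphometry → image
colocalization → end-to-end report):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_transient_kinetics.py   # e.g. amplitude 536±19 vs 2468±121 fau, p = 5e-26
python analysis/03_em_morphometry.py       # e.g. sizes 0.060/0.076/0.628 µm²; contacts 4% vs 94%, Fisher p = 5e-22
python analysis/04_image_morphometry_coloc.py
python analysis/05_report.py
```

The same stages are available as CLI subcommands (`mitocal
simulate-traces|simulate-em|simulate-images|analyze-traces|morphometry|coloc|compare|report`),
each accepting `--seed`, `--config`, `--outdir`, `--log-level`.

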