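# ribofret

Single-molecule FRET analysis of ribosome function: aa-tRNA selection
kinetics and pre-translocation tRNA-state dynamics.

`ribofret` is a Python library (with a thin CLI) for the analysis chain
used in camera-based smFRET studies of translation. A donor dye on the
P-site tRNA and an acceptor on the incoming aa-tRNA report, frame by frame,
where a single ribosome is in the decoding pathway: initial binding
(FRET ≈ 0.2), GTPase activation (≈ 0.46) and stable accommodation (≈ 0.72).
The package covers every step from raw donor/acceptor intensity traces to
publishable numbers:

* **Synthetic data** — continuous-time Markov simulation of selection and
  pre-translocation dynamics with realistic photophysics (Gaussian channel
  noise, donor blinking, single-step photobleaching) and exact ground
  truth, so every estimator is testable without instrument data.
* **Quality control** — the standard trace-selection gates: one
  catastrophic bleach step, ≥ 8:1 signal/background-noise, ≥ 6:1
  signal/signal-noise, < 4 blinks, donor-acceptor correlation < 0.5.
* **Idealization** — Gaussian-emission hidden Markov models with *fixed*
  state definitions (4-state selection model; 3-state pre-translocation
  model, with a 0.61-FRET classical state for the LD650/Lys dye pair):
  pooled EM for the transition matrix, per-trace Viterbi paths.
* **Selection kinetics** — cumulative arrival distributions fit with a
  double-exponential + stop-flow dead-time model; the dominant fast-phase
  rate, corrected for donor photobleaching, gives the catalytic efficiency

      kcat/KM = (k1 − k_bleach) / [ternary complex]

* **Occupancy** — classical/hybrid-1/hybrid-2 state occupancy from
  hidden-Markov dwell times, cross-checked by three-Gaussian fits to
  trace-averaged FRET histograms.
* **Statistics** — trace-level bootstrap SEMs for every estimator and a
  bootstrap Welch's t-test whose null distribution comes from resampling
  after shifting both distributions to their pooled mean.

## Worked example

```python
import ribofret as rf

# a control-ribosome dataset displaying the Phe (UUC) codon:
# 15 ms frames, 10 nM ternary complex, encoded kcat/KM = 50 uM^-1 s^-1
traces, ground_truth = rf.simulate_dataset("ctrl-phe", n_traces=200, seed=3)

analysis = rf.analyze_selection(traces, seed=3, n_boot=100)
f = analysis.fit
print(f"{analysis.n_passed}/{analysis.n_total} traces passed QC; "
      f"{analysis.n_productive} productive events")
print(f"fit: A1={f.A1:.3f} k1={f.k1:.3f}/s  A2={f.A2:.3f} k2={f.k2:.3f}/s  t0={f.t0:.3f}s")
print(f"donor bleach rate: {f.k_bleach:.4f}/s")
print(f"kcat/KM = {f.kcat_km:.1f} +- {f.sem['kcat_km']:.1f} uM^-1 s^-1")
```

prints

```
194/200 traces passed QC; 155 productive events
fit: A1=0.760 k1=0.622/s  A2=0.039 k2=0.093/s  t0=0.236s
donor bleach rate: 0.0929/s
kcat/KM = 52.9 +- 6.6 uM^-1 s^-1
```

The apparent fast rate k1 = 0.622 /s overstates the true arrival hazard
because photobleaching (0.093 /s here) silently removes molecules before
they can react; subtracting it and dividing by the 0.01 µM ternary-complex
concentration recovers the encoded catalytic efficiency of 50 µM⁻¹s⁻¹
within the bootstrap SEM. The dead time t0 is the stop-flow delivery delay.

The `examples/` directory has one short script per capability (simulation,
QC + idealization, selection kinetics, occupancy, bootstrap comparison);
each prints the numbers it computes and a line on what they mean. The same
stages are available from a shell:

```bash
ribofret all --preset ctrl-phe --n-traces 400 --seed 1 --out runs/ctrl-phe
ribofret all --preset sg24-phe --n-traces 400 --seed 1 --out runs/sg24-phe
ribofret compare --a runs/ctrl-phe --b runs/sg24-phe \
    --estimator kcat_km --n-null 1000000 --out compare.json
```

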