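"""Catalytic efficiency of aa-tRNA selection from cumulative arrivals.

Runs the full kinetics pipeline on a control-Phe dataset: classify
productive events, build the cumulative arrival distribution, fit the
double-exponential + dead-time model, subtract the independently measured
donor bleach rate, and convert the corrected fast-phase rate to kcat/KM.
"""

import ribofret as rf

traceset, _ = rf.simulate_dataset("ctrl-phe", n_traces=200, seed=3)
analysis = rf.analyze_selection(traceset, seed=3, n_boot=100)

f = analysis.fit
print(f"{analysis.n_passed}/{analysis.n_total} traces passed QC; "
      f"{analysis.n_productive} productive events")
print(f"fit: A1={f.A1:.3f} k1={f.k1:.3f}/s  A2={f.A2:.3f} k2={f.k2:.3f}/s  "
      f"t0={f.t0:.3f}s")
print(f"fast phase carries {f.fast_amplitude_fraction:.1%} of the amplitude")
print(f"donor bleach rate (censored MLE over all traces): {f.k_bleach:.4f}/s")
print(f"kcat/KM = (k1 - k_bleach)/[TC] = {f.kcat_km:.1f} "
      f"+- {f.sem['kcat_km']:.1f} uM^-1 s^-1 (bootstrap SEM over traces)")
print("\nthe preset encodes kcat/KM = 50 uM^-1 s^-1; the apparent fast rate")
print("k1 exceeds the true arrival hazard because photobleaching competes")
print("with arrival, which is why the bleach rate is subtracted.")
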