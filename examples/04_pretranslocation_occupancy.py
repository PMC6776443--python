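"""Pre-translocation tRNA-state occupancy, two ways.

Pre-translocation ribosomes exchange between classical (FRET 0.72),
hybrid-1 (0.42) and hybrid-2 (0.22) tRNA configurations. Occupancy is
quantified from hidden-Markov dwell times and, independently, from the
amplitude shares of a three-Gaussian fit to the trace-averaged FRET
histogram; the two estimates should agree.
"""

import numpy as np

import ribofret as rf

traceset, _ = rf.simulate_dataset("pretrans-low", n_traces=250, seed=4)
analysis = rf.analyze_pretranslocation(traceset, seed=4, n_boot=100)

occ = analysis.occupancy
print(f"{analysis.n_passed}/{analysis.n_total} traces passed QC, "
      f"{occ.n_frames} analyzed frames")
for label, frac, sem in zip(occ.state_labels, occ.fractions, occ.sem):
    print(f"  {label:<10} dwell fraction {frac:.1%} +- {sem:.1%}")

hf = analysis.histogram_fit
print("\nthree-Gaussian fit of the FRET histogram:")
print(f"  component means  {np.round(hf.means, 3)}")
print(f"  amplitude shares {np.round(hf.amplitude_shares, 3)}")
print("\nthe preset encodes a 15% classical occupancy; dwell fractions and")
print("Gaussian shares are two routes to the same quantity and should both")
print("land within a point or two of it.")
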