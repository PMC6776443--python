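"""Trace selection and hidden-Markov idealization.

Applies the experimental QC gates (single catastrophic bleach, 8:1 and 6:1
SNR, <4 blinks, donor-acceptor correlation < 0.5) to a simulated dataset,
then idealizes the survivors with the fixed 4-state selection model
(FRET 0.0 / 0.2 / 0.46 / 0.72) and prints one trace's dwell sequence.
"""

import pandas as pd

import ribofret as rf
from ribofret.idealize import idealize_dataset

traceset, _ = rf.simulate_dataset("ctrl-phe", n_traces=60, seed=2)
filtered, report = rf.select_traces(traceset)

print(f"QC: {filtered.n_traces}/{traceset.n_traces} traces pass")
failed = report[~report["passed"]]
if len(failed):
    print("failure reasons:", failed["failure_reasons"].value_counts().to_dict())

bleach = {r.trace_id: (int(r.bleach_frame) if pd.notna(r.bleach_frame) else None)
          for r in report.itertuples(index=False)}
ideal, fit, paths = idealize_dataset(filtered, "selection4", bleach)
print(f"\npooled EM: converged={fit.converged} after {fit.n_iter} sweeps; "
      f"mean state occupancy {fit.occupancy.round(3)}")

tid, path = next(iter(paths.items()))
labels = fit.model.state_labels
print(f"\ndwell sequence of {tid} (state, start frame, frames):")
for state, start, n in path.dwells[:10]:
    print(f"  {labels[state]:<12} {start:>5} {n:>5}")
print("each dwell is a maximal run of one hidden state; the stepwise")
print("0.2 -> 0.46 -> 0.72 progression marks productive tRNA selection.")
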