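"""Simulate one condition and recover its kinetics.

Generates 150 two-state FRET traces of the inter-stem reporter (undocked
E=0.32, docked E=0.57) with docking/undocking rates 0.4/0.22 s^-1, runs
trace selection, shared-emission HMM idealization and dwell-time rate
estimation, and compares the recovered numbers with the ground truth.
"""

from smfretkit.pipeline import analyze_condition
from smfretkit.scenarios import canonical_t99
from smfretkit.synth import render_trace, sample_state_path

import numpy as np

K_DOCK, K_UNDOCK = 0.4, 0.22
scenario = canonical_t99()

traces = []
for i, sub in enumerate(np.random.SeedSequence(11).spawn(150)):
    rng = np.random.default_rng(sub)
    path = sample_state_path(K_DOCK, K_UNDOCK, scenario.duration, rng)
    tr = render_trace(path, scenario, rng)
    tr.molecule_id = i
    traces.append(tr)

res = analyze_condition(traces, seed=0, with_rates=True)

print(f"accepted traces        : {res.n_accepted}/{res.n_total}")
print(f"emission means (E)     : {res.model.emission_means.round(3)}  (truth 0.32, 0.57)")
print(f"docked occupancy       : {res.occupancy:.3f}  (truth {K_DOCK/(K_DOCK+K_UNDOCK):.3f})")
print(f"k_dock                 : {res.rates.k_dock:.3f} /s  (truth {K_DOCK})")
print(f"k_undock               : {res.rates.k_undock:.3f} /s  (truth {K_UNDOCK})")
lo, hi = res.rates.ci_undock
print(f"k_undock 95% CI        : [{lo:.3f}, {hi:.3f}] /s (bootstrap over traces)")
print("\nOccupancy is the fraction of idealized frames in the docked state;")
print("rates come from censored-ML exponential fits of the dwell times.")
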