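"""tRNA binding isotherm and dissociation constant.

Simulates the inter-stem reporter across tRNA concentrations (1 nM - 2 uM;
pseudo-first-order binding makes the stationary docked fraction an exact
isotherm with K_d = 40 nM), runs the occupancy pipeline and fits the
isotherm.
"""

from smfretkit.pipeline import fit_titration, titration_occupancy
from smfretkit.scenarios import TRNA_LEVELS, canonical_t99
from smfretkit.synth import make_titration_dataset

dataset = make_titration_dataset(canonical_t99(), "tRNA", TRNA_LEVELS,
                                 n_traces=100, seed=31)
table = titration_occupancy(dataset, seed=2)
fit = fit_titration(table, "tRNA")

print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"\nK_d = {fit.midpoint:.1f} nM (generating 40 nM)")
print("At [tRNA] = K_d the molecule spends half its time docked; the high")
print("concentrations are rate-blurred (sub-frame binding events), which the")
print("shared-emission HMM tolerates because the docked state dominates there.")
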