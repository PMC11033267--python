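"""Generate a study-scale synthetic community and summarize it.

Draws 213 children in 70 households, allocates 6507 directed dyadic events
over the 19 behavior categories from known intercepts, and prints the
descriptive tallies: per-child and per-household occurrence counts (each
event credits both participants) and the same/different-household contrast
in events per directed dyad.
"""

import numpy as np

from dyadmnl import dyad_descriptives
from dyadmnl.synthetic import (
    SimulationConfig,
    draw_truth,
    simulate_community,
    simulate_observations,
)

cfg = SimulationConfig(seed=1)
roster = simulate_community(cfg)
truth = draw_truth(
    cfg,
    {
        "alpha": np.linspace(1.2, -0.6, 18),  # a realistic frequency gradient
        "scale_I": 0.4 * np.ones(18),
        "scale_R": 0.4 * np.ones(18),
    },
)
events, ledger = simulate_observations(roster, truth, cfg)
out = dyad_descriptives(events, roster)

print(f"children: {out.n_children}, households: {out.n_households}, events: {out.n_events}")
print(f"occurrences per child:     mean {out.per_child[0]:.2f}, SD {out.per_child[1]:.2f}")
print(f"occurrences per household: mean {out.per_household[0]:.2f}, SD {out.per_household[1]:.2f}")
same = ledger[ledger.same_household]["n_events"].mean()
diff = ledger[~ledger.same_household]["n_events"].mean()
print(f"events per directed dyad: same household {same:.2f}, different {diff:.2f}")
print("-> the per-child mean equals 2 * events / children; same-household dyads")
print("   are observed together far more often, as in the field data.")
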