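"""Generate a growing planted-partition graph and inspect its snapshots.

The generator plants k communities and, at every step, wires previously
unconnected pairs with probability p_in inside a community and p_out
between communities.  Snapshots are cumulative, so the adjacency support
grows monotonically; the temporal influence matrix discounts each edge by
the exponential of its age.
"""

import numpy as np

from temporalign import (DecayConfig, SimConfig, build_snapshots,
                         simulate_dynamic_sbm, temporal_influence)

cfg = SimConfig(n=100, k=4, T=6, p_in=0.08, p_out=0.008, seed=42)
g = simulate_dynamic_sbm(cfg)
print(g)

snaps = build_snapshots(g, T=6)
counts = [int((A != 0).sum() // 2) for A in snaps.A]
print("edges per cumulative snapshot:", counts)
# counts grow monotonically: edges are only ever added

influence = temporal_influence(snaps, 5, DecayConfig(mode="per_edge"))
fresh = influence[snaps.edge_time[5] == 6].max() if (snaps.edge_time[5] == 6).any() else None
print("max decayed entry of a step-6 edge:", round(float(fresh), 4))
old_mask = snaps.edge_time[5] == 1
print("max decayed entry of a step-1 edge:",
      round(float(influence[old_mask].max()), 4))
# the older an edge, the smaller its decayed influence: e^{-age - eps}
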