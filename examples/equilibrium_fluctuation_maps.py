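"""Average and fluctuation contact maps of a quasi-equilibrium trajectory.

Builds a small synthetic trajectory whose residue pairs jitter around
fixed distances, then computes the per-pair mean and standard deviation of
the clamped interresidue distance — the contact-based analogue of RMSF:
pairs with large σ are the mobile parts of the structure, without any
coordinate fitting.
"""

import numpy as np

from mdcontacts import (FixtureSpec, aggregate, build_pair_store, make_frames,
                        select_atoms)

spec = FixtureSpec(scenario="static", n_residues=6, n_frames=500,
                   noise_sigma=0.01, seed=0)
topology, frames, _ = make_frames(spec)
selection = select_atoms(topology, "heavy")
store = build_pair_store(frames, selection)
agg = aggregate(store)

print(f"{store.n_pairs} live pairs over {store.n_frames} frames")
print("pair    mean(nm)  sigma(nm)  contact fraction")
for p, (i, j) in enumerate(agg.pairs):
    print(f"({i},{j})   {agg.mean_distance[p]:.3f}     "
          f"{agg.std_distance[p]:.4f}     {agg.contact_fraction[p]:.2f}")

# The mean map tracks the scripted geometry (0.4 nm between neighbours,
# 0.8 nm at |i-j| = 2) minus the small downward bias of taking a minimum
# over noisy atom pairs; sigma ~ sqrt(2) * 0.01 nm reflects only the imposed
# positional noise, and contact fraction is 1 for pairs inside the 0.5 nm
# interaction cutoff and 0 beyond it.
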