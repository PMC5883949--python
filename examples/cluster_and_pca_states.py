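"""Identifying conformational states by contact-RMSD clustering and PCA.

A two-state trajectory switches its dimer geometry halfway through the
run.  The inter-frame contact RMSD (no fitting, no average structure)
feeds hierarchical clustering with medoids; PCA of the same pair-distance
vectors separates the two states on the first component.
"""

import numpy as np

from mdcontacts import (FixtureSpec, build_pair_store, cluster_frames,
                        interframe_rmsd, make_frames, pca, select_atoms)

spec = FixtureSpec(scenario="two_state", n_frames=100, noise_sigma=0.01,
                   seed=4)
topology, frames, gt = make_frames(spec)
store = build_pair_store(frames, select_atoms(topology, "heavy"))

fdm = interframe_rmsd(store)
cl = cluster_frames(fdm, k=2, linkage_method="average")
agree = (cl.labels == gt.state_sequence).mean()
print(f"cluster labels match the scripted state sequence on "
      f"{100 * max(agree, 1 - agree):.0f}% of frames")
for c, m in enumerate(cl.medoids):
    members = int((cl.labels == c).sum())
    print(f"cluster {c}: {members} frames, medoid frame {m} "
          f"(t = {store.times[m]:.0f} ps)")

pr = pca(store, 2)
print(f"PC1 explains {100 * pr.explained_variance_ratio[0]:.1f}% of the "
      f"contact-map variance")
s0 = pr.projections[gt.state_sequence == 0, 0]
s1 = pr.projections[gt.state_sequence == 1, 0]
print(f"PC1 projections: state A in [{s0.min():.2f}, {s0.max():.2f}] nm, "
      f"state B in [{s1.min():.2f}, {s1.max():.2f}] nm")

# With a 0.3 nm state separation and 0.01 nm positional noise the clustering
# recovers the scripted states exactly and PC1 carries essentially all the
# variance, with the two states projecting to disjoint intervals.
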