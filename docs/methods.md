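# Methods

## Model

The unit of analysis is the residue pair.  For a frame at time *t* and a
pair (*i*, *j*), the engine computes the minimum Euclidean distance over
all selected-atom cross pairs and clamps it at the main cutoff:

    r_ij(t) = min_d   if min_d < r_cut
              r_cut   otherwise.

A pair is **live** once its minimum falls strictly below `r_cut` in any
frame; only live pairs are stored (sparse in the pair dimension, dense in
the frame dimension).  Frames before a pair's first sub-cutoff encounter
are backfilled with exactly `r_cut` — correct by definition of first
encounter.  Ties at exactly `r_cut` count as *outside* the cutoff,
matching the strict case split of the clamping rule.

Distances are plain Euclidean: no minimum-image or periodic-boundary
correction is applied.  Trajectories are expected to be pre-processed so
molecules are whole; this is stated rather than guessed because the
distance definition itself is silent on periodicity.

**Atom classes.**  `heavy` (non-hydrogen; the default, which shrinks the
search space ~4× with little information loss), `c_alpha` (atoms named
CA), `backbone` (heavy N/CA/C/O), `side_chain` (heavy minus backbone; a
glycine has none and becomes *inert* — excluded from every pair), `all`.
By construction backbone ∪ side_chain = heavy with empty intersection.

**Contact states (hysteresis).**  Two thresholds `r_inter ≤ r_inter_high
≤ r_cut`: a contact switches on when `d < r_inter` (strict), off when
`d > r_inter_high` (strict), and otherwise carries its previous state.
With equal thresholds this reduces to plain thresholding.  The dual form
prevents a few outlier frames from under-counting the stability of an
interaction; on any distance series it can only reduce, never increase,
the number of on→off transitions relative to the single cutoff (a
property test asserts this on random walks).  The state at frame 0 is the
plain `r_inter` threshold; a first distance inside the
`[r_inter, r_inter_high]` band therefore starts *off* — the convention is
logged, and the encounter-time maps accept a switch to non-hysteretic
thresholding.

**Defaults.**  `r_cut = 1.0 nm`, `r_inter = r_inter_high = 0.5 nm`, atom
class `heavy`, `min_seq_separation = 1` (only the diagonal excluded, so
near-diagonal secondary-structure signal is kept), frame times from the
trajectory when present, otherwise `frame_index × dt` with `dt = 1 ps`.

## Storage precision

The store's dtype is selectable (`float64` default, `float32`, or
`float16` for memory-constrained long trajectories; `float16` still
guarantees about three significant decimal digits, and values in
(0, r_cut] are well inside its range).  The default is full precision so
that downstream statistics are limited by the method, not the container;
aggregate statistics are *always* accumulated in float64 regardless of
the store dtype.  Economy mode (below) avoids per-frame storage entirely.

## Economy mode

`build_pair_store(..., mode="economy")` performs the identical
live-pair discovery in a single pass but keeps only the current frame's
distances plus per-pair running statistics: Welford mean/M2, minimum,
hysteretic state, on-counts and first/last on-times.  A pair discovered
at frame *f* initialises its accumulator as if it had seen *f* copies of
`r_cut` (exact, by the backfill argument).  Memory is independent of the
frame count; a high-water counter (`max_resident_frames`, always 1) makes
the contract assertable.  Full-mode and economy-mode aggregates agree to
float64 round-off on the same input; the suite checks ≤ 0.002 nm on
means and ≤ 0.005 nm on σ, which also holds when a reduced store dtype
is used on the full-mode side.

## Statistics

* σ is the **population** (1/N) standard deviation — N is the full frame
  count of the analysis window, and no inference to a larger ensemble is
  implied.
* Contact fraction is the mean of the boolean hysteretic state, exactly.
* Encounter times: first/last frame with state on; never-on pairs carry
  NaN; pairs on at the final frame are *persistent* (last encounter =
  final time plus a flag, rendered as the −1 sentinel in matrices so
  unbroken contacts cannot be misread as late ruptures).
* Pearson correlations are computed on the clamped series (what the store
  holds), optionally restricted to frames with `d < r_cut`.  Zero-variance
  series give **NaN**, never 0 — an undefined correlation must not imitate
  "no change".  Negative distance-vs-time r means approach (formation),
  positive means separation (rupture).
* Contact-count cross-correlation: `n_i(t)` counts the live pairs
  involving residue *i* whose state is on; `C = Pearson(n_i, n_j)` is
  computed as a normalised Gram matrix and symmetrised exactly.
* Differential maps: per-pair mean over window B minus window A
  (inclusive time ranges); antisymmetric under swap by construction.

## Inter-frame RMSD, clustering, PCA

The frame-frame distance is

    D[a,b] = sqrt( (1/P) Σ_p (d_p(a) − d_p(b))² )

over the P live pairs — a Euclidean norm scaled by 1/√P, hence a true
metric (symmetry, identity, triangle inequality), and a drop-in,
fitting-free alternative to coordinate RMSD.  Hierarchical clustering
runs on D (scipy linkage; average linkage by default; scipy's
deterministic tie-breaking), cut at k clusters or at a merge height.
Labels are renumbered by first frame occurrence; medoids minimise the
within-cluster distance sum with ties to the lowest frame index.  Nothing
is randomised, so identical inputs give identical results.

PCA mean-centers the (frames × pairs) matrix and eigendecomposes the
population covariance; when there are more live pairs than frames the
frames×frames Gram matrix is decomposed instead, with identical results
(asserted against the direct route).  All eigenvalues are retained so
their sum equals the total variance; each component's largest-magnitude
loading is made positive (deterministic sign).  A flag switches the input
from clamped distances to 0/1 contact states — distances are the default
because they carry strictly more information.

Residue clustering takes per-residue feature rows — rows of the
mean-distance matrix, of the last-encounter matrix, or of the
cross-correlation matrix — and clusters them with Euclidean agglomerative
linkage.  For the last-encounter features, persistent entries map to the
final frame time and never-live entries to 0, keeping the rows in a
meaningful metric space; inert residues get the reserved label −1.

## Synthetic fixtures

All test inputs are generated, never downloaded.  Residue centers live in
the x–y plane; each residue's atoms are stacked along z with the same
offset pattern, so the minimum interatomic distance between two residues
equals their center distance *exactly* before noise — every scenario's
distance schedule is therefore exact ground truth.  Scenarios: `static`
(all distances constant), `linear_drift` (one pair strictly linear in
time), `two_state` (dimer pairs 0.4 vs 0.7 nm, a 0.3 nm separation across
≥ 3 pairs, switching at mid-run), `scripted_unfolding` (dimer pairs jump
from 0.4 to 1.5 nm at scheduled frames; the last pair persists),
`competitive_switch` (residue A alternates partners B and C in
antiphase).  Noise is Gaussian on atom positions (per axis), giving each
pair distance a fluctuation ≈ √2·σ and a small downward bias from the
minimum over k² atom pairs, bounded to first order by
√2·σ·√(2·ln k²) + 2σ²/d; `reference_stats` folds these bounds into its
tolerances.  A seed fully determines the output — files are byte-identical
across runs.

What the fixtures do *not* emulate: force-field physics, solvent,
correlated collective motion, periodic boxes.  Passing tests demonstrate
the correctness of the machinery on exactly known kinetics, not the
biological findings obtainable from real trajectories.

Default study sizes (6–12 residues, 1–4 atoms per residue, 100–2000
frames, noise σ = 0.005–0.02 nm) were chosen as the smallest systems in
which every scenario's signal is unambiguous by construction.

## Input/output conventions

Coordinates are nm internally; PDB Å are divided by 10 on read.  Residue
identity is (chain, residue number); insertion codes are rejected,
altloc 'A'/' ' kept and others dropped with a warning.  HETATM records
become their own residues unless excluded via the restriction file.
Matrices are written 1-based in the three-column `i j value` format with
`#` headers naming semantics, size and sentinels; diagonals carry the
field's null value.  Sequential data (distances, times) render with
cubehelix; divergent data (correlations, differentials) with PuOr whose
midpoint is pinned exactly at 0.  Video assembly is an optional wrapper
over an external encoder (probed at runtime) and never a dependency of
the analysis.

## Known limitations

* No periodic-boundary handling: broken molecules at box edges produce
  wrong distances (pre-process trajectories first).
* Element inference from atom names resolves one-letter elements only;
  provide element columns for ions such as Cl/Na.
* The agglomeration tie-break among exactly equal merge heights is
  scipy's, not a lexicographic rule; it is deterministic, which is the
  property that matters.
* Binary trajectory reading requires MDAnalysis; the plain frame format
  and multi-model PDB cover the dependency-free path.
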