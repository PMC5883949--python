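"""Synthetic desk-scale fixtures with exactly known contact kinetics.

Every test input is generated programmatically from a :class:`FixtureSpec`:
a toy topology plus a scripted trajectory in which the intended
interresidue distance schedule holds *exactly* before noise.

Geometry trick: residue centers live in the x-y plane and each residue's
atoms are stacked along z with the identical offset pattern
(0, 0.05, 0.10, ... nm).  Because the atom offsets are perpendicular to
every center-center separation and equal across residues, the minimum
interatomic distance between two residues equals their center distance
exactly — atom pairs with unequal z offsets are strictly farther.  Gaussian
noise, when requested, is applied to atom positions (not distances), so
observed distances carry a noise of standard deviation ≈ sqrt(2)·σ per
coordinate pair plus a small positive bias from taking the minimum over
atom pairs; :func:`reference_stats` states first-order tolerance bounds.

Scenarios
---------
static              all pair distances constant (residues on a line).
linear_drift        one pair's distance strictly linear in time.
two_state           dimer pairs switch between two geometries ≥ 0.3 nm apart.
scripted_unfolding  dimer pairs jump beyond the cutoff at scheduled frames.
competitive_switch  residue A alternates partners B and C in antiphase.

A given seed fully determines the output (byte-identical files on re-run);
there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from .trajectory_io import Frame, Topology, write_pdb, write_plain_trajectory

__all__ = ["FixtureSpec", "GroundTruth", "make_frames", "make_fixture",
           "reference_stats", "topology_from_centers"]

SCENARIOS = ("static", "linear_drift", "two_state", "scripted_unfolding",
             "competitive_switch")

#: z spacing of the atoms within one residue (nm)
_ATOM_DZ = 0.05
#: y offset separating independent residue groups (nm); far beyond any cutoff
_GROUP_DY = 6.0
#: heavy-atom names assigned within a residue (first is always CA)
_ATOM_NAMES = ("CA", "CB", "CG", "CD", "CE", "CZ", "CH", "CI")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic trajectory.

    Distances are nm, times ps.  ``noise_sigma`` is the per-axis Gaussian
    displacement applied to every atom position.  Defaults mirror the
    standard contact conventions: contacts scripted at 0.4 nm (inside the
    0.5 nm interaction cutoff), broken pairs at 1.5 nm (outside the 1.0 nm
    main cutoff), and the two-state geometries 0.3 nm apart.
    """

    scenario: str
    n_residues: int = 6
    atoms_per_residue: int = 3
    n_frames: int = 100
    dt: float = 1.0
    noise_sigma: float = 0.0
    seed: int = 0
    contact_distance: float = 0.4
    far_distance: float = 1.5
    drift_start: float = 0.9
    drift_rate: float = 0.004          # nm per ps, linear_drift only
    state_b_distance: float = 0.7      # two_state: state A is contact_distance
    rupture_schedule: Optional[dict[int, int]] = None  # pair rank -> frame
    block_length: int = 10             # competitive_switch

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_frames < 1 or self.n_residues < 2:
            raise ValueError("need at least 1 frame and 2 residues")
        if not (1 <= self.atoms_per_residue <= len(_ATOM_NAMES)):
            raise ValueError(f"atoms_per_residue must be in [1, {len(_ATOM_NAMES)}]")
        # noise must not be able to defeat the scripted schedules: the
        # tightest margin is contact (0.4) vs r_inter (0.5); 6 sigma of the
        # pairwise distance noise (sqrt(2) sigma) must fit inside it
        if 6.0 * np.sqrt(2.0) * self.noise_sigma > 0.25:
            raise ValueError(
                f"noise_sigma={self.noise_sigma} nm is geometrically "
                "unsatisfiable: scripted contact schedules could be violated")
        if self.scenario == "linear_drift":
            d_end = self.drift_start - self.drift_rate * (self.n_frames - 1) * self.dt
            if d_end <= 0.1:
                raise ValueError("linear drift would collapse the pair "
                                 f"(final distance {d_end:.3f} nm)")
        if self.scenario == "competitive_switch" and self.n_residues < 3:
            raise ValueError("competitive_switch needs >= 3 residues")


@dataclass
class GroundTruth:
    """Exact pre-noise schedules of a fixture, for direct assertion.

    ``center_distance[f]`` is the (R, R) matrix of scripted center
    distances at frame ``f`` (callable to stay cheap for long runs).
    """

    scenario: str
    pairs: list[tuple[int, int]]                  # the scripted live pairs
    center_distance: Callable[[int], np.ndarray]
    times: np.ndarray
    state_sequence: Optional[np.ndarray] = None   # two_state: 0/1 per frame
    rupture_frame: Optional[dict[tuple[int, int], Optional[int]]] = None
    drift_pair: Optional[tuple[int, int]] = None
    switch_residues: Optional[tuple[int, int, int]] = None
    block_length: Optional[int] = None


def topology_from_centers(n_residues: int, atoms_per_residue: int) -> Topology:
    """Toy all-carbon topology: one ALA-like residue per center."""
    names, elements, res_of = [], [], []
    residues = []
    for r in range(n_residues):
        residues.append(("A", r + 1, "ALA"))
        for a in range(atoms_per_residue):
            names.append(_ATOM_NAMES[a])
            elements.append("C")
            res_of.append(r)
    return Topology(atom_names=tuple(names), elements=tuple(elements),
                    atom_residue=np.asarray(res_of, dtype=np.intp),
                    residues=tuple(residues))


def _dimer_groups(n_residues: int) -> list[tuple[int, int]]:
    return [(2 * g, 2 * g + 1) for g in range(n_residues // 2)]


def _centers_fn(spec: FixtureSpec):
    """Return (centers(frame) -> (R, 2) array, GroundTruth skeleton data)."""
    R = spec.n_residues
    d0 = spec.contact_distance

    if spec.scenario == "static":
        base = np.column_stack([d0 * np.arange(R), np.zeros(R)])

        def centers(_f: int) -> np.ndarray:
            return base

        return centers, {"pairs": [(i, j) for i in range(R) for j in range(i + 1, R)]}

    if spec.scenario == "linear_drift":
        def centers(f: int) -> np.ndarray:
            c = np.column_stack([np.zeros(R), _GROUP_DY * np.arange(R)])
            c[1] = (spec.drift_start - spec.drift_rate * f * spec.dt, 0.0)
            return c

        return centers, {"pairs": [(0, 1)], "drift_pair": (0, 1)}

    if spec.scenario == "two_state":
        pairs = _dimer_groups(R)
        half = spec.n_frames // 2
        state_seq = (np.arange(spec.n_frames) >= half).astype(np.intp)

        def centers(f: int) -> np.ndarray:
            d = d0 if state_seq[f] == 0 else spec.state_b_distance
            c = np.zeros((R, 2))
            for g, (i, j) in enumerate(pairs):
                c[i] = (0.0, _GROUP_DY * g)
                c[j] = (d, _GROUP_DY * g)
            for r in range(2 * len(pairs), R):  # odd leftover residue: isolated
                c[r] = (0.0, _GROUP_DY * (len(pairs) + r))
            return c

        return centers, {"pairs": pairs, "state_sequence": state_seq}

    if spec.scenario == "scripted_unfolding":
        pairs = _dimer_groups(R)
        schedule = spec.rupture_schedule
        if schedule is None:
            # pair g breaks at frame 10*(g+1); the last pair never breaks
            schedule = {g: 10 * (g + 1) for g in range(len(pairs) - 1)}
        for g, f in schedule.items():
            if not (0 <= g < len(pairs)):
                raise ValueError(f"rupture schedule names pair rank {g}, "
                                 f"only {len(pairs)} dimer pairs exist")
            if not (0 <= f < spec.n_frames):
                raise ValueError(f"rupture frame {f} outside trajectory")
        rupture = {pairs[g]: schedule.get(g) for g in range(len(pairs))}

        def centers(f: int) -> np.ndarray:
            c = np.zeros((R, 2))
            for g, (i, j) in enumerate(pairs):
                broken = schedule.get(g) is not None and f > schedule[g]
                d = spec.far_distance if broken else d0
                c[i] = (0.0, _GROUP_DY * g)
                c[j] = (d, _GROUP_DY * g)
            for r in range(2 * len(pairs), R):
                c[r] = (0.0, _GROUP_DY * (len(pairs) + r))
            return c

        return centers, {"pairs": pairs, "rupture_frame": rupture}

    # competitive_switch
    def centers(f: int) -> np.ndarray:
        c = np.column_stack([np.zeros(R), _GROUP_DY * (1 + np.arange(R))])
        b_near = (f // spec.block_length) % 2 == 0
        c[0] = (0.0, 0.0)
        c[1] = (d0 if b_near else spec.far_distance, 0.0)
        c[2] = (-(spec.far_distance if b_near else d0), 0.0)
        return c

    return centers, {"pairs": [(0, 1), (0, 2)], "switch_residues": (0, 1, 2),
                     "block_length": spec.block_length}


def make_frames(spec: FixtureSpec) -> tuple[Topology, list[Frame], GroundTruth]:
    """Generate the fixture in memory: topology, frames and ground truth."""
    topology = topology_from_centers(spec.n_residues, spec.atoms_per_residue)
    centers, gt_kw = _centers_fn(spec)
    rng = np.random.default_rng(spec.seed)
    n_atoms = topology.n_atoms
    zoff = _ATOM_DZ * np.arange(spec.atoms_per_residue)
    frames: list[Frame] = []
    times = spec.dt * np.arange(spec.n_frames)
    for f in range(spec.n_frames):
        c = centers(f)
        coords = np.empty((n_atoms, 3))
        a = 0
        for r in range(spec.n_residues):
            for m in range(spec.atoms_per_residue):
                coords[a] = (c[r, 0], c[r, 1], zoff[m])
                a += 1
        if spec.noise_sigma > 0:
            coords = coords + rng.normal(0.0, spec.noise_sigma, coords.shape)
        frames.append(Frame(index=f, time=float(times[f]), coords=coords))

    def center_distance(f: int) -> np.ndarray:
        c = centers(f)
        diff = c[:, None, :] - c[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=-1))

    gt = GroundTruth(scenario=spec.scenario, center_distance=center_distance,
                     times=times, **gt_kw)
    return topology, frames, gt


def make_fixture(spec: FixtureSpec, outdir: str | Path
                 ) -> tuple[Path, Path, GroundTruth]:
    """Write the fixture to disk: a PDB topology and a plain trajectory.

    Returns (topology_path, trajectory_path, ground_truth).  The same spec
    and seed produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    topology, frames, gt = make_frames(spec)
    top_path = outdir / f"{spec.scenario}_top.pdb"
    traj_path = outdir / f"{spec.scenario}_traj.dat"
    write_pdb(top_path, topology, frames[0].coords)
    write_plain_trajectory(traj_path, [fr.time for fr in frames],
                           [fr.coords for fr in frames])
    return top_path, traj_path, gt


def reference_stats(gt: GroundTruth, spec: FixtureSpec) -> dict:
    """Analytically expected values (with noise-aware tolerances) per scenario.

    Tolerances use the first-order propagation: a center distance measured
    between noisy atom clouds has standard deviation ≈ sqrt(2)·σ and a
    positive bias from the min over k² atom pairs bounded (for the small k
    used here) by ≈ sqrt(2)·σ·sqrt(2·ln(k²)) plus the 2σ²/d curvature term.
    """
    s = spec.noise_sigma
    k = spec.atoms_per_residue
    sd = np.sqrt(2.0) * s
    bias = sd * np.sqrt(2.0 * np.log(max(k * k, 2))) + (
        2 * s ** 2 / spec.contact_distance if s else 0.0)
    out: dict = {"distance_noise_std": sd, "distance_bias_bound": bias}
    if gt.scenario == "static":
        out["sigma_expected"] = 0.0 if s == 0 else sd
        out["sigma_tol"] = 0.0 if s == 0 else 3.0 * sd
        d0 = gt.center_distance(0)
        out["contact_fraction"] = {
            (i, j): 1.0 if d0[i, j] < 0.5 else 0.0 for (i, j) in gt.pairs}
    elif gt.scenario == "linear_drift":
        out["time_pearson"] = {"pair": gt.drift_pair, "expected": -1.0,
                               "tol": 0.0 if s == 0 else 0.05}
    elif gt.scenario == "two_state":
        out["expected_ari"] = 1.0
        out["pc1_min_variance_fraction"] = 0.9
        out["state_separation"] = abs(spec.state_b_distance - spec.contact_distance)
    elif gt.scenario == "scripted_unfolding":
        out["last_encounter_ps"] = {
            pair: (None if f is None else f * spec.dt)
            for pair, f in gt.rupture_frame.items()}
        out["persistent_pairs"] = [p for p, f in gt.rupture_frame.items()
                                   if f is None]
    elif gt.scenario == "competitive_switch":
        out["anticorrelated_residues"] = gt.switch_residues[1:]
        out["expected_sign"] = -1.0
    return out
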