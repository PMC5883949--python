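"""Per-pair summary maps: mean/σ distance, contact fraction, encounter times,
and differential maps between trajectory windows.

The σ map is the contact-based analogue of coordinate RMSF: it reports the
fluctuation of each interresidue distance (restricted to pairs that ever
came within the main cutoff) without any structural fitting.  σ uses the
population (1/N) convention.

Last-encounter maps are the rupture-time maps of pulling simulations: the
time of the last frame in which a pair was in (hysteretic) contact.  Pairs
still in contact at the final frame are flagged *persistent* and carry a
distinct sentinel in matrix output so unbroken contacts are not misread as
late ruptures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .contact_engine import ContactTimeline, ResiduePairStore, contact_states

__all__ = [
    "AggregateMap",
    "DifferentialMap",
    "aggregate",
    "encounter_times",
    "differential_map",
    "pairs_to_matrix",
    "PERSISTENT_SENTINEL",
]

#: value written for persistent (never-broken) pairs in last-encounter matrices;
#: valid times are >= 0 so -1 cannot collide.
PERSISTENT_SENTINEL = -1.0


@dataclass
class AggregateMap:
    """Streaming-safe per-pair summary statistics over a trajectory.

    first/last encounter are NaN for pairs whose hysteretic state was never
    on.  ``max_resident_frames`` is populated by economy-mode builds and
    records the high-water mark of frames resident in memory (always 1).
    """

    pairs: np.ndarray            # (P, 2)
    n_residues: int
    n_frames: int
    r_cut: float
    mean_distance: np.ndarray
    std_distance: np.ndarray
    min_distance: np.ndarray
    contact_fraction: np.ndarray
    first_encounter: np.ndarray
    last_encounter: np.ndarray
    persistent: np.ndarray       # bool: in contact at the final frame
    final_time: float
    max_resident_frames: Optional[int] = None

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def matrix(self, field: str) -> np.ndarray:
        """Full symmetric n_residues × n_residues matrix of one statistic.

        Never-live pairs carry sentinels matching their "disregarded"
        semantics: clamped distance fields fill with r_cut, fractions with 0,
        encounter times with NaN.  The diagonal is the field's null value
        (0 for distances and fractions, NaN for times).
        """
        spec = {
            "mean_distance": (self.mean_distance, self.r_cut, 0.0),
            "std_distance": (self.std_distance, 0.0, 0.0),
            "min_distance": (self.min_distance, self.r_cut, 0.0),
            "contact_fraction": (self.contact_fraction, 0.0, 0.0),
            "first_encounter": (self.first_encounter, np.nan, np.nan),
            "last_encounter": (self._last_with_sentinel(), np.nan, np.nan),
        }
        if field not in spec:
            raise KeyError(field)
        values, fill, diag = spec[field]
        return pairs_to_matrix(self.pairs, values, self.n_residues, fill, diag)

    def _last_with_sentinel(self) -> np.ndarray:
        out = self.last_encounter.copy()
        out[self.persistent] = PERSISTENT_SENTINEL
        return out


@dataclass
class DifferentialMap:
    """Per-pair change of mean clamped distance, window B minus window A."""

    pairs: np.ndarray
    n_residues: int
    delta_mean_distance: np.ndarray
    window_a: tuple[float, float]
    window_b: tuple[float, float]

    def matrix(self) -> np.ndarray:
        # never-live pairs did not change: fill 0, null diagonal 0
        return pairs_to_matrix(self.pairs, self.delta_mean_distance,
                               self.n_residues, 0.0, 0.0)


def pairs_to_matrix(pairs: np.ndarray, values: np.ndarray, n_residues: int,
                    fill: float, diag: float) -> np.ndarray:
    """Scatter per-pair values into a symmetric square matrix."""
    m = np.full((n_residues, n_residues), fill, dtype=np.float64)
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        m[i, j] = values
        m[j, i] = values
    np.fill_diagonal(m, diag)
    return m


def aggregate(store: ResiduePairStore,
              timeline: ContactTimeline | None = None) -> AggregateMap:
    """Per-pair mean/σ/min clamped distance, contact fraction and encounter
    times from a full store.

    Matches economy-mode streaming aggregation (built by
    :func:`~mdcontacts.contact_engine.build_pair_store`) within the store's
    precision.  σ is the population standard deviation.
    """
    if store.n_frames == 0:
        raise ValueError("empty store")
    if timeline is None:
        timeline = contact_states(store)
    d = store.distances()
    mean = d.mean(axis=1) if store.n_pairs else np.empty(0)
    std = d.std(axis=1) if store.n_pairs else np.empty(0)
    minv = d.min(axis=1) if store.n_pairs else np.empty(0)
    frac = timeline.states.mean(axis=1) if store.n_pairs else np.empty(0)
    first, last, persistent = encounter_times(timeline)
    return AggregateMap(
        pairs=store.pairs, n_residues=store.n_residues, n_frames=store.n_frames,
        r_cut=store.cutoffs.r_cut, mean_distance=mean, std_distance=std,
        min_distance=minv, contact_fraction=frac,
        first_encounter=first, last_encounter=last, persistent=persistent,
        final_time=float(store.times[-1]))


def encounter_times(timeline: ContactTimeline
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First and last on-times per pair, plus the persistent flag.

    Returns (first, last, persistent); first/last are NaN for pairs never on,
    and a pair on at the final frame has last = final time and
    persistent = True.
    """
    states = timeline.states
    times = np.asarray(timeline.times, dtype=np.float64)
    P = states.shape[0]
    first = np.full(P, np.nan)
    last = np.full(P, np.nan)
    for p in range(P):
        on = np.flatnonzero(states[p])
        if len(on):
            first[p] = times[on[0]]
            last[p] = times[on[-1]]
    persistent = states[:, -1].copy() if states.size else np.zeros(P, dtype=bool)
    return first, last, persistent


def differential_map(store: ResiduePairStore,
                     window_a: tuple[float, float],
                     window_b: tuple[float, float]) -> DifferentialMap:
    """Mean clamped distance over window B minus over window A, per pair.

    Windows are inclusive time ranges in ps; antisymmetric under swap.
    """
    times = store.times
    masks = {}
    for name, (lo, hi) in (("window_a", window_a), ("window_b", window_b)):
        m = (times >= lo) & (times <= hi)
        if not m.any():
            raise ValueError(f"{name} [{lo}, {hi}] ps contains no frames")
        masks[name] = m
    d = store.distances()
    delta = d[:, masks["window_b"]].mean(axis=1) - d[:, masks["window_a"]].mean(axis=1)
    return DifferentialMap(pairs=store.pairs, n_residues=store.n_residues,
                           delta_mean_distance=delta,
                           window_a=tuple(window_a), window_b=tuple(window_b))
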