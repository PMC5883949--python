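"""Clamped interresidue minimum distances and hysteretic contact states.

The central quantity is the clamped minimum distance between the selected
atoms of two residues,

    r_ij(t) = min_atoms d        if min_atoms d < r_cut
              r_cut              otherwise,

so every stored value lies in (0, r_cut].  A residue pair is *live* iff its
minimum distance fell strictly below the main cutoff ``r_cut`` in at least
one frame; all other pairs are disregarded entirely, which keeps the store
sparse in the pair dimension.

Contact on/off states use a dual cutoff: a contact forms when the distance
drops below ``r_inter`` and breaks only when it exceeds ``r_inter_high``.
Distances in between carry the previous state forward, which suppresses
flicker from a few outlier frames.  With ``r_inter == r_inter_high`` this
reduces to plain thresholding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from scipy.spatial import cKDTree

from .trajectory_io import Frame, SelectionMap

logger = logging.getLogger(__name__)

__all__ = [
    "CutoffScheme",
    "ResiduePairStore",
    "ContactTimeline",
    "min_residue_distance",
    "frame_pair_minima",
    "build_pair_store",
    "contact_states",
    "hysteretic_states",
]


@dataclass(frozen=True)
class CutoffScheme:
    """The three contact cutoffs, in nm.

    r_cut : main cutoff; pairs never strictly below it are disregarded and
        distances are clamped to it.
    r_inter : contacts form below this value.
    r_inter_high : contacts break above this value.

    Defaults follow the convention of heavy-atom maps with r_cut = 1.0 nm
    and a single interaction cutoff r_inter = r_inter_high = 0.5 nm.
    """

    r_cut: float = 1.0
    r_inter: float = 0.5
    r_inter_high: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.r_inter <= self.r_inter_high <= self.r_cut):
            raise ValueError(
                f"cutoffs must satisfy 0 < r_inter <= r_inter_high <= r_cut, "
                f"got r_inter={self.r_inter}, r_inter_high={self.r_inter_high}, "
                f"r_cut={self.r_cut}")


_DTYPES = {"float16": np.float16, "float32": np.float32, "float64": np.float64}


@dataclass
class ResiduePairStore:
    """Sparse per-frame clamped distances for the live residue pairs.

    values[p, f] is the clamped distance of live pair ``p`` at frame ``f``.
    Only pairs with i < j are stored (the map is symmetric by construction)
    and pairs with |i - j| < min_seq_separation are never live.

    ``dtype`` may be reduced (float16 guarantees about three significant
    decimal digits) to cut memory on long trajectories; aggregate statistics
    downstream are always accumulated in float64.
    """

    pairs: np.ndarray          # (P, 2) int, i < j
    values: np.ndarray         # (P, F)
    times: np.ndarray          # (F,) ps
    n_residues: int
    cutoffs: CutoffScheme
    min_seq_separation: int = 1

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_frames(self) -> int:
        return self.values.shape[1] if self.values.ndim == 2 else 0

    def distances(self) -> np.ndarray:
        """Clamped distances as float64, shape (n_pairs, n_frames)."""
        return self.values.astype(np.float64)

    def pair_index(self, i: int, j: int) -> int:
        """Row of pair (i, j); raises KeyError if the pair is not live."""
        if i > j:
            i, j = j, i
        hit = np.flatnonzero((self.pairs[:, 0] == i) & (self.pairs[:, 1] == j))
        if len(hit) == 0:
            raise KeyError(f"pair ({i}, {j}) is not live")
        return int(hit[0])


@dataclass
class ContactTimeline:
    """Boolean hysteretic contact state per live pair per frame.

    The initial state is on iff the first frame's distance is strictly below
    ``r_inter``; a first distance inside [r_inter, r_inter_high] starts off.
    """

    pairs: np.ndarray       # (P, 2)
    states: np.ndarray      # (P, F) bool
    times: np.ndarray
    n_residues: int

    @property
    def n_frames(self) -> int:
        return self.states.shape[1]


def _euclidean(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # explicit form so accelerated and exhaustive paths are bit-identical
    d = a - b
    return np.sqrt((d * d).sum(axis=-1))


def min_residue_distance(frame: Frame, selection: SelectionMap,
                         pair: tuple[int, int]) -> float:
    """Minimum distance (nm) between the selected atoms of two residues.

    Exhaustive over all selected-atom cross pairs; serves as the reference
    the accelerated engine must match exactly.
    """
    i, j = pair
    if i == j:
        raise ValueError("a residue has no distance to itself (i == j)")
    gi, gj = selection.groups[i], selection.groups[j]
    if len(gi) == 0 or len(gj) == 0:
        raise ValueError(f"pair ({i}, {j}) involves an inert residue")
    d = _euclidean(frame.coords[gi][:, None, :], frame.coords[gj][None, :, :])
    return float(d.min())


def frame_pair_minima(coords: np.ndarray, selection: SelectionMap,
                      r_cut: float, min_seq_separation: int = 1
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Residue pairs with minimum distance strictly below ``r_cut`` in one frame.

    Returns (keys, dmin) where key = i * n_residues + j with i < j.  Uses a
    k-d tree to enumerate candidate atom pairs within the cutoff; the
    distances themselves are recomputed with the exhaustive formula, so the
    result is identical to brute force.
    """
    flat = selection.flat_indices
    labels = selection.flat_residue_labels
    n_res = selection.n_residues
    empty = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.float64))
    if len(flat) == 0:
        return empty
    pts = np.ascontiguousarray(coords[flat], dtype=np.float64)
    tree = cKDTree(pts)
    ap = tree.query_pairs(r_cut, output_type="ndarray")
    if len(ap) == 0:
        return empty
    a, b = ap[:, 0], ap[:, 1]
    ra, rb = labels[a], labels[b]
    i = np.minimum(ra, rb)
    j = np.maximum(ra, rb)
    sep = max(int(min_seq_separation), 1)
    mask = (j - i) >= sep
    if not mask.any():
        return empty
    a, b, i, j = a[mask], b[mask], i[mask], j[mask]
    d = _euclidean(pts[a], pts[b])
    below = d < r_cut  # strictly below: the tree query is inclusive
    if not below.any():
        return empty
    d, i, j = d[below], i[below], j[below]
    key = i.astype(np.int64) * n_res + j.astype(np.int64)
    order = np.argsort(key, kind="stable")
    key, d = key[order], d[order]
    starts = np.flatnonzero(np.r_[True, key[1:] != key[:-1]])
    return key[starts], np.minimum.reduceat(d, starts)


class StreamingAggregator:
    """Single-pass per-pair statistics with memory independent of frame count.

    Holds Welford accumulators, running minima, the hysteretic contact state
    and first/last on-times for every live pair, but never more than one
    frame of per-pair distances at a time (``max_resident_frames`` counts the
    high-water mark and is asserted to stay at 1 in economy mode).
    """

    def __init__(self, n_residues: int, cutoffs: CutoffScheme,
                 min_seq_separation: int = 1):
        self.n_residues = n_residues
        self.cutoffs = cutoffs
        self.min_seq_separation = min_seq_separation
        self.times: list[float] = []
        self._acc: dict[int, list] = {}  # key -> [n, mean, M2, minv, state, on_n, first_t, last_t]
        self.max_resident_frames = 0

    def update(self, keys: np.ndarray, dmin: np.ndarray, time: float) -> None:
        self.max_resident_frames = max(self.max_resident_frames, 1)
        f = len(self.times)
        r_cut = self.cutoffs.r_cut
        ri, rih = self.cutoffs.r_inter, self.cutoffs.r_inter_high
        frame_vals = dict(zip(keys.tolist(), dmin.tolist()))
        for key, v in frame_vals.items():
            if key not in self._acc:
                # backfill: all earlier frames were >= r_cut, i.e. clamped
                self._acc[key] = [f, r_cut, 0.0, r_cut if f else np.inf,
                                  False, 0, np.nan, np.nan]
        for key, acc in self._acc.items():
            v = frame_vals.get(key, r_cut)
            n, mean, m2, minv, state, on_n, first_t, last_t = acc
            n += 1
            delta = v - mean
            mean += delta / n
            m2 += delta * (v - mean)
            minv = min(minv, v)
            if v < ri:
                state = True
            elif v > rih:
                state = False
            if state:
                on_n += 1
                if np.isnan(first_t):
                    first_t = time
                last_t = time
            acc[:] = [n, mean, m2, minv, state, on_n, first_t, last_t]
        self.times.append(time)

    def sorted_keys(self) -> list[int]:
        return sorted(self._acc)

    def result_arrays(self):
        """(pairs, mean, std, min, fraction, first, last, persistent)."""
        keys = self.sorted_keys()
        F = len(self.times)
        P = len(keys)
        pairs = np.array([[k // self.n_residues, k % self.n_residues] for k in keys],
                         dtype=np.intp).reshape(P, 2)
        mean = np.empty(P)
        std = np.empty(P)
        minv = np.empty(P)
        frac = np.empty(P)
        first = np.full(P, np.nan)
        last = np.full(P, np.nan)
        persistent = np.zeros(P, dtype=bool)
        for p, k in enumerate(keys):
            n, m, m2, mn, state, on_n, ft, lt = self._acc[k]
            assert n == F
            mean[p] = m
            std[p] = np.sqrt(m2 / n) if n else 0.0
            minv[p] = mn
            frac[p] = on_n / n if n else 0.0
            first[p], last[p] = ft, lt
            persistent[p] = bool(state)
        return pairs, mean, std, minv, frac, first, last, persistent


def build_pair_store(
    frames: Iterable[Frame],
    selection: SelectionMap,
    cutoffs: CutoffScheme = CutoffScheme(),
    min_seq_separation: int = 1,
    mode: str = "full",
    dtype: str | np.dtype = "float64",
):
    """Stream frames once and build the sparse live-pair distance store.

    mode="full" returns a :class:`ResiduePairStore` holding every live pair's
    clamped distance at every frame.  mode="economy" never retains more than
    the current frame and returns an :class:`~mdcontacts.aggregate_maps.AggregateMap`
    of streaming statistics instead; the set of live pairs is identical in
    both modes.
    """
    if mode not in ("full", "economy"):
        raise ValueError(f"mode must be 'full' or 'economy', got {mode!r}")
    dtype = _DTYPES[str(np.dtype(dtype))] if not isinstance(dtype, str) else _DTYPES[dtype]
    n_res = selection.n_residues
    r_cut = cutoffs.r_cut

    if mode == "economy":
        agg = StreamingAggregator(n_res, cutoffs, min_seq_separation)
        for frame in frames:
            keys, dmin = frame_pair_minima(frame.coords, selection, r_cut,
                                           min_seq_separation)
            agg.update(keys, dmin, frame.time)
        if not agg.times:
            raise ValueError("trajectory yielded no frames")
        from .aggregate_maps import AggregateMap  # local import: avoid cycle
        pairs, mean, std, minv, frac, first, last, persistent = agg.result_arrays()
        if len(pairs) == 0:
            logger.warning("no residue pair ever came within r_cut=%g nm", r_cut)
        return AggregateMap(
            pairs=pairs, n_residues=n_res, n_frames=len(agg.times),
            r_cut=r_cut, mean_distance=mean, std_distance=std,
            min_distance=minv, contact_fraction=frac,
            first_encounter=first, last_encounter=last, persistent=persistent,
            final_time=agg.times[-1],
            max_resident_frames=agg.max_resident_frames)

    times: list[float] = []
    per_frame: list[tuple[np.ndarray, np.ndarray]] = []
    live: dict[int, None] = {}
    for frame in frames:
        keys, dmin = frame_pair_minima(frame.coords, selection, r_cut,
                                       min_seq_separation)
        for k in keys.tolist():
            live.setdefault(k)
        per_frame.append((keys, dmin))
        times.append(frame.time)
    if not times:
        raise ValueError("trajectory yielded no frames")
    keys_sorted = sorted(live)
    if not keys_sorted:
        logger.warning("no residue pair ever came within r_cut=%g nm", r_cut)
    row_of = {k: p for p, k in enumerate(keys_sorted)}
    P, F = len(keys_sorted), len(times)
    values = np.full((P, F), r_cut, dtype=dtype)
    for f, (keys, dmin) in enumerate(per_frame):
        if len(keys):
            rows = np.fromiter((row_of[k] for k in keys.tolist()),
                               dtype=np.intp, count=len(keys))
            values[rows, f] = dmin  # cast to store dtype here
    pairs = np.array([[k // n_res, k % n_res] for k in keys_sorted],
                     dtype=np.intp).reshape(P, 2)
    return ResiduePairStore(pairs=pairs, values=values,
                            times=np.asarray(times, dtype=np.float64),
                            n_residues=n_res, cutoffs=cutoffs,
                            min_seq_separation=min_seq_separation)


def hysteretic_states(distances: np.ndarray, r_inter: float,
                      r_inter_high: float) -> np.ndarray:
    """Dual-cutoff state machine over a distance series (or (P, F) matrix).

    on when d < r_inter, off when d > r_inter_high, carried over in between;
    initial state is the plain r_inter threshold of the first frame.
    """
    d = np.atleast_2d(np.asarray(distances, dtype=np.float64))
    on = d < r_inter
    off = d > r_inter_high
    states = np.empty_like(on)
    states[:, 0] = on[:, 0]
    for t in range(1, d.shape[1]):
        states[:, t] = on[:, t] | (states[:, t - 1] & ~off[:, t])
    return states if np.asarray(distances).ndim == 2 else states[0]


def contact_states(store: ResiduePairStore,
                   cutoffs: CutoffScheme | None = None) -> ContactTimeline:
    """Hysteretic contact timeline for every live pair of the store."""
    if store.n_frames == 0:
        raise ValueError("empty store")
    cs = cutoffs or store.cutoffs
    states = hysteretic_states(store.distances(), cs.r_inter, cs.r_inter_high)
    return ContactTimeline(pairs=store.pairs, states=states,
                           times=store.times, n_residues=store.n_residues)
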