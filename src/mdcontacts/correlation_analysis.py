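"""Pearson statistics on contact dynamics.

Three flavours:

* per-pair correlation of the clamped interresidue distance with time —
  negative r means the pair is approaching (contact formation), positive r
  means it is separating (rupture);
* per-pair correlation with an arbitrary scalar observable (pulling force,
  radius of gyration, ...) read from a two-column time series;
* residue-residue cross-correlation of per-residue contact *counts*,
  a fit-free alternative to coordinate covariance analysis.

Zero-variance series make Pearson's r undefined; such entries are emitted
as NaN (a null sentinel), never silently as 0, so maps are not biased
toward "no change".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .contact_engine import ContactTimeline, ResiduePairStore

logger = logging.getLogger(__name__)

__all__ = [
    "PairCorrelationMap",
    "ResidueCrossCorrelation",
    "pearson_rows",
    "time_correlation",
    "observable_correlation",
    "contact_counts",
    "cross_correlation",
    "read_observable",
]


@dataclass
class PairCorrelationMap:
    """Pearson r per live pair against a common target series.

    ``r`` is NaN where undefined (zero-variance distance series).
    ``target`` tags what was correlated against: "time" or the observable name.
    """

    pairs: np.ndarray
    n_residues: int
    r: np.ndarray
    target: str

    def matrix(self) -> np.ndarray:
        from .aggregate_maps import pairs_to_matrix
        return pairs_to_matrix(self.pairs, self.r, self.n_residues,
                               np.nan, np.nan)


@dataclass
class ResidueCrossCorrelation:
    """Contact-count series n_i(t) and their residue×residue Pearson matrix.

    The matrix is exactly symmetric; rows for residues whose count never
    varies are NaN, and the diagonal is 1 for varying residues.
    """

    counts: np.ndarray   # (R, F) int
    matrix: np.ndarray   # (R, R)


def pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r between each row of ``x`` and the vector ``y`` (float64).

    Rows (or a target) with zero variance give NaN.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum(axis=1))
    sy = np.sqrt((yc * yc).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (sx * sy)
    r[sx == 0.0] = np.nan
    if sy == 0.0:
        r[:] = np.nan
    return r


def _correlate(store: ResiduePairStore, target: np.ndarray, tag: str,
               below_cut_only: bool) -> PairCorrelationMap:
    if store.n_frames < 3:
        raise ValueError("need at least 3 frames for a correlation")
    d = store.distances()
    if below_cut_only:
        r = np.full(store.n_pairs, np.nan)
        r_cut = store.cutoffs.r_cut
        for p in range(store.n_pairs):
            m = d[p] < r_cut
            if m.sum() >= 3:
                r[p] = pearson_rows(d[p][m][None, :], target[m])[0]
    else:
        r = pearson_rows(d, target)
    n_undef = int(np.isnan(r).sum())
    if n_undef:
        logger.info("%d of %d pairs have undefined %s correlation "
                    "(zero variance)", n_undef, store.n_pairs, tag)
    return PairCorrelationMap(pairs=store.pairs, n_residues=store.n_residues,
                              r=r, target=tag)


def time_correlation(store: ResiduePairStore,
                     below_cut_only: bool = False) -> PairCorrelationMap:
    """Pearson r of each pair's clamped distance against frame time.

    Negative r: the pair approaches over the trajectory (formation);
    positive r: it separates (rupture).  ``below_cut_only`` restricts each
    pair to frames where its distance was strictly below r_cut.
    """
    return _correlate(store, store.times, "time", below_cut_only)


def observable_correlation(store: ResiduePairStore,
                           obs_times: np.ndarray, obs_values: np.ndarray,
                           name: str = "observable",
                           nearest: bool = False,
                           below_cut_only: bool = False) -> PairCorrelationMap:
    """Pearson r of each pair's distance against a scalar time series.

    Observable times must match frame times within 1e-6 ps, frame by frame;
    with ``nearest=True`` each frame instead takes the nearest observable
    sample.
    """
    obs_times = np.asarray(obs_times, dtype=np.float64)
    obs_values = np.asarray(obs_values, dtype=np.float64)
    ft = store.times
    if nearest:
        idx = np.searchsorted(obs_times, ft)
        idx = np.clip(idx, 1, len(obs_times) - 1) if len(obs_times) > 1 else np.zeros(len(ft), dtype=int)
        lo = np.clip(idx - 1, 0, len(obs_times) - 1)
        choose_lo = np.abs(ft - obs_times[lo]) <= np.abs(obs_times[idx] - ft)
        idx = np.where(choose_lo, lo, idx)
        target = obs_values[idx]
    else:
        if len(obs_times) != len(ft) or np.max(np.abs(obs_times - ft)) > 1e-6:
            raise ValueError(
                "observable times do not match frame times (within 1e-6 ps); "
                "pass nearest=True to map to the nearest sample")
        target = obs_values
    return _correlate(store, target, name, below_cut_only)


def contact_counts(timeline: ContactTimeline, n_residues: int | None = None
                   ) -> np.ndarray:
    """n_i(t): number of live pairs involving residue i that are on at frame t.

    Returns an (n_residues, n_frames) integer array; inert or contact-free
    residues are all-zero rows.
    """
    R = n_residues if n_residues is not None else timeline.n_residues
    F = timeline.n_frames
    counts = np.zeros((R, F), dtype=np.int64)
    s = timeline.states.astype(np.int64)
    for p, (i, j) in enumerate(timeline.pairs):
        counts[i] += s[p]
        counts[j] += s[p]
    return counts


def cross_correlation(counts: np.ndarray) -> ResidueCrossCorrelation:
    """Residue×residue Pearson matrix of the contact-count series.

    C[i, j] = Pearson(n_i(t), n_j(t)); computed as a normalized Gram matrix,
    so C equals its transpose exactly.  Zero-variance residues yield NaN
    rows/columns.
    """
    c = np.asarray(counts, dtype=np.float64)
    if c.shape[1] < 3:
        raise ValueError("need at least 3 frames for a cross-correlation")
    cc = c - c.mean(axis=1, keepdims=True)
    norm = np.sqrt((cc * cc).sum(axis=1))
    varying = norm > 0.0
    unit = np.zeros_like(cc)
    unit[varying] = cc[varying] / norm[varying, None]
    C = unit @ unit.T
    C = np.triu(C) + np.triu(C, 1).T  # force exact symmetry
    np.fill_diagonal(C, np.where(varying, 1.0, np.nan))
    C[~varying, :] = np.nan
    C[:, ~varying] = np.nan
    return ResidueCrossCorrelation(counts=np.asarray(counts), matrix=C)


def read_observable(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Two-column whitespace time series (time_ps, value).

    Lines starting with ``#`` or ``@`` are ignored (xvg-compatible).
    """
    times, values = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith(("#", "@")):
                continue
            parts = s.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'time value'")
            times.append(float(parts[0]))
            values.append(float(parts[1]))
    return np.asarray(times), np.asarray(values)
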