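"""Plain-text matrix and table writers.

Square residue matrices are written in the three-column plotting format
(1-based residue indices ``i j value``, one row block per ``i``, blank line
between blocks) that heatmap tools such as gnuplot's ``splot`` consume
directly.  A ``#``-prefixed header records the semantics, matrix size and
sentinel conventions, so every file is self-describing and re-readable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_matrix", "read_matrix", "write_pair_table", "write_table"]


def write_matrix(matrix: np.ndarray, path: str | Path, semantics: str,
                 sentinels: dict[str, float] | None = None,
                 decimals: int = 6) -> None:
    """Write a square matrix in the three-column gnuplot format.

    ``semantics`` tags what the values mean (e.g. ``mean_distance_nm``);
    ``sentinels`` documents reserved values (written into the header).
    Undefined entries (NaN) are written literally as ``nan``.
    """
    m = np.asarray(matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    n = m.shape[0]
    fmt = f"%.{decimals}g"
    with open(path, "w") as fh:
        fh.write(f"# semantics: {semantics}\n")
        fh.write(f"# n_residues: {n}\n")
        fh.write("# indices: 1-based\n")
        for name, value in (sentinels or {}).items():
            fh.write(f"# sentinel_{name}: {fmt % value}\n")
        for i in range(n):
            for j in range(n):
                fh.write(f"{i + 1} {j + 1} {fmt % m[i, j]}\n")
            if i < n - 1:
                fh.write("\n")


def read_matrix(path: str | Path, check_symmetric: bool = True
                ) -> tuple[np.ndarray, dict[str, str]]:
    """Read a matrix written by :func:`write_matrix`.

    Returns (matrix, header dict).  Symmetric files are verified
    (M[i][j] == M[j][i] at the written precision) unless disabled.
    """
    header: dict[str, str] = {}
    entries: list[tuple[int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                body = s.lstrip("#").strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    header[k.strip()] = v.strip()
                continue
            parts = s.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 'i j value'")
            entries.append((int(parts[0]), int(parts[1]), float(parts[2])))
    n = int(header.get("n_residues", max(i for i, _, _ in entries)))
    m = np.full((n, n), np.nan)
    for i, j, v in entries:
        m[i - 1, j - 1] = v
    if check_symmetric:
        a, b = m, m.T
        same = (a == b) | (np.isnan(a) & np.isnan(b))
        if not same.all():
            raise ValueError(f"{path}: matrix is not symmetric")
    return m, header


def write_table(path: str | Path, columns: list[str], rows,
                formats: list[str] | None = None) -> None:
    """Tab-separated table with a '#'-prefixed header line."""
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(columns) + "\n")
        for row in rows:
            if formats:
                cells = [f % v for f, v in zip(formats, row)]
            else:
                cells = [str(v) for v in row]
            fh.write("\t".join(cells) + "\n")


def write_pair_table(agg, path: str | Path) -> None:
    """Per-live-pair statistics table (1-based residue indices)."""
    rows = []
    for p in range(agg.n_pairs):
        i, j = agg.pairs[p]
        rows.append((int(i) + 1, int(j) + 1, agg.mean_distance[p],
                     agg.std_distance[p], agg.min_distance[p],
                     agg.contact_fraction[p], agg.first_encounter[p],
                     agg.last_encounter[p], int(agg.persistent[p])))
    write_table(path,
                ["pair_i", "pair_j", "mean_nm", "std_nm", "min_nm",
                 "fraction", "first_ps", "last_ps", "persistent"],
                rows,
                ["%d", "%d", "%.6g", "%.6g", "%.6g", "%.6g", "%.6g", "%.6g", "%d"])
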