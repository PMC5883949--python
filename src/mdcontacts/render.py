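"""Image rendering of contact maps and (optional) video assembly.

Color conventions: sequential quantities (distances, times) use the
cubehelix colormap; divergent quantities (correlations, differential maps)
use the purple-orange PuOr colormap with its midpoint anchored exactly at
the null value (0), so "no change" is the neutral central color.

Rendering problems are logged and skipped, never fatal; video assembly
shells out to an external encoder (ffmpeg) only if one is present on PATH
and is skipped with a warning otherwise.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from pathlib import Path

import matplotlib
matplotlib.use("Agg")  # noqa: E402 - headless rendering
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import Normalize, TwoSlopeNorm

logger = logging.getLogger(__name__)

__all__ = ["divergent_norm", "render_map", "render_frame_images", "encode_video"]


def divergent_norm(vmin: float, vmax: float) -> TwoSlopeNorm:
    """Norm for divergent data with the midpoint pinned at 0."""
    lim = max(abs(vmin), abs(vmax), 1e-12)
    return TwoSlopeNorm(vmin=-lim, vcenter=0.0, vmax=lim)


def render_map(matrix: np.ndarray, path: str | Path, title: str,
               kind: str = "sequential", colorbar_label: str = "") -> bool:
    """Render one square map to PNG.  Returns False (and logs) on failure."""
    try:
        m = np.asarray(matrix, dtype=np.float64)
        fig, ax = plt.subplots(figsize=(5.0, 4.2), dpi=120)
        if kind == "divergent":
            finite = m[np.isfinite(m)]
            vmin = float(finite.min()) if finite.size else -1.0
            vmax = float(finite.max()) if finite.size else 1.0
            norm = divergent_norm(vmin, vmax)
            cmap = "PuOr"
        else:
            norm = Normalize()
            cmap = "cubehelix"
        im = ax.imshow(m, origin="lower", cmap=cmap, norm=norm,
                       extent=(0.5, m.shape[1] + 0.5, 0.5, m.shape[0] + 0.5))
        ax.set_xlabel("residue j")
        ax.set_ylabel("residue i")
        ax.set_title(title)
        fig.colorbar(im, ax=ax, label=colorbar_label)
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)
        return True
    except Exception:  # pragma: no cover - defensive: rendering is best-effort
        logger.exception("rendering %s failed; skipping", path)
        plt.close("all")
        return False


def render_frame_images(store, outdir: str | Path, prefix: str = "frame") -> list[Path]:
    """One distance-map PNG per frame of a full store."""
    from .aggregate_maps import pairs_to_matrix
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    d = store.distances()
    r_cut = store.cutoffs.r_cut
    for f in range(store.n_frames):
        m = pairs_to_matrix(store.pairs, d[:, f], store.n_residues, r_cut, 0.0)
        p = outdir / f"{prefix}_{f:06d}.png"
        if render_map(m, p, f"t = {store.times[f]:g} ps",
                      kind="sequential", colorbar_label="distance (nm)"):
            paths.append(p)
    return paths


def encode_video(frame_dir: str | Path, out_path: str | Path,
                 pattern: str = "frame_%06d.png", fps: int = 10) -> bool:
    """Collate per-frame PNGs into a video via ffmpeg, if available."""
    encoder = shutil.which("ffmpeg")
    if encoder is None:
        logger.warning("no external video encoder (ffmpeg) on PATH; "
                       "skipping video assembly")
        return False
    cmd = [encoder, "-y", "-loglevel", "error", "-framerate", str(fps),
           "-i", str(Path(frame_dir) / pattern),
           "-pix_fmt", "yuv420p", str(out_path)]
    try:
        subprocess.run(cmd, check=True)
        return True
    except subprocess.CalledProcessError:  # pragma: no cover
        logger.warning("video encoding failed; continuing without video")
        return False
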