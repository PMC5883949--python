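"""Single-input-file driver: run every requested analysis and write artifacts.

All text artifacts are deterministic (no timestamps), so re-running the
same configuration reproduces them byte for byte.  The run log echoes the
resolved configuration, frame count and live-pair count — enough to
reproduce the run.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import __version__
from .aggregate_maps import (PERSISTENT_SENTINEL, aggregate, differential_map,
                             pairs_to_matrix)
from .config import RunConfig, serialize_config
from .contact_engine import build_pair_store, contact_states
from .correlation_analysis import (contact_counts, cross_correlation,
                                   observable_correlation, read_observable,
                                   time_correlation)
from .dimred_cluster import (cluster_frames, cluster_residues, interframe_rmsd,
                             pca)
from .matrixio import write_matrix, write_pair_table, write_table
from .render import encode_video, render_frame_images, render_map
from .trajectory_io import iter_frames, load_restriction, load_topology, select_atoms

logger = logging.getLogger(__name__)

__all__ = ["run"]

_SENT_DIST = {"never_live": None}  # filled with r_cut at write time


def _log_to(path: Path) -> logging.Handler:
    handler = logging.FileHandler(path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    handler.setLevel(logging.INFO)
    return handler


def run(cfg: RunConfig, output_dir: str | Path | None = None,
        images: bool | None = None) -> dict:
    """Execute one configured analysis run.  Returns a result summary."""
    cfg.validate()
    outdir = Path(output_dir if output_dir is not None else cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    do_images = cfg.images if images is None else images

    root = logging.getLogger("mdcontacts")
    handler = _log_to(outdir / "run.log")
    root.addHandler(handler)
    old_level = root.level
    root.setLevel(logging.INFO)
    artifacts: list[str] = []
    try:
        logger.info("mdcontacts version %s", __version__)
        for line in serialize_config(cfg).rstrip().splitlines():
            logger.info("config: %s", line)

        topology = load_topology(cfg.topology)
        restrict = load_restriction(cfg.restrict_file) if cfg.restrict_file else None
        selection = select_atoms(topology, cfg.atom_class, restrict=restrict)
        cutoffs = cfg.cutoffs()
        frames = iter_frames(cfg.trajectory, topology, begin=cfg.begin,
                             end=cfg.end, stride=cfg.stride, dt=cfg.dt)

        result: dict = {"output_dir": outdir, "n_residues": topology.n_residues}
        needs_store = any([cfg.time_correlation, cfg.observable,
                           cfg.cross_correlation, cfg.cluster_frames,
                           cfg.cluster_residues, cfg.pca,
                           cfg.per_frame_images])
        if cfg.mode == "economy" and needs_store:
            logger.warning("economy mode stores no per-frame values; "
                           "correlation/clustering/PCA analyses are skipped")

        if cfg.mode == "economy":
            agg = build_pair_store(frames, selection, cutoffs,
                                   cfg.min_seq_separation, mode="economy")
            store = None
            timeline = None
        else:
            store = build_pair_store(frames, selection, cutoffs,
                                     cfg.min_seq_separation, mode="full")
            timeline = contact_states(store)
            agg = aggregate(store, timeline)
        logger.info("frames analyzed: %d", agg.n_frames)
        logger.info("live residue pairs: %d of %d possible", agg.n_pairs,
                    agg.n_residues * (agg.n_residues - 1) // 2)
        result["n_frames"] = agg.n_frames
        result["n_live_pairs"] = agg.n_pairs
        result["aggregate"] = agg

        def emit(name: str) -> Path:
            p = outdir / name
            artifacts.append(name)
            return p

        if cfg.aggregates:
            r_cut = agg.r_cut
            for fieldname, sent, kind, label in [
                ("mean_distance", {"never_live": r_cut}, "sequential", "mean distance (nm)"),
                ("std_distance", {"never_live": 0.0}, "sequential", "σ distance (nm)"),
                ("min_distance", {"never_live": r_cut}, "sequential", "min distance (nm)"),
                ("contact_fraction", {"never_live": 0.0}, "sequential", "contact fraction"),
                ("first_encounter", {}, "sequential", "first encounter (ps)"),
                ("last_encounter", {"persistent": PERSISTENT_SENTINEL}, "sequential",
                 "last encounter (ps)"),
            ]:
                m = agg.matrix(fieldname)
                write_matrix(m, emit(f"{fieldname}.dat"), f"{fieldname}", sent)
                if do_images:
                    render_map(m, emit(f"{fieldname}.png"), fieldname.replace("_", " "),
                               kind=kind, colorbar_label=label)
            write_pair_table(agg, emit("pairs.tsv"))

        if store is not None and cfg.time_correlation:
            tc = time_correlation(store)
            m = tc.matrix()
            write_matrix(m, emit("time_correlation.dat"), "pearson_r_vs_time",
                         {"undefined": float("nan")})
            if do_images:
                render_map(m, emit("time_correlation.png"),
                           "distance-time correlation", kind="divergent",
                           colorbar_label="Pearson r")
            result["time_correlation"] = tc

        if store is not None and cfg.observable:
            t, v = read_observable(cfg.observable)
            oc = observable_correlation(store, t, v,
                                        name=Path(cfg.observable).stem,
                                        nearest=cfg.observable_nearest)
            m = oc.matrix()
            write_matrix(m, emit("observable_correlation.dat"),
                         f"pearson_r_vs_{oc.target}", {"undefined": float("nan")})
            if do_images:
                render_map(m, emit("observable_correlation.png"),
                           f"distance-{oc.target} correlation", kind="divergent",
                           colorbar_label="Pearson r")
            result["observable_correlation"] = oc

        if store is not None and cfg.cross_correlation:
            counts = contact_counts(timeline, store.n_residues)
            xc = cross_correlation(counts)
            write_matrix(xc.matrix, emit("cross_correlation.dat"),
                         "contact_count_pearson", {"undefined": float("nan")})
            write_table(emit("contact_counts.tsv"),
                        ["residue"] + [f"f{f}" for f in range(counts.shape[1])],
                        [(r + 1, *counts[r]) for r in range(counts.shape[0])])
            if do_images:
                render_map(xc.matrix, emit("cross_correlation.png"),
                           "contact-count cross-correlation", kind="divergent",
                           colorbar_label="Pearson r")
            result["cross_correlation"] = xc

        fdm = None
        if store is not None and (cfg.cluster_frames or cfg.pca):
            if store.n_pairs == 0:
                logger.warning("no live pairs; frame clustering and PCA skipped")
        if store is not None and cfg.cluster_frames and store.n_pairs:
            fdm = interframe_rmsd(store)
            cl = cluster_frames(fdm, k=cfg.cluster_frames,
                                linkage_method=cfg.cluster_linkage)
            write_table(emit("dendrogram.tsv"),
                        ["child_a", "child_b", "height_nm", "size"],
                        [(int(a), int(b), h, int(s)) for a, b, h, s in cl.linkage],
                        ["%d", "%d", "%.8g", "%d"])
            write_table(emit("cluster_timeline.tsv"),
                        ["frame", "time_ps", "label", "distance_to_medoid_nm"],
                        [(f, store.times[f], int(cl.labels[f]),
                          cl.distance_to_medoid[f])
                         for f in range(store.n_frames)],
                        ["%d", "%.6g", "%d", "%.8g"])
            write_table(emit("medoids.tsv"), ["cluster", "medoid_frame"],
                        [(c, int(m)) for c, m in enumerate(cl.medoids)],
                        ["%d", "%d"])
            result["cluster_frames"] = cl

        if store is not None and cfg.cluster_residues and store.n_pairs:
            feat_name = cfg.residue_feature
            if feat_name == "mean_distance":
                features = agg.matrix("mean_distance")
            elif feat_name == "last_encounter":
                m = agg.matrix("last_encounter")
                # numeric feature rows: persistent -> final time, never -> 0
                m[m == PERSISTENT_SENTINEL] = agg.final_time
                features = np.nan_to_num(m, nan=0.0)
            else:
                counts = contact_counts(timeline, store.n_residues)
                features = np.nan_to_num(cross_correlation(counts).matrix, nan=0.0)
            rc = cluster_residues(features, cfg.cluster_residues,
                                  inert=selection.inert, feature_name=feat_name)
            write_table(emit("residue_clusters.tsv"), ["residue", "label"],
                        [(r + 1, int(rc.labels[r]))
                         for r in range(topology.n_residues)],
                        ["%d", "%d"])
            result["cluster_residues"] = rc

        if store is not None and cfg.pca and store.n_pairs:
            pr = pca(store, cfg.pca, binary_states=cfg.pca_binary)
            write_table(emit("pca_eigenvalues.tsv"),
                        ["component", "eigenvalue_nm2"],
                        [(c + 1, w) for c, w in enumerate(pr.eigenvalues)],
                        ["%d", "%.10g"])
            write_table(emit("pca_projections.tsv"),
                        ["frame", "time_ps"] + [f"pc{c+1}" for c in range(cfg.pca)],
                        [(f, store.times[f], *pr.projections[f])
                         for f in range(store.n_frames)])
            for c in range(cfg.pca):
                m = pairs_to_matrix(store.pairs, pr.loadings[:, c],
                                    store.n_residues, 0.0, 0.0)
                write_matrix(m, emit(f"pca_loadings_pc{c+1}.dat"),
                             f"pca_loading_component_{c+1}", {"never_live": 0.0})
            result["pca"] = pr

        if store is not None and cfg.per_frame_images and do_images:
            fdir = outdir / "frames"
            paths = render_frame_images(store, fdir)
            artifacts.extend(str(p.relative_to(outdir)) for p in paths)
            if cfg.video:
                if encode_video(fdir, outdir / "contacts.mp4"):
                    artifacts.append("contacts.mp4")

        artifacts.append("run.log")
        result["artifacts"] = sorted(artifacts)
        logger.info("artifacts written: %d", len(artifacts))
        return result
    finally:
        root.removeHandler(handler)
        handler.close()
        root.setLevel(old_level)
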