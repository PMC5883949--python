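"""Keyword-based run-configuration files.

One analysis run is driven by a single plain-text input file of
``keyword value`` lines (``#`` starts a comment).  Unknown keywords are
rejected with the offending line number; defaults are applied for
everything omitted and echoed to the run log.

Keywords
--------
topology PATH              (required) PDB or GRO topology
trajectory PATH            (required) multi-model PDB / plain format / XTC...
atom_class NAME            c_alpha | backbone | side_chain | heavy | all
r_cut X                    main cutoff, nm                      [1.0]
r_inter X                  contact-formation cutoff, nm         [0.5]
r_inter_high X             contact-breaking cutoff, nm          [0.5]
begin X / end X            analysis time window, ps             [0 / inf]
stride N                   take every N-th stored frame         [1]
dt X                       fallback frame spacing, ps           [1.0]
mode full|economy                                               [full]
min_seq_separation N                                            [1]
restrict_file PATH         1-based residue indices, one per line
aggregates on|off                                               [on]
time_correlation on|off                                         [off]
observable PATH            enables distance-vs-observable correlation
observable_nearest on|off  nearest-neighbour time mapping       [off]
cross_correlation on|off                                        [off]
cluster_frames N           cut the frame dendrogram at N clusters
cluster_linkage NAME       average | single | complete          [average]
cluster_residues N         residue clustering with N clusters
residue_feature NAME       mean_distance | last_encounter | cross_correlation
pca N                      number of principal components
pca_binary on|off          PCA on 0/1 contact states            [off]
use_hysteresis on|off      encounter maps from hysteretic state [on]
images on|off                                                   [on]
per_frame_images on|off                                         [off]
video on|off                                                    [off]
output_dir PATH                                                 [contacts_out]
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

from .contact_engine import CutoffScheme
from .trajectory_io import AtomClass

__all__ = ["RunConfig", "ConfigError", "parse_input", "serialize_config"]


class ConfigError(ValueError):
    """Raised for malformed or inconsistent run-configuration input."""


_BOOL = {"on": True, "off": False, "true": True, "false": False,
         "yes": True, "no": False}


@dataclass
class RunConfig:
    topology: str = ""
    trajectory: str = ""
    atom_class: str = "heavy"
    r_cut: float = 1.0
    r_inter: float = 0.5
    r_inter_high: float = 0.5
    begin: float = 0.0
    end: float = math.inf
    stride: int = 1
    dt: float = 1.0
    mode: str = "full"
    min_seq_separation: int = 1
    restrict_file: Optional[str] = None
    aggregates: bool = True
    time_correlation: bool = False
    observable: Optional[str] = None
    observable_nearest: bool = False
    cross_correlation: bool = False
    cluster_frames: Optional[int] = None
    cluster_linkage: str = "average"
    cluster_residues: Optional[int] = None
    residue_feature: str = "mean_distance"
    pca: Optional[int] = None
    pca_binary: bool = False
    use_hysteresis: bool = True
    images: bool = True
    per_frame_images: bool = False
    video: bool = False
    output_dir: str = "contacts_out"

    def cutoffs(self) -> CutoffScheme:
        return CutoffScheme(r_cut=self.r_cut, r_inter=self.r_inter,
                            r_inter_high=self.r_inter_high)

    def validate(self, where: str = "config") -> None:
        if not self.topology:
            raise ConfigError(f"{where}: missing required keyword 'topology'")
        if not self.trajectory:
            raise ConfigError(f"{where}: missing required keyword 'trajectory'")
        try:
            AtomClass(self.atom_class)
        except ValueError:
            raise ConfigError(f"{where}: unknown atom_class {self.atom_class!r}") from None
        try:
            self.cutoffs()
        except ValueError as exc:
            raise ConfigError(f"{where}: {exc}") from None
        if self.mode not in ("full", "economy"):
            raise ConfigError(f"{where}: mode must be 'full' or 'economy'")
        if self.stride < 1:
            raise ConfigError(f"{where}: stride must be >= 1")
        if self.begin > self.end:
            raise ConfigError(f"{where}: begin > end")
        if self.cluster_linkage not in ("average", "single", "complete"):
            raise ConfigError(f"{where}: unknown linkage {self.cluster_linkage!r}")
        if self.residue_feature not in ("mean_distance", "last_encounter",
                                        "cross_correlation"):
            raise ConfigError(f"{where}: unknown residue_feature "
                              f"{self.residue_feature!r}")


_PARSERS = {
    str: lambda v: v,
    float: float,
    int: int,
    bool: lambda v: _BOOL[v.lower()],
}

# dataclass fields with Optional annotations, mapped to their inner parser
_OPTIONAL = {"restrict_file": str, "observable": str, "cluster_frames": int,
             "cluster_residues": int, "pca": int}


def parse_input(path: str | Path) -> RunConfig:
    """Parse a keyword file into a fully resolved, validated RunConfig."""
    path = Path(path)
    cfg = RunConfig()
    known = {f.name: f.type for f in fields(RunConfig)}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise ConfigError(f"{path}:{lineno}: expected 'keyword value', "
                                  f"got {raw.strip()!r}")
            key, value = parts[0], parts[1].strip()
            if key not in known:
                raise ConfigError(f"{path}:{lineno}: unknown keyword {key!r}")
            if key in _OPTIONAL:
                parser = _OPTIONAL[key]
            else:
                parser = _PARSERS[type(getattr(cfg, key))]
            try:
                setattr(cfg, key, parser(value))
            except (ValueError, KeyError):
                raise ConfigError(
                    f"{path}:{lineno}: bad value {value!r} for keyword {key!r}") from None
    cfg.validate(where=str(path))
    return cfg


def serialize_config(cfg: RunConfig) -> str:
    """Canonical text form of a config; re-parsing it reproduces the config."""
    lines = []
    for f in fields(RunConfig):
        v = getattr(cfg, f.name)
        if v is None:
            continue
        if isinstance(v, bool):
            v = "on" if v else "off"
        elif isinstance(v, float) and math.isinf(v):
            v = "inf"
        lines.append(f"{f.name} {v}")
    return "\n".join(lines) + "\n"
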