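"""Flat key-value pipeline configuration.

One config object carries every tunable of the pipeline; a YAML file with
flat keys overrides the defaults, and CLI flags override the file. The
effective parameter set is logged with each run so builds are
attributable.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, fields, replace
from pathlib import Path

import yaml

from .homology_scan import ScanParams

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "file_checksum"]


@dataclass
class PipelineConfig:
    """All pipeline tunables (documented flat keys)."""

    tile_len: int = 50          # fragment length, nt
    step: int = 50              # tiling stride, nt (== tile_len: non-overlapping)
    max_hits_per_tile: int = 10  # placement cap per tile (multi-hit reporting)
    min_fragments: int = 8      # min adjacent placements per reported run
    join_gap: int = 200         # max gap between adjacent placements, nt (exclusive)
    flank_annot: int = 100      # buffer for annotation/BLAT/satellite intervals, nt
    flank_scan: int = 500       # buffer for fragment-scan runs, nt
    mask_mode: str = "hard"     # 'hard' (N) or 'soft' (lowercase)
    cut_pos: int | None = None  # 1-based rotation cut; None = no default, must be given
    chrR_name: str = "chrR"
    seed: int = 17

    def scan_params(self) -> ScanParams:
        return ScanParams(
            tile_len=self.tile_len,
            step=self.step,
            max_hits_per_tile=self.max_hits_per_tile,
            min_fragments=self.min_fragments,
            join_gap=self.join_gap,
        )

    def describe(self) -> str:
        return " ".join(f"{f.name}={getattr(self, f.name)}" for f in fields(self))


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a config from defaults, an optional YAML file, and overrides.

    Overrides with value None are ignored (unset CLI flags pass through).
    """
    cfg = PipelineConfig()
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(PipelineConfig)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        cfg = replace(cfg, **data)
    clean = {k: v for k, v in overrides.items() if v is not None}
    if clean:
        cfg = replace(cfg, **clean)
    return cfg


def file_checksum(path: str | Path) -> str:
    """Short SHA256 of an input file, for provenance logs."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]
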