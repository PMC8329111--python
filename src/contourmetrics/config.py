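"""Panel configuration: which tolerances, percentiles and modes to compute.

Defaults follow the standard evaluation panel for thoracic autosegmentation
correction studies: surface Dice at 0/4/8/10 mm tolerance, pooled Hausdorff
percentiles 100/99/98/95, slice-wise 2D added-path-length counting, and
face-surfel boundaries for surface Dice vs voxel-center boundaries for the
distance metrics. A config file (YAML or TOML) may override any of these
under sections [boundary], [surface_dsc], [hausdorff], [apl], [stats].
"""

from __future__ import annotations

import os
import tomllib
from dataclasses import dataclass, field, replace

import yaml

__all__ = ["PanelConfig", "load_config"]


@dataclass(frozen=True)
class PanelConfig:
    surface_dsc_tolerances_mm: tuple[float, ...] = (0.0, 4.0, 8.0, 10.0)
    hausdorff_percentiles: tuple[float, ...] = (100.0, 99.0, 98.0, 95.0)
    apl_mode: str = "slice2d"  # or "boundary3d"
    surface_boundary_mode: str = "face-surfel"  # surface DSC boundaries
    distance_boundary_mode: str = "voxel-center"  # HD / ASD boundaries
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if any(t < 0 for t in self.surface_dsc_tolerances_mm):
            raise ValueError("surface DSC tolerances must be >= 0 mm")
        if any(not 0 < p <= 100 for p in self.hausdorff_percentiles):
            raise ValueError("Hausdorff percentiles must be in (0, 100]")

    @staticmethod
    def tau_column(tau: float) -> str:
        return f"surface_dsc_{tau:g}mm"

    @staticmethod
    def hd_column(p: float) -> str:
        return f"hd{p:g}_mm"

    def metric_columns(self) -> list[str]:
        cols = ["volumetric_dsc", "jaccard"]
        cols += [self.tau_column(t) for t in self.surface_dsc_tolerances_mm]
        cols += [self.hd_column(p) for p in self.hausdorff_percentiles]
        cols += ["asd_mm", "apl_px", "fnpl_px", "fnv_px"]
        return cols


def _from_sections(raw: dict) -> PanelConfig:
    cfg = PanelConfig()
    updates: dict = {}
    if "surface_dsc" in raw and "tolerances_mm" in raw["surface_dsc"]:
        updates["surface_dsc_tolerances_mm"] = tuple(
            float(t) for t in raw["surface_dsc"]["tolerances_mm"]
        )
    if "hausdorff" in raw and "percentiles" in raw["hausdorff"]:
        updates["hausdorff_percentiles"] = tuple(
            float(p) for p in raw["hausdorff"]["percentiles"]
        )
    if "apl" in raw and "mode" in raw["apl"]:
        updates["apl_mode"] = str(raw["apl"]["mode"])
    if "boundary" in raw:
        b = raw["boundary"]
        if "surface_mode" in b:
            updates["surface_boundary_mode"] = str(b["surface_mode"])
        if "distance_mode" in b:
            updates["distance_boundary_mode"] = str(b["distance_mode"])
    if "stats" in raw and "alpha" in raw["stats"]:
        updates["alpha"] = float(raw["stats"]["alpha"])
    return replace(cfg, **updates)


def load_config(path: str | os.PathLike | None) -> PanelConfig:
    """Load a PanelConfig from a YAML or TOML file; None gives the defaults."""
    if path is None:
        return PanelConfig()
    path = os.fspath(path)
    if path.endswith(".toml"):
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    return _from_sections(raw)
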