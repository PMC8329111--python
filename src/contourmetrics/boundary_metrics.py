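"""Surface-based similarity metrics.

* ``surface_dsc`` — Dice on surface elements with a distance tolerance τ:
  elements of each surface whose nearest distance to the other surface is
  within τ mm count toward the intersection, area-weighted. Defaults to
  face-surfel boundaries, which carry the surface-area semantics the metric
  is defined on; voxel-center boundaries are available for sensitivity
  analysis.
* ``hausdorff_percentile`` — the two directed nearest-distance sets are
  pooled into one ascending multiset and a percentile of that pooled
  ordering is returned (linear interpolation between closest ranks;
  p = 100 is the exact maximum). Voxel-center boundaries.
* ``average_surface_distance`` — the unweighted average of the two directed
  mean nearest distances, NOT the mean of the pooled multiset. The two
  conventions differ whenever the surfaces have different element counts.
* ``added_path_length`` / ``false_negative_path_length`` — slice-wise 2D
  edge-pixel counts, reported in raw pixels: APL counts corrected edge
  pixels that are not auto edge pixels (exact index coincidence, no
  tolerance); FNPL additionally excludes corrected edge pixels lying inside
  the auto volume, i.e. edge segments that exist only because voxels were
  erased from the autosegmentation. A 3D-boundary APL variant is exposed
  via ``mode="boundary3d"`` for sensitivity analysis; slice-wise is the
  default because corrections are made slice-wise.
"""

from __future__ import annotations

import numpy as np

from .boundary_geometry import (
    BoundaryElementSet,
    DirectedDistanceSet,
    boundary_voxel_mask,
    extract_boundary_3d,
    extract_edges_2d,
    nearest_distances,
)
from .mask_io import BinaryMask
from .overlap_metrics import _require_comparable

__all__ = [
    "surface_dsc",
    "surface_dsc_from_sets",
    "hausdorff_percentile",
    "average_surface_distance",
    "average_surface_distance_from_sets",
    "added_path_length",
    "false_negative_path_length",
]


def _check_tau(tau: float) -> float:
    tau = float(tau)
    if not np.isfinite(tau) or tau < 0:
        raise ValueError(f"tolerance must be finite and >= 0 mm, got {tau}")
    return tau


def _check_percentile(p: float) -> float:
    p = float(p)
    if not 0 < p <= 100:
        raise ValueError(f"percentile must be in (0, 100], got {p}")
    return p


def surface_dsc_from_sets(
    sa: BoundaryElementSet, sb: BoundaryElementSet, tau: float,
    dists: DirectedDistanceSet | None = None,
) -> float:
    """Surface Dice at tolerance ``tau`` from precomputed boundary sets."""
    tau = _check_tau(tau)
    if dists is None:
        dists = nearest_distances(sa, sb)
    w_a_close = float(sa.weights[dists.d_ab <= tau].sum())
    w_b_close = float(sb.weights[dists.d_ba <= tau].sum())
    return (w_a_close + w_b_close) / (sa.total_weight + sb.total_weight)


def surface_dsc(
    a: BinaryMask, b: BinaryMask, tau: float, boundary_mode: str = "face-surfel"
) -> float:
    """Tolerance-parameterised surface Dice between two comparable masks."""
    _require_comparable(a, b)
    tau = _check_tau(tau)
    sa = extract_boundary_3d(a, mode=boundary_mode)
    sb = extract_boundary_3d(b, mode=boundary_mode)
    return surface_dsc_from_sets(sa, sb, tau)


def hausdorff_percentile(
    a: BinaryMask, b: BinaryMask, p: float = 100.0, boundary_mode: str = "voxel-center"
) -> float:
    """Percentile Hausdorff distance (mm) on the pooled directed distances."""
    _require_comparable(a, b)
    p = _check_percentile(p)
    sa = extract_boundary_3d(a, mode=boundary_mode)
    sb = extract_boundary_3d(b, mode=boundary_mode)
    pooled = nearest_distances(sa, sb).pooled
    if p == 100.0:
        return float(pooled.max())
    return float(np.percentile(pooled, p))  # linear interpolation


def average_surface_distance_from_sets(dists: DirectedDistanceSet) -> float:
    return float((dists.d_ab.mean() + dists.d_ba.mean()) / 2.0)


def average_surface_distance(
    a: BinaryMask, b: BinaryMask, boundary_mode: str = "voxel-center"
) -> float:
    """Average of the two directed mean nearest surface distances (mm)."""
    _require_comparable(a, b)
    sa = extract_boundary_3d(a, mode=boundary_mode)
    sb = extract_boundary_3d(b, mode=boundary_mode)
    return average_surface_distance_from_sets(nearest_distances(sa, sb))


def _edge_masks(a: BinaryMask, b: BinaryMask, mode: str) -> tuple[np.ndarray, np.ndarray]:
    if mode == "slice2d":
        return extract_edges_2d(a).edge_voxels, extract_edges_2d(b).edge_voxels
    if mode == "boundary3d":
        return boundary_voxel_mask(a.voxels), boundary_voxel_mask(b.voxels)
    raise ValueError(f"mode must be 'slice2d' or 'boundary3d', got {mode!r}")


def added_path_length(a: BinaryMask, b: BinaryMask, mode: str = "slice2d") -> int:
    """Edge pixels of the corrected mask ``b`` absent from the auto mask
    ``a``'s edge — the contour length a human had to redraw, in pixels."""
    _require_comparable(a, b)
    edges_a, edges_b = _edge_masks(a, b, mode)
    return int((edges_b & ~edges_a).sum())


def false_negative_path_length(a: BinaryMask, b: BinaryMask, mode: str = "slice2d") -> int:
    """APL excluding corrected edge pixels inside the auto volume, i.e.
    excluding edge segments that arise only from erasing auto voxels."""
    _require_comparable(a, b)
    edges_a, edges_b = _edge_masks(a, b, mode)
    return int((edges_b & ~edges_a & ~a.voxels).sum())
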