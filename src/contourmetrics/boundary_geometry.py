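"""Boundary extraction and nearest-distance computation.

Two boundary representations are supported:

* ``voxel-center`` — one element per foreground voxel with at least one
  face-adjacent (6-connected) background neighbour; its position is the
  voxel center in mm and its weight the total exposed face area. This is
  the "every point in surface A" reading used for Hausdorff and average
  surface distances.
* ``face-surfel`` — one element per exposed voxel face; its position is the
  face center and its weight the face area. This carries the surface-area
  semantics the tolerance-parameterised surface Dice is defined on.

The lattice border counts as background, so a structure clipped by the
field of view still has a surface there. All positions and distances are
in mm with anisotropic spacing applied.

``nearest_distances`` uses a KD-tree; ``nearest_distances_bruteforce`` is
the all-pairs oracle kept deliberately free of spatial indexing so the two
routes stay independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import EmptySurfaceError
from .mask_io import BinaryMask

__all__ = [
    "BoundaryElementSet",
    "SliceEdgeSet",
    "DirectedDistanceSet",
    "extract_boundary_3d",
    "extract_edges_2d",
    "nearest_distances",
    "nearest_distances_bruteforce",
    "boundary_voxel_mask",
]

_MODES = ("voxel-center", "face-surfel")


@dataclass(frozen=True)
class BoundaryElementSet:
    """Surface of a mask: element positions (mm) and per-element areas (mm^2)."""

    positions: np.ndarray  # (n, 3) float64, mm
    weights: np.ndarray  # (n,) float64, mm^2
    mode: str
    source_mask_id: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        w = np.asarray(self.weights, dtype=float).ravel()
        if pos.shape[0] != w.shape[0]:
            raise ValueError("positions and weights length mismatch")
        if pos.shape[0] and not (w > 0).all():
            raise ValueError("all boundary element weights must be > 0")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


@dataclass(frozen=True)
class SliceEdgeSet:
    """Per-axial-slice 2D edge pixels, stored as one boolean lattice.

    ``edge_voxels[i, j, k]`` is True when pixel (i, j) is an edge pixel of
    slice k. ``total_count`` is the number of edge pixels over all slices.
    """

    edge_voxels: np.ndarray

    @property
    def total_count(self) -> int:
        return int(self.edge_voxels.sum())

    def slice_pixels(self, k: int) -> set[tuple[int, int]]:
        ii, jj = np.nonzero(self.edge_voxels[:, :, k])
        return set(zip(ii.tolist(), jj.tolist()))


@dataclass(frozen=True)
class DirectedDistanceSet:
    """Nearest-distance values a→b and b→a between two boundary sets (mm)."""

    d_ab: np.ndarray  # one value per element of a
    d_ba: np.ndarray  # one value per element of b

    @property
    def pooled(self) -> np.ndarray:
        return np.concatenate([self.d_ab, self.d_ba])

    def swapped(self) -> "DirectedDistanceSet":
        return DirectedDistanceSet(d_ab=self.d_ba, d_ba=self.d_ab)


def _face_exposure(vox: np.ndarray) -> list[tuple[int, int, np.ndarray]]:
    """For each axis and direction, the foreground voxels whose face-adjacent
    neighbour in that direction is background (outside the lattice counts as
    background). Returns (axis, direction, boolean mask) triples."""
    out = []
    for axis in range(3):
        for direction in (-1, +1):
            neighbour = np.zeros_like(vox)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if direction == +1:
                src[axis] = slice(1, None)
                dst[axis] = slice(None, -1)
            else:
                src[axis] = slice(None, -1)
                dst[axis] = slice(1, None)
            neighbour[tuple(dst)] = vox[tuple(src)]
            out.append((axis, direction, vox & ~neighbour))
    return out


def boundary_voxel_mask(vox: np.ndarray) -> np.ndarray:
    """Boolean mask of foreground voxels with >=1 face-adjacent background
    neighbour (6-connectivity, lattice border = background)."""
    exposed = np.zeros_like(vox)
    for _, _, m in _face_exposure(vox):
        exposed |= m
    return exposed


def extract_boundary_3d(mask: BinaryMask, mode: str = "voxel-center") -> BoundaryElementSet:
    """Extract the 3D boundary of a mask as a weighted element set.

    Raises :class:`EmptySurfaceError` for an empty mask — surface metrics
    are undefined without a surface.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    vox = mask.voxels
    if not vox.any():
        raise EmptySurfaceError("cannot extract the surface of an empty mask")
    sx, sy, sz = mask.spacing
    spacing = np.array([sx, sy, sz])
    face_area = {0: sy * sz, 1: sx * sz, 2: sx * sy}

    if mode == "voxel-center":
        weights_grid = np.zeros(vox.shape)
        for axis, _, m in _face_exposure(vox):
            weights_grid += m * face_area[axis]
        idx = np.argwhere(weights_grid > 0)
        positions = idx * spacing
        weights = weights_grid[tuple(idx.T)]
    else:  # face-surfel
        pos_chunks, w_chunks = [], []
        for axis, direction, m in _face_exposure(vox):
            idx = np.argwhere(m)
            if idx.size == 0:
                continue
            centers = idx * spacing
            centers[:, axis] += direction * spacing[axis] / 2.0
            pos_chunks.append(centers)
            w_chunks.append(np.full(len(idx), face_area[axis]))
        positions = np.concatenate(pos_chunks, axis=0)
        weights = np.concatenate(w_chunks)

    return BoundaryElementSet(
        positions=positions, weights=weights, mode=mode, source_mask_id=mask.source_path
    )


def extract_edges_2d(mask: BinaryMask) -> SliceEdgeSet:
    """Per-axial-slice edge pixels: foreground pixels with >=1 of their
    4-connected in-plane neighbours background (outside the slice counts as
    background). An empty mask yields an empty edge set."""
    vox = mask.voxels
    edges = np.zeros_like(vox)
    for axis in (0, 1):  # in-plane axes only; z is the slice axis
        for direction in (-1, +1):
            neighbour = np.zeros_like(vox)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if direction == +1:
                src[axis] = slice(1, None)
                dst[axis] = slice(None, -1)
            else:
                src[axis] = slice(None, -1)
                dst[axis] = slice(1, None)
            neighbour[tuple(dst)] = vox[tuple(src)]
            edges |= vox & ~neighbour
    return SliceEdgeSet(edge_voxels=edges)


def nearest_distances(a: BoundaryElementSet, b: BoundaryElementSet) -> DirectedDistanceSet:
    """Euclidean nearest-neighbour distances (mm) from every element of a to
    b's elements and vice versa, via KD-trees."""
    if len(a) == 0 or len(b) == 0:
        raise EmptySurfaceError("nearest distances need two nonempty boundary sets")
    tree_b = cKDTree(b.positions)
    tree_a = cKDTree(a.positions)
    d_ab, _ = tree_b.query(a.positions, k=1)
    d_ba, _ = tree_a.query(b.positions, k=1)
    return DirectedDistanceSet(d_ab=np.asarray(d_ab, float), d_ba=np.asarray(d_ba, float))


def nearest_distances_bruteforce(
    a: BoundaryElementSet, b: BoundaryElementSet
) -> DirectedDistanceSet:
    """All-pairs oracle for :func:`nearest_distances`; O(|a|*|b|)."""
    if len(a) == 0 or len(b) == 0:
        raise EmptySurfaceError("nearest distances need two nonempty boundary sets")
    dmat = cdist(a.positions, b.positions)
    return DirectedDistanceSet(d_ab=dmat.min(axis=1), d_ba=dmat.min(axis=0))
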