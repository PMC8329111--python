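"""Synthetic auto/corrected mask-pair cohorts with known edit structure.

The generator emulates the situation the metrics are designed for: an
automatic segmentation of a smooth organ-scale structure that a human
corrects slice-wise. The *corrected* mask is a clean base shape (ellipsoid,
box, or a two-lobe "pair of lungs"); the *auto* mask is the same shape
degraded by localized spherical edits:

* add-blobs — regions the human had to add back, i.e. auto false
  negatives: spheres centered on the base surface, intersected with the
  base and removed from auto (boundary notches, as an undertrained model
  produces — interior holes would be invisible to contour-length metrics);
* erase-blobs — regions the human had to erase, i.e. auto false
  positives: spheres just outside the base are added to auto;
* an optional uniform boundary shift — auto dilated (positive) or eroded
  (negative) by whole voxel steps before the blob edits.

Every edit is recorded in a ledger of exactly which voxels changed, so
metric values can be checked against ground truth (e.g. the false negative
volume equals the ledger's removed-voxel count when blobs do not overlap).

Correction times are simulated as a monotone noisy function of a chosen
driver metric, ``time = exp(log(intercept + slope * driver) + eps)`` with
Gaussian ``eps`` on the log scale — lognormal noise keeps times positive
and right-skewed, matching the non-normal time distributions these
workflows produce.

Blob radii are in mm and blobs are spheres in physical space, so the
default anisotropic spacing (1, 1, 3) mm produces flattened voxel
footprints exactly as a sphere would on lung-CT-like slices.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .boundary_geometry import boundary_voxel_mask
from .boundary_metrics import added_path_length, false_negative_path_length
from .errors import DegenerateInputError, GenerationError
from .mask_io import BinaryMask, save_mask
from .overlap_metrics import false_negative_volume, volumetric_dsc

__all__ = [
    "PerturbationSpec",
    "TimeModelSpec",
    "EditLedger",
    "make_pair",
    "make_cohort",
    "CohortResult",
]

_BASE_SHAPES = ("ellipsoid", "box", "two-lobe")
_MAX_PLACEMENT_TRIES = 200


@dataclass(frozen=True)
class PerturbationSpec:
    """Recipe for one auto/corrected pair. Seed fixed => bit-identical output."""

    base_shape: str = "ellipsoid"
    grid_dims: tuple[int, int, int] = (64, 64, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    n_add_blobs: int = 2
    add_blob_radius_range: tuple[float, float] = (4.0, 8.0)
    n_erase_blobs: int = 1
    erase_blob_radius_range: tuple[float, float] = (3.0, 6.0)
    boundary_shift_px: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_shape not in _BASE_SHAPES:
            raise ValueError(f"base_shape must be one of {_BASE_SHAPES}")
        for lo, hi in (self.add_blob_radius_range, self.erase_blob_radius_range):
            if not (0 < lo <= hi):
                raise ValueError("blob radius ranges must satisfy 0 < lo <= hi")


@dataclass(frozen=True)
class TimeModelSpec:
    """Monotone noisy map from a driver metric to correction time (minutes)."""

    driver_metric: str = "apl"
    intercept: float = 5.0  # minutes at zero driver: load/save overhead
    slope: float = 0.05  # minutes per driver unit; puts desk-scale cohorts
    #                      at ~15-25 min medians, the scale of real corrections
    noise_sd: float = 0.35  # sd of Gaussian noise on the log scale
    seed: int = 0


@dataclass(frozen=True)
class EditLedger:
    """Ground truth of a generated pair: which voxels each edit changed."""

    edits: list = field(default_factory=list)  # dicts: kind, center_mm, radius_mm, n_voxels
    removed_from_auto: np.ndarray | None = None  # corrected voxels auto lost
    added_to_auto: np.ndarray | None = None  # spurious voxels auto gained

    @property
    def n_removed(self) -> int:
        return 0 if self.removed_from_auto is None else int(self.removed_from_auto.sum())

    @property
    def n_added(self) -> int:
        return 0 if self.added_to_auto is None else int(self.added_to_auto.sum())

    @property
    def is_empty(self) -> bool:
        return self.n_removed == 0 and self.n_added == 0


def _coord_grids(dims, spacing):
    axes = [np.arange(n) * s for n, s in zip(dims, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _base_mask(shape: str, dims, spacing) -> np.ndarray:
    X, Y, Z = _coord_grids(dims, spacing)
    extent = [n * s for n, s in zip(dims, spacing)]
    cx, cy, cz = (e / 2 for e in extent)
    if shape == "box":
        half = [0.3 * e for e in extent]
        return (
            (np.abs(X - cx) <= half[0])
            & (np.abs(Y - cy) <= half[1])
            & (np.abs(Z - cz) <= half[2])
        )
    if shape == "ellipsoid":
        semi = [0.35 * e for e in extent]
        return ((X - cx) / semi[0]) ** 2 + ((Y - cy) / semi[1]) ** 2 + (
            (Z - cz) / semi[2]
        ) ** 2 <= 1.0
    # two-lobe: two ellipsoids offset along x, like left/right lung
    semi = [0.18 * extent[0], 0.3 * extent[1], 0.35 * extent[2]]
    lobes = np.zeros(dims, dtype=bool)
    for off in (-0.22 * extent[0], +0.22 * extent[0]):
        lobes |= ((X - (cx + off)) / semi[0]) ** 2 + ((Y - cy) / semi[1]) ** 2 + (
            (Z - cz) / semi[2]
        ) ** 2 <= 1.0
    return lobes


def _sphere(center_mm, radius_mm, dims, spacing) -> np.ndarray:
    X, Y, Z = _coord_grids(dims, spacing)
    return (X - center_mm[0]) ** 2 + (Y - center_mm[1]) ** 2 + (
        Z - center_mm[2]
    ) ** 2 <= radius_mm**2


def _fully_inside(center_mm, radius_mm, dims, spacing) -> bool:
    for c, n, s in zip(center_mm, dims, spacing):
        if c - radius_mm < 0 or c + radius_mm > (n - 1) * s:
            return False
    return True


def _place_blob(rng, candidates_idx, radius_mm, dims, spacing):
    """Pick a candidate voxel whose sphere fits fully inside the lattice."""
    if len(candidates_idx) == 0:
        raise GenerationError("no candidate voxels for blob placement")
    for _ in range(_MAX_PLACEMENT_TRIES):
        i = rng.integers(len(candidates_idx))
        center = candidates_idx[i] * np.asarray(spacing)
        if _fully_inside(center, radius_mm, dims, spacing):
            return center
    raise GenerationError(
        f"could not place a blob of radius {radius_mm} mm inside the lattice "
        f"after {_MAX_PLACEMENT_TRIES} tries"
    )


def make_pair(spec: PerturbationSpec) -> tuple[BinaryMask, BinaryMask, EditLedger]:
    """Generate one (auto, corrected) mask pair with its edit ledger."""
    rng = np.random.default_rng(spec.seed)
    dims, spacing = spec.grid_dims, spec.spacing
    corrected_vox = _base_mask(spec.base_shape, dims, spacing)
    auto_vox = corrected_vox.copy()

    edits = []
    if spec.boundary_shift_px > 0:
        auto_vox = ndimage.binary_dilation(auto_vox, iterations=spec.boundary_shift_px)
        edits.append({"kind": "boundary_shift", "shift_px": spec.boundary_shift_px})
    elif spec.boundary_shift_px < 0:
        auto_vox = ndimage.binary_erosion(auto_vox, iterations=-spec.boundary_shift_px)
        edits.append({"kind": "boundary_shift", "shift_px": spec.boundary_shift_px})

    # add blobs notch the base surface; erase blobs bulge just outside it
    fg_idx = np.argwhere(boundary_voxel_mask(corrected_vox))
    band = ndimage.binary_dilation(corrected_vox, iterations=4) & ~corrected_vox
    bg_idx = np.argwhere(band)

    for _ in range(spec.n_add_blobs):
        r = rng.uniform(*spec.add_blob_radius_range)
        center = _place_blob(rng, fg_idx, r, dims, spacing)
        blob = _sphere(center, r, dims, spacing)
        changed = blob & auto_vox
        auto_vox = auto_vox & ~blob
        edits.append({"kind": "add", "center_mm": tuple(center), "radius_mm": float(r),
                      "n_voxels": int(changed.sum())})
    for _ in range(spec.n_erase_blobs):
        r = rng.uniform(*spec.erase_blob_radius_range)
        center = _place_blob(rng, bg_idx, r, dims, spacing)
        blob = _sphere(center, r, dims, spacing) & ~corrected_vox
        changed = blob & ~auto_vox
        auto_vox = auto_vox | blob
        edits.append({"kind": "erase", "center_mm": tuple(center), "radius_mm": float(r),
                      "n_voxels": int(changed.sum())})

    auto = BinaryMask(voxels=auto_vox, spacing=spacing, source_path="synthetic:auto")
    corrected = BinaryMask(voxels=corrected_vox, spacing=spacing,
                           source_path="synthetic:corrected")
    ledger = EditLedger(
        edits=edits,
        removed_from_auto=corrected_vox & ~auto_vox,
        added_to_auto=auto_vox & ~corrected_vox,
    )
    return auto, corrected, ledger


def _default_spec_distribution(rng: np.random.Generator, i: int) -> PerturbationSpec:
    """Default cohort regime: the edit *count* varies widely case to case
    while the total edited volume varies much less (blob radii shrink as
    counts grow), so path-length metrics spread far more than volume-overlap
    metrics — the regime in which the two metric families disagree."""
    n_add = int(rng.integers(1, 13))
    # keep k * r^3 roughly constant: target ~1500 mm^3 of edits total
    r0 = (1500.0 / n_add) ** (1.0 / 3.0)
    r_lo, r_hi = 0.85 * r0, 1.15 * r0
    n_erase = int(rng.integers(0, 3))
    shape = ("ellipsoid", "two-lobe", "box")[int(rng.integers(3))]
    return PerturbationSpec(
        base_shape=shape,
        n_add_blobs=n_add,
        add_blob_radius_range=(r_lo, r_hi),
        n_erase_blobs=n_erase,
        erase_blob_radius_range=(3.0, 5.0),
        seed=int(rng.integers(2**31 - 1)),
    )


_DRIVER_FUNCS = {
    "apl": added_path_length,
    "fnpl": false_negative_path_length,
    "fnv": false_negative_volume,
    "volumetric_dsc": volumetric_dsc,
}


@dataclass(frozen=True)
class CohortResult:
    """In-memory cohort: manifest + case table + the generated mask pairs."""

    manifest: pd.DataFrame
    case_table: pd.DataFrame
    pairs: list  # [(case_id, auto, corrected, ledger), ...]


def make_cohort(
    n: int,
    spec_distribution=None,
    time_model: TimeModelSpec | None = None,
    out_dir: str | os.PathLike | None = None,
    seed: int = 0,
) -> CohortResult:
    """Generate ``n`` auto/corrected pairs with simulated correction times.

    ``spec_distribution(rng, i)`` returns the i-th case's
    :class:`PerturbationSpec`; the default varies edit count at roughly
    constant edited volume. When ``out_dir`` is given, NIfTI pairs plus
    ``manifest.csv`` and ``cases.csv`` are written there; otherwise the
    cohort stays in memory. The case table records the simulated
    ``correction_time`` (minutes), covariates derived from the generation
    recipe, and the true driver value in the ``_driver_value`` column for
    recovery tests.
    """
    if n < 3:
        raise DegenerateInputError(f"a cohort needs n >= 3 cases, got n={n}")
    if spec_distribution is None:
        spec_distribution = _default_spec_distribution
    if time_model is None:
        time_model = TimeModelSpec()
    if time_model.driver_metric not in _DRIVER_FUNCS:
        raise ValueError(
            f"driver_metric must be one of {sorted(_DRIVER_FUNCS)}, "
            f"got {time_model.driver_metric!r}"
        )
    driver_fn = _DRIVER_FUNCS[time_model.driver_metric]

    rng_specs = np.random.default_rng(seed)
    rng_noise = np.random.default_rng(time_model.seed + 1_000_003 * (seed + 1))

    pairs, manifest_rows, case_rows = [], [], []
    for i in range(n):
        case_id = f"case_{i:04d}"
        spec = spec_distribution(rng_specs, i)
        auto, corrected, ledger = make_pair(spec)
        driver = float(driver_fn(auto, corrected))
        eps = rng_noise.normal(0.0, time_model.noise_sd)
        t = float(np.exp(np.log(time_model.intercept + time_model.slope * driver) + eps))
        burden = ("low", "medium", "high")[min(2, spec.n_add_blobs // 5)]
        auto_path, corr_path = "", ""
        if out_dir is not None:
            os.makedirs(out_dir, exist_ok=True)
            auto_path = os.path.join(out_dir, f"{case_id}_auto.nii.gz")
            corr_path = os.path.join(out_dir, f"{case_id}_corrected.nii.gz")
            save_mask(auto, auto_path)
            save_mask(corrected, corr_path)
        pairs.append((case_id, auto, corrected, ledger))
        manifest_rows.append(
            {"case_id": case_id, "auto_path": auto_path or f"<memory:{case_id}:auto>",
             "corrected_path": corr_path or f"<memory:{case_id}:corrected>"}
        )
        case_rows.append(
            {
                "case_id": case_id,
                "correction_time": t,
                "structure_volume_cm3": corrected.n_foreground * corrected.voxel_volume_mm3 / 1000.0,
                "base_shape": spec.base_shape,
                "edit_burden": burden,
                "_driver_value": driver,
            }
        )

    manifest = pd.DataFrame(manifest_rows)
    cases = pd.DataFrame(case_rows)
    if out_dir is not None:
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
        cases.to_csv(os.path.join(out_dir, "cases.csv"), index=False)
    return CohortResult(manifest=manifest, case_table=cases, pairs=pairs)
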