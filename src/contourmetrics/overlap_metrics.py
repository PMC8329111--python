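"""Volume-overlap metrics: volumetric Dice, Jaccard index, false negative volume.

Conventions: two empty masks agree perfectly (DSC = JI = 1); one empty mask
against a nonempty one has no overlap (DSC = JI = 0). The false negative
volume is directional — it counts corrected voxels absent from the
autosegmentation — and is reported as a raw voxel ("pixel") count, not mm^3.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import GeometryError
from .mask_io import BinaryMask

__all__ = ["OverlapCounts", "overlap_counts", "volumetric_dsc", "jaccard_index",
           "false_negative_volume"]


@dataclass(frozen=True)
class OverlapCounts:
    n_a: int
    n_b: int
    n_intersect: int

    @property
    def n_union(self) -> int:
        return self.n_a + self.n_b - self.n_intersect

    @property
    def n_b_minus_a(self) -> int:
        return self.n_b - self.n_intersect


def _require_comparable(a: BinaryMask, b: BinaryMask) -> None:
    if not a.is_comparable(b):
        raise GeometryError(
            f"masks are not comparable: shapes {a.shape} vs {b.shape}, "
            f"spacings {a.spacing} vs {b.spacing}"
        )


def overlap_counts(a: BinaryMask, b: BinaryMask) -> OverlapCounts:
    _require_comparable(a, b)
    return OverlapCounts(
        n_a=a.n_foreground,
        n_b=b.n_foreground,
        n_intersect=int((a.voxels & b.voxels).sum()),
    )


def volumetric_dsc(a: BinaryMask, b: BinaryMask) -> float:
    """2|A∩B| / (|A|+|B|). 1 is perfect overlap, 0 is none."""
    c = overlap_counts(a, b)
    if c.n_a == 0 and c.n_b == 0:
        return 1.0
    return 2.0 * c.n_intersect / (c.n_a + c.n_b)


def jaccard_index(a: BinaryMask, b: BinaryMask) -> float:
    """|A∩B| / |A∪B|; related to Dice by DSC = 2J/(1+J)."""
    c = overlap_counts(a, b)
    if c.n_union == 0:
        return 1.0
    return c.n_intersect / c.n_union


def false_negative_volume(a: BinaryMask, b: BinaryMask) -> int:
    """Voxels of the corrected mask ``b`` missing from the auto mask ``a``."""
    return overlap_counts(a, b).n_b_minus_a
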