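"""Binary tendon masks on regular grids, with anatomical orientation.

Grids are axis-aligned: world position of voxel (i, j, k) center is
``origin + (i + ½, j + ½, k + ½) · voxel_dims``.  Orientation metadata
records which array axis runs superior–inferior (``slice_axis``), which end
of it is proximal, which limb the mask belongs to, and which signed
in-plane axis points toward the subject's anatomical left
(``left_direction``, e.g. ``"+x"``).  The medial side is derived per limb:
for a right knee the medial side faces the subject's left (the midline),
for a left knee the opposite.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec", "TendonMask"]

_AXIS_BY_LETTER = {"x": 0, "y": 1, "z": 2}


def parse_signed_axis(spec: str) -> tuple[int, int]:
    """Parse a signed-axis string like ``"+x"`` or ``"-y"`` to (axis, sign)."""
    s = spec.strip().lower()
    if len(s) == 1:
        s = "+" + s
    if len(s) != 2 or s[0] not in "+-" or s[1] not in _AXIS_BY_LETTER:
        raise ValueError(f"cannot parse signed axis {spec!r}; expected e.g. '+x'")
    return _AXIS_BY_LETTER[s[1]], (1 if s[0] == "+" else -1)


@dataclass(frozen=True)
class GridSpec:
    """Shape, voxel dimensions (mm) and world origin of a regular grid."""

    shape: tuple[int, int, int]
    voxel_dims: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "voxel_dims",
                           tuple(float(d) for d in self.voxel_dims))
        object.__setattr__(self, "origin",
                           tuple(float(o) for o in self.origin))
        if any(n <= 0 for n in self.shape):
            raise ValueError("grid shape entries must be positive")
        if any(d <= 0 for d in self.voxel_dims):
            raise ValueError("voxel dimensions must be positive")

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.voxel_dims
        return dx * dy * dz

    def extent(self) -> tuple[tuple[float, float], ...]:
        """World-coordinate (low, high) bounds per axis."""
        return tuple((o, o + n * d) for o, n, d
                     in zip(self.origin, self.shape, self.voxel_dims))


@dataclass
class TendonMask:
    """Binary 3D mask plus the metadata needed for region geometry."""

    voxels: np.ndarray
    voxel_dims: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    slice_axis: int = 2
    proximal_end: str = "low"            # which end of slice_axis is proximal
    limb_side: str | None = None         # "left" | "right"
    left_direction: str | None = None    # signed in-plane axis toward subject left

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3D")
        self.voxel_dims = tuple(float(d) for d in self.voxel_dims)
        if any(d <= 0 for d in self.voxel_dims):
            raise ValueError("voxel dimensions must be positive")
        self.origin = tuple(float(o) for o in self.origin)
        if self.slice_axis not in (0, 1, 2):
            raise ValueError("slice_axis must be 0, 1 or 2")
        if self.proximal_end not in ("low", "high"):
            raise ValueError("proximal_end must be 'low' or 'high'")
        if self.limb_side is not None and self.limb_side not in ("left", "right"):
            raise ValueError("limb_side must be 'left' or 'right'")
        if self.left_direction is not None:
            ax, _ = parse_signed_axis(self.left_direction)
            if ax == self.slice_axis:
                raise ValueError("left_direction cannot lie along slice_axis")

    # -- geometry -----------------------------------------------------------

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.voxels.shape, self.voxel_dims, self.origin)

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def is_empty(self) -> bool:
        return not self.voxels.any()

    @property
    def inplane_axes(self) -> tuple[int, int]:
        return tuple(a for a in (0, 1, 2) if a != self.slice_axis)

    def occupied_slices(self) -> np.ndarray:
        """Indices (ascending) of slices containing at least one voxel."""
        proj = np.any(self.voxels, axis=self.inplane_axes)
        return np.flatnonzero(proj)

    def slice2d(self, index: int) -> np.ndarray:
        """The 2D boolean in-plane slab at the given slice index."""
        return np.take(self.voxels, index, axis=self.slice_axis)

    # -- anatomy ------------------------------------------------------------

    def medial_direction(self) -> tuple[int, int]:
        """Signed in-plane axis toward the medial side, as (axis, sign).

        Derived from ``left_direction`` and ``limb_side``: the medial side of
        a right knee faces the subject's left, and vice versa.
        """
        if self.limb_side is None:
            raise ValueError(
                "cannot resolve the medial side: limb_side is not set on this mask"
            )
        if self.left_direction is None:
            raise ValueError(
                "cannot resolve the medial side: left_direction is not set on this mask"
            )
        ax, sign = parse_signed_axis(self.left_direction)
        return ax, (sign if self.limb_side == "right" else -sign)

    # -- convenience --------------------------------------------------------

    def with_voxels(self, voxels: np.ndarray) -> "TendonMask":
        """Copy of this mask with a different boolean array, same metadata."""
        return dataclasses.replace(self, voxels=np.asarray(voxels, dtype=bool))

    def same_grid(self, other: "TendonMask") -> bool:
        return (self.voxels.shape == other.voxels.shape
                and np.allclose(self.voxel_dims, other.voxel_dims)
                and np.allclose(self.origin, other.origin)
                and self.slice_axis == other.slice_axis)
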