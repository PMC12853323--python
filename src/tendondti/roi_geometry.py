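"""Tendon region-of-interest geometry.

Implements the region scheme used for tendon DTI analysis: per slice, the
longest in-plane chord of the tendon cross-section (its greatest
cross-sectional diameter) is trisected into equal lengths, and boundary
lines perpendicular to the chord split the slice into medial, central and
lateral thirds of equal width.  Separately the tendon is bisected
length-wise into proximal and distal halves, the middle slice belonging to
both when the slice count is odd.  Supporting operations: calcification
exclusion, voxel-count volumes, occupancy-based downsampling to the DTI
grid, and one-pixel in-plane boundary erosion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .masks import GridSpec, TendonMask

__all__ = [
    "DiameterSegment",
    "RegionSet",
    "longest_diameter",
    "trisect_mask",
    "bisect_mask",
    "full_region_set",
    "exclude_calcifications",
    "mask_volume",
    "downsample_mask",
    "downsample_region_labels",
    "erode_boundary",
    "erode_region_set",
]

LONGITUDINAL_REGIONS = ("medial", "central", "lateral")
TRANSVERSE_REGIONS = ("proximal", "distal")
ALL_REGIONS = ("whole",) + LONGITUDINAL_REGIONS + TRANSVERSE_REGIONS

# slices whose diameter is shorter than this many in-plane voxels are too
# thin to trisect meaningfully; all their voxels are assigned central
_DEGENERATE_EXTENT_VOXELS = 3


@dataclass(frozen=True)
class DiameterSegment:
    """Longest in-plane chord of one slice, between voxel centers (mm)."""

    p1: tuple[float, float]
    p2: tuple[float, float]
    axis: tuple[float, float]       # unit vector p1 → p2 (fallback (1, 0))
    length: float
    slice_index: int


@dataclass
class RegionSet:
    """Named boolean sub-masks sharing one grid."""

    masks: dict[str, np.ndarray]
    voxel_dims: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    slice_axis: int = 2
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def names(self) -> tuple[str, ...]:
        return tuple(self.masks)

    def counts(self) -> dict[str, int]:
        return {k: int(v.sum()) for k, v in self.masks.items()}


# ---------------------------------------------------------------------------
# longest diameter
# ---------------------------------------------------------------------------

def _boundary_points(slab: np.ndarray, dims2d: tuple[float, float]) -> np.ndarray:
    """Centers (mm) of boundary voxels of the largest 8-connected component."""
    labels, n = ndimage.label(slab, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise ValueError("empty slice: no voxels to measure")
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        comp = labels == (int(np.argmax(sizes)) + 1)
    else:
        comp = labels == 1
    interior = ndimage.binary_erosion(
        comp, structure=ndimage.generate_binary_structure(2, 1),
        border_value=0)
    boundary = comp & ~interior
    idx = np.argwhere(boundary)
    return (idx + 0.5) * np.asarray(dims2d)


def _longest_chord(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Longest chord endpoints among 2D points, deterministic tie-break.

    Candidate endpoints are reduced to convex-hull vertices when the point
    count is large (the farthest pair is always a hull vertex pair); ties
    within floating precision resolve to the lexicographically smallest
    ordered endpoint pair.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) == 1:
        p = pts[0]
        return p, p, 0.0
    cand = pts
    if len(pts) > 80:
        try:
            cand = pts[ConvexHull(pts).vertices]
        except QhullError:                   # collinear or degenerate
            cand = pts
    diff = cand[:, None, :] - cand[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    best = d2.max()
    ii, jj = np.nonzero(d2 >= best * (1.0 - 1e-12))
    pairs = []
    for a, b in zip(ii, jj):
        pa, pb = cand[a], cand[b]
        key = (tuple(pa), tuple(pb)) if tuple(pa) <= tuple(pb) else (tuple(pb), tuple(pa))
        pairs.append(key)
    p1t, p2t = min(pairs)
    p1, p2 = np.array(p1t), np.array(p2t)
    return p1, p2, float(np.linalg.norm(p2 - p1))


def longest_diameter(mask: TendonMask, slice_index: int) -> DiameterSegment:
    """Greatest cross-sectional diameter of one transverse slice.

    The longest chord between boundary-voxel centers of the slice's largest
    connected component.  A single-voxel slice yields length 0 with the
    axis defaulting to the first in-plane direction.
    """
    slab = mask.slice2d(slice_index)
    a0, a1 = mask.inplane_axes
    dims2d = (mask.voxel_dims[a0], mask.voxel_dims[a1])
    pts = _boundary_points(slab, dims2d)
    p1, p2, length = _longest_chord(pts)
    if length > 0:
        axis = tuple((p2 - p1) / length)
    else:
        axis = (1.0, 0.0)
    return DiameterSegment(tuple(p1), tuple(p2), axis, length, slice_index)


# ---------------------------------------------------------------------------
# trisection / bisection
# ---------------------------------------------------------------------------

def trisect_mask(mask: TendonMask) -> RegionSet:
    """Split every slice into medial / central / lateral thirds.

    Per slice, voxel centers are projected onto the longest-diameter axis;
    cut points at 1/3 and 2/3 of the diameter length define boundaries
    perpendicular to the axis.  Which end is medial comes from the mask's
    limb side and anatomical orientation.  Voxels projecting exactly onto a
    cut point go to central; slices whose diameter is shorter than three
    in-plane voxels are assigned entirely to central.
    """
    if mask.is_empty:
        raise ValueError("cannot trisect an empty mask")
    med_axis, med_sign = mask.medial_direction()   # raises if unresolvable
    a0, a1 = mask.inplane_axes
    dims2d = np.array([mask.voxel_dims[a0], mask.voxel_dims[a1]])
    med_vec = np.zeros(2)
    med_vec[0 if med_axis == a0 else 1] = med_sign

    shape = mask.voxels.shape
    medial = np.zeros(shape, dtype=bool)
    central = np.zeros(shape, dtype=bool)
    lateral = np.zeros(shape, dtype=bool)
    degenerate_len = _DEGENERATE_EXTENT_VOXELS * float(dims2d.min())

    for k in mask.occupied_slices():
        slab = mask.slice2d(k)
        seg = longest_diameter(mask, int(k))
        idx = np.argwhere(slab)
        coords = (idx + 0.5) * dims2d
        sel_central = np.zeros(len(idx), dtype=bool)
        sel_low = np.zeros(len(idx), dtype=bool)
        sel_high = np.zeros(len(idx), dtype=bool)
        if seg.length < degenerate_len:
            sel_central[:] = True
        else:
            axis = np.asarray(seg.axis)
            t = (coords - np.asarray(seg.p1)) @ axis
            c1, c2 = seg.length / 3.0, 2.0 * seg.length / 3.0
            sel_low = t < c1
            sel_high = t > c2
            sel_central = ~sel_low & ~sel_high
        # orient: the end of the axis pointing medially gets the medial label;
        # a perpendicular axis (dot == 0) deterministically treats high-t as medial
        if seg.length >= degenerate_len and np.asarray(seg.axis) @ med_vec < 0:
            sel_low, sel_high = sel_high, sel_low
        for sel, out in ((sel_low, lateral), (sel_central, central),
                         (sel_high, medial)):
            if sel.any():
                sub = idx[sel]
                full = _inplane_to_full(sub, k, mask.slice_axis, a0, a1)
                out[tuple(full.T)] = True

    return RegionSet(
        {"whole": mask.voxels.copy(), "medial": medial, "central": central,
         "lateral": lateral},
        mask.voxel_dims, mask.origin, mask.slice_axis,
        provenance={"operation": "trisect"},
    )


def _inplane_to_full(idx2d: np.ndarray, k: int, slice_axis: int,
                     a0: int, a1: int) -> np.ndarray:
    full = np.empty((len(idx2d), 3), dtype=int)
    full[:, a0] = idx2d[:, 0]
    full[:, a1] = idx2d[:, 1]
    full[:, slice_axis] = k
    return full


def bisect_mask(mask: TendonMask) -> RegionSet:
    """Split occupied slices into proximal and distal halves of equal length.

    With an odd slice count the middle slice belongs to both regions.
    """
    occ = mask.occupied_slices()
    if occ.size == 0:
        raise ValueError("cannot bisect an empty mask")
    ordered = occ if mask.proximal_end == "low" else occ[::-1]
    n = len(ordered)
    if n % 2 == 0:
        prox_slices = ordered[: n // 2]
        dist_slices = ordered[n // 2:]
    else:
        half = (n + 1) // 2
        prox_slices = ordered[:half]
        dist_slices = ordered[half - 1:]

    def _select(slices) -> np.ndarray:
        keep = np.zeros(mask.voxels.shape[mask.slice_axis], dtype=bool)
        keep[np.asarray(slices, dtype=int)] = True
        shape = [1, 1, 1]
        shape[mask.slice_axis] = -1
        return mask.voxels & keep.reshape(shape)

    return RegionSet(
        {"whole": mask.voxels.copy(), "proximal": _select(prox_slices),
         "distal": _select(dist_slices)},
        mask.voxel_dims, mask.origin, mask.slice_axis,
        provenance={"operation": "bisect"},
    )


def full_region_set(mask: TendonMask) -> RegionSet:
    """Whole + medial/central/lateral + proximal/distal in one RegionSet."""
    tri = trisect_mask(mask)
    bi = bisect_mask(mask)
    masks = dict(tri.masks)
    masks["proximal"] = bi["proximal"]
    masks["distal"] = bi["distal"]
    return RegionSet(masks, mask.voxel_dims, mask.origin, mask.slice_axis,
                     provenance={"operation": "full_region_set"})


# ---------------------------------------------------------------------------
# calcifications, volume
# ---------------------------------------------------------------------------

def exclude_calcifications(mask: TendonMask, calcification: TendonMask) -> TendonMask:
    """Remove calcified voxels from the tendon mask (set difference)."""
    if not mask.same_grid(calcification):
        raise ValueError("grid mismatch between tendon and calcification masks")
    return mask.with_voxels(mask.voxels & ~calcification.voxels)


def mask_volume(mask: TendonMask) -> float:
    """Mask volume in mm³: true-voxel count × voxel volume."""
    return float(mask.n_voxels) * mask.grid.voxel_volume


def mask_volume_cm3(mask: TendonMask) -> float:
    return mask_volume(mask) / 1000.0


# ---------------------------------------------------------------------------
# downsampling
# ---------------------------------------------------------------------------

def _overlap_matrix(n_t: int, d_t: float, o_t: float,
                    n_s: int, d_s: float, o_s: float) -> np.ndarray:
    """(n_t, n_s) matrix of 1D interval overlaps (mm) between grid cells."""
    t_lo = o_t + np.arange(n_t) * d_t
    s_lo = o_s + np.arange(n_s) * d_s
    lo = np.maximum(t_lo[:, None], s_lo[None, :])
    hi = np.minimum(t_lo[:, None] + d_t, s_lo[None, :] + d_s)
    return np.clip(hi - lo, 0.0, None)


def occupancy_fractions(mask: TendonMask, target: GridSpec) -> np.ndarray:
    """Fraction of each target voxel's volume covered by true source voxels.

    Both grids must be axis-aligned; the overlap volume is separable into
    per-axis interval overlaps, contracted against the source mask.
    """
    src = mask.grid
    for (lo_t, hi_t), (lo_s, hi_s) in zip(target.extent(), src.extent()):
        if hi_t <= lo_s or hi_s <= lo_t:
            raise ValueError("grids do not overlap")
    W = [
        _overlap_matrix(target.shape[ax], target.voxel_dims[ax],
                        target.origin[ax], src.shape[ax],
                        src.voxel_dims[ax], src.origin[ax])
        for ax in range(3)
    ]
    vol = mask.voxels.astype(float)
    out = np.tensordot(W[0], vol, axes=(1, 0))          # (tx, sy, sz)
    out = np.tensordot(W[1], out, axes=(1, 1)).transpose(1, 0, 2)
    out = np.tensordot(W[2], out, axes=(1, 2)).transpose(1, 2, 0)
    return out / target.voxel_volume


def downsample_mask(mask: TendonMask, target: GridSpec,
                    occupancy_threshold: float = 0.5) -> TendonMask:
    """Resample a high-resolution mask to a coarser grid by occupancy.

    A target voxel is included iff the fraction of its volume covered by
    true source voxels is ≥ ``occupancy_threshold`` (ties included).
    """
    if not 0 < occupancy_threshold <= 1:
        raise ValueError("occupancy_threshold must be in (0, 1]")
    if any(dt < ds - 1e-9 for dt, ds in
           zip(target.voxel_dims, mask.voxel_dims)):
        raise ValueError("target grid must be coarser than (or equal to) "
                         "the source grid")
    occ = occupancy_fractions(mask, target)
    return TendonMask(
        occ >= occupancy_threshold, target.voxel_dims, target.origin,
        slice_axis=mask.slice_axis, proximal_end=mask.proximal_end,
        limb_side=mask.limb_side, left_direction=mask.left_direction,
    )


def downsample_region_labels(regions: RegionSet, mask: TendonMask,
                             target: GridSpec,
                             occupancy_threshold: float = 0.5) -> RegionSet:
    """Transfer a high-resolution region set to the DTI grid.

    The whole mask is downsampled by the occupancy rule; each included
    target voxel takes the longitudinal label (medial/central/lateral) with
    the largest occupancy among the three, ties resolving to central.
    Proximal/distal masks are downsampled independently (they overlap on an
    odd middle slice) and restricted to the downsampled whole mask.
    """
    whole_t = downsample_mask(mask, target, occupancy_threshold)
    out = {"whole": whole_t.voxels}
    if all(name in regions.masks for name in LONGITUDINAL_REGIONS):
        # central first: argmax takes the first maximum, so exact ties
        # between labels resolve to central
        order = ("central", "medial", "lateral")
        occ = np.stack([
            occupancy_fractions(mask.with_voxels(regions[name]), target)
            for name in order
        ])
        lab = np.argmax(occ, axis=0)
        for i, name in enumerate(order):
            out[name] = whole_t.voxels & (lab == i) & (occ[i] > 0)
        # voxels where every label occupancy is zero (possible when the whole
        # mask just clears the threshold through rounding) default to central
        unassigned = whole_t.voxels & ~(out["central"] | out["medial"]
                                        | out["lateral"])
        out["central"] |= unassigned
    for name in TRANSVERSE_REGIONS:
        if name in regions.masks:
            part = downsample_mask(mask.with_voxels(regions[name]), target,
                                   occupancy_threshold)
            out[name] = part.voxels & whole_t.voxels
    return RegionSet(out, target.voxel_dims, target.origin, mask.slice_axis,
                     provenance={"operation": "downsample_region_labels",
                                 "occupancy_threshold": occupancy_threshold})


# ---------------------------------------------------------------------------
# erosion
# ---------------------------------------------------------------------------

def _inplane_cross(slice_axis: int) -> np.ndarray:
    """3×3×3 structuring element: 4-connected cross within the slice plane."""
    st = np.zeros((3, 3, 3), dtype=bool)
    center = [1, 1, 1]
    st[tuple(center)] = True
    for ax in (0, 1, 2):
        if ax == slice_axis:
            continue
        for delta in (-1, 1):
            pos = center.copy()
            pos[ax] += delta
            st[tuple(pos)] = True
    return st


def erode_boundary(mask: TendonMask) -> TendonMask:
    """Erode one boundary pixel in-plane (2D, per slice).

    Erosion is deliberately two-dimensional: with 3 mm slices a 3D erosion
    would delete the first and last slices outright.  Slices eroded to
    empty stay empty.
    """
    if mask.is_empty:
        raise ValueError("cannot erode an empty mask")
    eroded = ndimage.binary_erosion(
        mask.voxels, structure=_inplane_cross(mask.slice_axis), border_value=0)
    return mask.with_voxels(eroded)


def erode_region_set(regions: RegionSet, mask: TendonMask) -> RegionSet:
    """Erode the whole-mask boundary and clip every region to it.

    Only the outer tendon boundary is eroded; internal boundaries between
    regions are untouched, matching a whole-mask erosion followed by region
    mask application.
    """
    whole_eroded = erode_boundary(mask.with_voxels(regions["whole"])).voxels
    out = {name: (arr if name == "whole" else arr) & whole_eroded
           for name, arr in regions.masks.items()}
    out["whole"] = whole_eroded
    return RegionSet(out, regions.voxel_dims, regions.origin,
                     regions.slice_axis,
                     provenance=dict(regions.provenance, eroded=True))
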