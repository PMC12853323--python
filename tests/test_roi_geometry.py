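"""Region geometry: diameters, trisection, bisection, volumes, resampling."""

import numpy as np
import pytest
from scipy import ndimage

from tendondti import (GridSpec, TendonMask, bisect_mask, downsample_mask,
                       erode_boundary, exclude_calcifications, longest_diameter,
                       mask_volume, trisect_mask)
from tendondti.roi_geometry import (downsample_region_labels, erode_region_set,
                                    full_region_set, occupancy_fractions)

from conftest import blob_mask


def simple_mask(vox, dims=(0.5, 0.5, 0.5), **kw):
    kwargs = dict(limb_side="right", left_direction="+x")
    kwargs.update(kw)
    return TendonMask(np.asarray(vox, dtype=bool), dims, **kwargs)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_diameter(slab: np.ndarray, dims2d) -> tuple[np.ndarray, np.ndarray, float]:
    """Exhaustive longest chord over all voxels of the largest component."""
    lab, n = ndimage.label(slab, structure=np.ones((3, 3), dtype=int))
    sizes = [np.sum(lab == i + 1) for i in range(n)]
    comp = lab == (int(np.argmax(sizes)) + 1)
    pts = (np.argwhere(comp) + 0.5) * np.asarray(dims2d)
    best = -1.0
    pairs = []
    for i in range(len(pts)):
        for j in range(len(pts)):
            d2 = float(((pts[i] - pts[j]) ** 2).sum())
            if d2 > best * (1 + 1e-12):
                best = d2
                pairs = []
            if d2 >= best * (1 - 1e-12):
                a, b = tuple(pts[i]), tuple(pts[j])
                pairs.append((a, b) if a <= b else (b, a))
    p1, p2 = min(pairs)
    return np.array(p1), np.array(p2), float(np.sqrt(best))


def oracle_trisect_slice(slab, dims2d, medial_vec2):
    """Per-voxel projection classification, written independently."""
    p1, p2, L = oracle_diameter(slab, dims2d)
    labels = np.zeros(slab.shape, dtype="U7")
    idx = np.argwhere(slab)
    if L < 3 * min(dims2d):
        for i, j in idx:
            labels[i, j] = "central"
        return labels
    axis = (p2 - p1) / L
    flip = float(axis @ medial_vec2) < 0
    for i, j in idx:
        c = (np.array([i, j]) + 0.5) * np.asarray(dims2d)
        t = float((c - p1) @ axis)
        if t < L / 3:
            lab = "lateral"
        elif t > 2 * L / 3:
            lab = "medial"
        else:
            lab = "central"
        if flip and lab != "central":
            lab = "medial" if lab == "lateral" else "lateral"
        labels[i, j] = lab
    return labels


def oracle_erode_2d(slab):
    """4-neighbour check: keep voxels whose in-plane neighbours all exist."""
    out = np.zeros_like(slab)
    for i, j in np.argwhere(slab):
        ok = True
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            a, b = i + di, j + dj
            if not (0 <= a < slab.shape[0] and 0 <= b < slab.shape[1]
                    and slab[a, b]):
                ok = False
                break
        out[i, j] = ok
    return out


# ---------------------------------------------------------------------------
# longest diameter
# ---------------------------------------------------------------------------

def test_diameter_of_voxel_row():
    """30 voxels in a row at 0.5 mm: extreme centers are 14.5 mm apart."""
    vox = np.zeros((30, 5, 3), dtype=bool)
    vox[:, 2, 1] = True
    seg = longest_diameter(simple_mask(vox), 1)
    assert seg.length == pytest.approx(14.5, abs=1e-12)
    assert abs(seg.axis[0]) == pytest.approx(1.0)
    assert seg.axis[1] == pytest.approx(0.0)


def test_diameter_of_digital_disk_matches_bruteforce():
    r = 10
    n = 2 * r + 3
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    disk = (ii - n // 2) ** 2 + (jj - n // 2) ** 2 <= r ** 2
    vox = disk[:, :, None]
    mask = simple_mask(vox, dims=(1.0, 1.0, 1.0))
    seg = longest_diameter(mask, 0)
    p1, p2, L = oracle_diameter(disk, (1.0, 1.0))
    assert seg.length == pytest.approx(L, abs=1e-12)
    assert abs(seg.length - 2 * r) <= 1.0          # within one voxel of 2r
    assert np.allclose(seg.p1, p1) and np.allclose(seg.p2, p2)


def test_diameter_random_blobs_match_bruteforce(rng):
    for trial in range(20):
        mask = blob_mask(rng, shape=(14, 11, 1))
        seg = longest_diameter(mask, 0)
        p1, p2, L = oracle_diameter(mask.voxels[:, :, 0], (0.5, 0.5))
        assert seg.length == pytest.approx(L, abs=1e-12)
        assert np.allclose(seg.p1, p1) and np.allclose(seg.p2, p2)


def test_diameter_degenerate_cases():
    vox = np.zeros((5, 5, 1), dtype=bool)
    vox[2, 2, 0] = True
    seg = longest_diameter(simple_mask(vox), 0)
    assert seg.length == 0.0
    assert seg.axis == (1.0, 0.0)
    with pytest.raises(ValueError, match="empty"):
        longest_diameter(simple_mask(np.zeros((5, 5, 1), bool)), 0)


# ---------------------------------------------------------------------------
# trisection
# ---------------------------------------------------------------------------

def test_trisect_axis_aligned_rectangle():
    """A 30×6 rectangle slice splits into three exact 10×6 thirds."""
    vox = np.zeros((34, 10, 2), dtype=bool)
    vox[2:32, 2:8, :] = True
    rs = trisect_mask(simple_mask(vox))
    assert rs.counts() == {"whole": 360, "medial": 120, "central": 120,
                           "lateral": 120}
    # medial is the high-x side for a right limb with subject-left = +x
    assert rs["medial"][22:32, 2:8, :].all()
    assert rs["lateral"][2:12, 2:8, :].all()


def test_trisect_rotated_rectangle_equal_counts():
    """A 30°-rotated rectangle still yields near-equal thirds."""
    H, W = 40, 40
    ii, jj = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    c, s = np.cos(np.pi / 6), np.sin(np.pi / 6)
    u = (ii - H / 2) * c + (jj - W / 2) * s
    v = -(ii - H / 2) * s + (jj - W / 2) * c
    rect = (np.abs(u) <= 15) & (np.abs(v) <= 3)
    rs = trisect_mask(simple_mask(rect[:, :, None]))
    counts = [rs.counts()[r] for r in ("medial", "central", "lateral")]
    # equal widths within one voxel row across the 6-voxel thickness
    assert max(counts) - min(counts) <= 7


@pytest.mark.parametrize("shape_name", ["L", "blob"])
def test_trisect_matches_projection_oracle(rng, shape_name):
    if shape_name == "L":
        vox = np.zeros((20, 16, 2), dtype=bool)
        vox[2:18, 2:6, :] = True
        vox[2:7, 2:14, :] = True
        masks = [simple_mask(vox)]
    else:
        masks = [blob_mask(rng) for _ in range(10)]
    for mask in masks:
        rs = trisect_mask(mask)
        med_vec = np.zeros(2)
        ax, sign = mask.medial_direction()
        med_vec[mask.inplane_axes.index(ax)] = sign
        for k in mask.occupied_slices():
            labels = oracle_trisect_slice(mask.voxels[:, :, k], (0.5, 0.5),
                                          med_vec)
            for name in ("medial", "central", "lateral"):
                got = rs[name][:, :, k]
                assert np.array_equal(got, labels == name), \
                    f"slice {k} region {name}"


def test_trisect_partition_invariants(rng):
    for _ in range(15):
        mask = blob_mask(rng)
        rs = trisect_mask(mask)
        m, c, l = rs["medial"], rs["central"], rs["lateral"]
        assert not (m & c).any() and not (m & l).any() and not (c & l).any()
        assert np.array_equal(m | c | l, mask.voxels)


def test_trisect_requires_laterality():
    vox = np.ones((6, 6, 3), dtype=bool)
    with pytest.raises(ValueError, match="limb_side"):
        trisect_mask(TendonMask(vox, (0.5, 0.5, 0.5),
                                left_direction="+x"))


def test_trisect_mirror_symmetry(rng):
    """Laterality resolution is anatomically consistent under mirroring.

    Flipping the limb side alone swaps medial and lateral voxel-for-voxel;
    reflecting the mask along the left–right axis alone swaps them under
    the reflection map; doing both (building the contralateral limb)
    leaves every label on the same tissue.
    """
    mask = blob_mask(rng, limb_side="right")
    rs = trisect_mask(mask)

    side_flipped = TendonMask(mask.voxels.copy(), mask.voxel_dims,
                              limb_side="left", left_direction="+x")
    rs_s = trisect_mask(side_flipped)
    assert np.array_equal(rs_s["medial"], rs["lateral"])
    assert np.array_equal(rs_s["lateral"], rs["medial"])
    assert np.array_equal(rs_s["central"], rs["central"])

    contralateral = TendonMask(mask.voxels[::-1, :, :].copy(),
                               mask.voxel_dims, limb_side="left",
                               left_direction="+x")
    rs_c = trisect_mask(contralateral)
    assert np.array_equal(rs_c["medial"], rs["medial"][::-1, :, :])
    assert np.array_equal(rs_c["lateral"], rs["lateral"][::-1, :, :])


# ---------------------------------------------------------------------------
# bisection
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n_slices,prox,dist,overlap", [
    (7, 4, 4, [3]),       # odd: middle slice (index 3) in both
    (6, 3, 3, []),        # even: disjoint halves
    (1, 1, 1, [0]),       # single slice in both
])
def test_bisect_slice_rules(n_slices, prox, dist, overlap):
    vox = np.zeros((4, 4, n_slices), dtype=bool)
    vox[1:3, 1:3, :] = True
    rs = bisect_mask(simple_mask(vox))
    prox_slices = np.unique(np.argwhere(rs["proximal"])[:, 2])
    dist_slices = np.unique(np.argwhere(rs["distal"])[:, 2])
    assert len(prox_slices) == prox and len(dist_slices) == dist
    both = sorted(set(prox_slices) & set(dist_slices))
    assert both == overlap
    assert np.array_equal(rs["proximal"] | rs["distal"], vox)


def test_bisect_respects_proximal_end():
    vox = np.zeros((4, 4, 6), dtype=bool)
    vox[1:3, 1:3, :] = True
    low = bisect_mask(simple_mask(vox, proximal_end="low"))
    high = bisect_mask(simple_mask(vox, proximal_end="high"))
    assert np.array_equal(low["proximal"], high["distal"])


# ---------------------------------------------------------------------------
# calcifications, volume
# ---------------------------------------------------------------------------

def test_exclude_calcifications_set_arithmetic():
    vox = np.zeros((5, 5, 4), dtype=bool)
    vox[1:4, 1:4, :] = True                      # 36 voxels
    calc = np.zeros_like(vox)
    calc[2, 2, :2] = True                        # 2 inside
    mask = simple_mask(vox)
    out = exclude_calcifications(mask, simple_mask(calc))
    assert out.n_voxels == 34
    # empty calcification mask is the identity
    same = exclude_calcifications(mask, simple_mask(np.zeros_like(vox)))
    assert np.array_equal(same.voxels, vox)
    # covering calcification leaves an empty mask; downstream ops reject it
    gone = exclude_calcifications(mask, simple_mask(vox.copy()))
    assert gone.is_empty
    with pytest.raises(ValueError):
        trisect_mask(gone)
    with pytest.raises(ValueError, match="grid mismatch"):
        exclude_calcifications(mask, simple_mask(vox[:, :, :2].copy()))


@pytest.mark.parametrize("count,dims,expected", [
    (100, (0.5, 0.5, 0.5), 12.5),
    (10, (1.4, 1.4, 3.0), 58.8),
    (0, (0.5, 0.5, 0.5), 0.0),
])
def test_mask_volume(count, dims, expected):
    vox = np.zeros((50, 50, 4), dtype=bool)
    vox.flat[:count] = True
    assert mask_volume(TendonMask(vox.reshape(50, 50, 4), dims)) \
        == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# downsampling
# ---------------------------------------------------------------------------

def test_downsample_exact_fill_and_tie_rule():
    # one 1×1×1 mm target voxel exactly filled by 8 half-mm voxels
    vox = np.zeros((4, 4, 4), dtype=bool)
    vox[:2, :2, :2] = True
    mask = simple_mask(vox)
    target = GridSpec((2, 2, 2), (1.0, 1.0, 1.0))
    occ = occupancy_fractions(mask, target)
    assert occ[0, 0, 0] == pytest.approx(1.0)
    out = downsample_mask(mask, target, 0.5)
    assert out.voxels[0, 0, 0] and out.n_voxels == 1

    # occupancy exactly 0.5 (4 of 8 sub-voxels) is included by the ≥ rule
    vox = np.zeros((4, 4, 4), dtype=bool)
    vox[:2, :2, 0] = True
    half = downsample_mask(simple_mask(vox), target, 0.5)
    assert occupancy_fractions(simple_mask(vox), target)[0, 0, 0] == 0.5
    assert half.voxels[0, 0, 0]


def test_downsample_matches_subvoxel_counting_oracle(rng):
    """Integer-ratio grids: occupancy equals exhaustive sub-voxel counts."""
    for _ in range(10):
        vox = rng.random((8, 8, 6)) < 0.4
        mask = simple_mask(vox)
        target = GridSpec((4, 4, 2), (1.0, 1.0, 1.5))
        occ = occupancy_fractions(mask, target)
        for i in range(4):
            for j in range(4):
                for k in range(2):
                    sub = vox[2 * i:2 * i + 2, 2 * j:2 * j + 2,
                              3 * k:3 * k + 3]
                    assert occ[i, j, k] == pytest.approx(sub.sum() / 12,
                                                         abs=1e-12)


def test_downsample_noninteger_ratio_matches_box_overlap_oracle(rng):
    """DTI-resolution grids (1.4 mm over 0.5 mm) vs direct box overlaps."""
    vox = rng.random((10, 10, 6)) < 0.5
    mask = simple_mask(vox)
    target = GridSpec((4, 4, 1), (1.4, 1.4, 3.0))
    occ = occupancy_fractions(mask, target)

    def overlap1d(lo1, hi1, lo2, hi2):
        return max(0.0, min(hi1, hi2) - max(lo1, lo2))

    for ti in range(4):
        for tj in range(4):
            for tk in range(1):
                vol = 0.0
                for si, sj, sk in np.argwhere(vox):
                    vol += (
                        overlap1d(1.4 * ti, 1.4 * (ti + 1), 0.5 * si, 0.5 * (si + 1))
                        * overlap1d(1.4 * tj, 1.4 * (tj + 1), 0.5 * sj, 0.5 * (sj + 1))
                        * overlap1d(3.0 * tk, 3.0 * (tk + 1), 0.5 * sk, 0.5 * (sk + 1)))
                assert occ[ti, tj, tk] == pytest.approx(vol / (1.4 * 1.4 * 3.0),
                                                        abs=1e-12)


def test_downsample_rejects_disjoint_and_finer_grids():
    vox = np.ones((4, 4, 4), dtype=bool)
    mask = simple_mask(vox)
    with pytest.raises(ValueError, match="overlap"):
        downsample_mask(mask, GridSpec((2, 2, 2), (1.0, 1.0, 1.0),
                                       origin=(100.0, 0.0, 0.0)))
    with pytest.raises(ValueError, match="coarser"):
        downsample_mask(mask, GridSpec((8, 8, 8), (0.25, 0.25, 0.25)))


# ---------------------------------------------------------------------------
# erosion
# ---------------------------------------------------------------------------

def test_erode_forced_cases():
    vox = np.zeros((5, 5, 1), dtype=bool)
    vox[1:4, 1:4, 0] = True
    out = erode_boundary(simple_mask(vox))
    assert np.argwhere(out.voxels).tolist() == [[2, 2, 0]]

    line = np.zeros((7, 5, 1), dtype=bool)
    line[1:6, 2, 0] = True
    assert erode_boundary(simple_mask(line)).is_empty


def test_erode_is_inplane_only():
    """A slab one slice thick survives: no erosion along the slice axis."""
    vox = np.zeros((7, 7, 1), dtype=bool)
    vox[1:6, 1:6, 0] = True
    out = erode_boundary(simple_mask(vox))
    assert out.n_voxels == 9


def test_erode_matches_neighbor_oracle(rng):
    for _ in range(10):
        mask = blob_mask(rng)
        out = erode_boundary(mask)
        for k in range(mask.voxels.shape[2]):
            assert np.array_equal(out.voxels[:, :, k],
                                  oracle_erode_2d(mask.voxels[:, :, k]))


# ---------------------------------------------------------------------------
# combined region sets and label transfer
# ---------------------------------------------------------------------------

def test_volume_additivity(rng):
    mask = blob_mask(rng, shape=(16, 12, 7))
    rs = full_region_set(mask)
    vol = {n: mask_volume(mask.with_voxels(rs[n])) for n in rs.names()}
    assert vol["medial"] + vol["central"] + vol["lateral"] \
        == pytest.approx(vol["whole"], rel=1e-12)
    # odd slice count: middle slice double-counted
    assert vol["proximal"] + vol["distal"] >= vol["whole"]


def test_region_label_transfer_partitions_downsampled_whole(rng):
    mask = blob_mask(rng, shape=(20, 16, 6), n_seeds=6)
    rs = full_region_set(mask)
    target = GridSpec((8, 6, 2), (1.4, 1.4, 1.6))
    out = downsample_region_labels(rs, mask, target, 0.5)
    m, c, l = out["medial"], out["central"], out["lateral"]
    assert np.array_equal(m | c | l, out["whole"])
    assert not (m & c).any() and not (m & l).any() and not (c & l).any()
    eroded = erode_region_set(out, mask.with_voxels(out["whole"]))
    assert eroded["whole"].sum() <= out["whole"].sum()
    assert np.array_equal(
        eroded["medial"] | eroded["central"] | eroded["lateral"],
        eroded["whole"])
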