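"""Synthetic tendon phantoms, raters and cohorts.

The phantom emulates a patellar-tendon DTI test–retest study: for each
participant, a pathological limb (tendinopathy or a bone–patellar
tendon–bone graft-harvest site) and a healthy contralateral limb; two scan
sessions within a week; two independent raters segmenting the session-1
anatomy and rater 1 alone segmenting session 2.

Geometry: a mildly bowed elliptic cylinder on a 0.5 mm isotropic
anatomical grid (~25 slices, in-plane radii of 8–15 voxels).  Tissue: a
transversely anisotropic tensor with the principal eigenvector along the
local tendon axis; healthy eigenvalues default to
(0.93, 0.80, 0.35)·10⁻³ mm²/s, reproducing the axial diffusivity (~0.92),
mean diffusivity (~0.69) and FA (~0.41) reported for healthy patellar
tendon.  Pathology raises diffusivity and lowers FA through a focal blob
(proximal-medial for tendinopathy, central third for graft harvest).

Raters are simulated by perturbing the mask's signed distance field with a
smooth (≈2 mm correlation length) zero-mean random field — segmentation
disagreement is spatially correlated, not voxel-wise salt-and-pepper.

Between-day repeatability is controlled analytically: each subject×limb
draws a diffusivity scale factor ``1 + a + e_s`` with
``a ~ N(0, ρσ²)`` shared across sessions and ``e_s ~ N(0, (1−ρ)σ²)`` per
session, so region-mean diffusivities have consistency ICC ρ in
expectation.  DWI noise is Rician with SNR defined on the b = 0 signal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .masks import GridSpec, TendonMask
from .protocols import DWIProtocol, DWIVolume
from .tensor_model import TensorField, pack_tensors

__all__ = [
    "TendonShape",
    "TissueParams",
    "CohortSpec",
    "LimbRecord",
    "CohortDataset",
    "make_tendon_mask",
    "make_tensor_field",
    "simulate_dwi",
    "perturb_rater",
    "simulate_cohort",
    "dice",
]

HEALTHY_LAMBDAS = (0.93e-3, 0.80e-3, 0.35e-3)   # mm²/s


@dataclass(frozen=True)
class TendonShape:
    """Curved elliptic-cylinder tendon geometry (all lengths in mm)."""

    n_slices: int = 25
    rx_mm: float = 6.0          # in-plane semi-axis, medial–lateral
    ry_mm: float = 4.0          # in-plane semi-axis, anterior–posterior
    bow_mm: float = 1.5         # peak lateral bowing of the centerline
    taper: float = 0.15         # fractional radius reduction at the distal end

    def __post_init__(self) -> None:
        if self.n_slices < 3:
            raise ValueError("tendon must span at least 3 slices")
        if self.rx_mm <= 0 or self.ry_mm <= 0:
            raise ValueError(
                "degenerate tendon shape: in-plane radii must be positive"
            )
        if not 0 <= self.taper < 1:
            raise ValueError("taper must lie in [0, 1)")


@dataclass(frozen=True)
class TissueParams:
    """Diffusion eigenvalues (mm²/s), principal axis and baseline signal."""

    lambda1: float = HEALTHY_LAMBDAS[0]
    lambda2: float = HEALTHY_LAMBDAS[1]
    lambda3: float = HEALTHY_LAMBDAS[2]
    principal_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    s0: float = 1.0

    def __post_init__(self) -> None:
        if not (self.lambda1 >= self.lambda2 >= self.lambda3 > 0):
            raise ValueError("require lambda1 >= lambda2 >= lambda3 > 0")
        ax = np.asarray(self.principal_axis, dtype=float)
        n = np.linalg.norm(ax)
        if n == 0:
            raise ValueError("principal_axis must be non-zero")
        object.__setattr__(self, "principal_axis", tuple(ax / n))

    @property
    def lambdas(self) -> np.ndarray:
        return np.array([self.lambda1, self.lambda2, self.lambda3])

    @property
    def md(self) -> float:
        return float(self.lambdas.mean())

    def scaled(self, factor: float) -> "TissueParams":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return dataclasses.replace(
            self, lambda1=self.lambda1 * factor, lambda2=self.lambda2 * factor,
            lambda3=self.lambda3 * factor)

    def blended(self, mu: float) -> "TissueParams":
        """Blend eigenvalues toward (μ > 0) or away from (μ < 0) isotropy."""
        lam = (1.0 - mu) * self.lambdas + mu * self.md
        if lam[2] <= 0:
            raise ValueError("isotropy blend produced a non-positive eigenvalue")
        return dataclasses.replace(self, lambda1=float(lam[0]),
                                   lambda2=float(lam[1]), lambda3=float(lam[2]))


# ---------------------------------------------------------------------------
# mask construction
# ---------------------------------------------------------------------------

def _centerline(shape: TendonShape, grid: GridSpec, slice_axis: int = 2):
    """Per-slice in-plane ellipse centers and radii (mm)."""
    a0, a1 = (a for a in (0, 1, 2) if a != slice_axis)
    nz = shape.n_slices
    frac = np.linspace(0.0, 1.0, nz)
    cx0 = grid.origin[a0] + grid.shape[a0] * grid.voxel_dims[a0] / 2.0
    cy0 = grid.origin[a1] + grid.shape[a1] * grid.voxel_dims[a1] / 2.0
    cx = cx0 + shape.bow_mm * np.sin(np.pi * frac)
    cy = np.full(nz, cy0)
    scale = 1.0 - shape.taper * frac
    return cx, cy, shape.rx_mm * scale, shape.ry_mm * scale


def make_tendon_mask(shape: TendonShape, grid: GridSpec | None = None, *,
                     limb_side: str = "right", left_direction: str = "+x",
                     proximal_end: str = "low",
                     voxel_dims: tuple[float, float, float] = (0.5, 0.5, 0.5),
                     ) -> TendonMask:
    """Rasterize a curved elliptic-cylinder tendon as a binary mask.

    If no grid is given, one is derived with a 2-voxel margin around the
    shape.  The result is a single connected component with every slice
    between the first and last occupied slice non-empty; a shape too thin
    to rasterize raises.
    """
    if grid is None:
        dx, dy, dz = voxel_dims
        nx = int(np.ceil(2 * (shape.rx_mm + shape.bow_mm) / dx)) + 4
        ny = int(np.ceil(2 * shape.ry_mm / dy)) + 4
        grid = GridSpec((nx, ny, shape.n_slices), voxel_dims)
    dx, dy, dz = grid.voxel_dims
    if shape.rx_mm < dx or shape.ry_mm < dy:
        raise ValueError(
            "degenerate tendon shape: in-plane radii smaller than a voxel "
            "would leave empty slices"
        )
    if grid.shape[2] < shape.n_slices:
        raise ValueError("grid too short for the requested slice count")

    cx, cy, rx, ry = _centerline(shape, grid)
    x = grid.origin[0] + (np.arange(grid.shape[0]) + 0.5) * dx
    y = grid.origin[1] + (np.arange(grid.shape[1]) + 0.5) * dy
    vox = np.zeros(grid.shape, dtype=bool)
    for k in range(shape.n_slices):
        ell = (((x[:, None] - cx[k]) / rx[k]) ** 2
               + ((y[None, :] - cy[k]) / ry[k]) ** 2) <= 1.0
        vox[:, :, k] = ell
        if not ell.any():
            raise ValueError(f"degenerate tendon shape: slice {k} is empty")

    labels, n = ndimage.label(vox, structure=np.ones((3, 3, 3), dtype=int))
    if n != 1:
        raise ValueError("tendon mask is not a single connected component; "
                         "reduce bowing or enlarge the radii")
    return TendonMask(vox, grid.voxel_dims, grid.origin, slice_axis=2,
                      proximal_end=proximal_end, limb_side=limb_side,
                      left_direction=left_direction)


# ---------------------------------------------------------------------------
# tensor field + DWI
# ---------------------------------------------------------------------------

def _slice_tangents(mask: TendonMask) -> dict[int, np.ndarray]:
    """Unit tangent of the mask centerline at each occupied slice."""
    occ = mask.occupied_slices()
    a0, a1 = mask.inplane_axes
    ax = mask.slice_axis
    cents = []
    for k in occ:
        idx = np.argwhere(mask.slice2d(int(k)))
        c = (idx.mean(axis=0) + 0.5) * np.array(
            [mask.voxel_dims[a0], mask.voxel_dims[a1]])
        cents.append(c)
    cents = np.asarray(cents)
    z = occ * mask.voxel_dims[ax]
    if len(occ) < 2:
        t = np.zeros(3)
        t[ax] = 1.0
        return {int(occ[0]): t}
    dxy = np.gradient(cents, z, axis=0)
    out = {}
    for i, k in enumerate(occ):
        t = np.zeros(3)
        t[a0], t[a1] = dxy[i]
        t[ax] = 1.0
        out[int(k)] = t / np.linalg.norm(t)
    return out


def make_tensor_field(mask: TendonMask, tissue: TissueParams,
                      pathology_map: np.ndarray | None = None,
                      pathology_gain: float = 0.5,
                      pathology_blend: float = 0.5) -> TensorField:
    """Analytic tensor field with principal eigenvector along the tendon.

    Each in-mask voxel holds ``D = R diag(λ1, λ2, λ3) Rᵀ`` with the first
    rotation column the local tendon-axis tangent.  A pathology map
    ``p ∈ [0, 1]`` rescales ``D → (1 + gain·p)((1 − blend·p) D + blend·p·MD·I)``
    — diffusivity rises and FA falls monotonically with p.  Parameter
    combinations that would produce non-positive eigenvalues raise.
    """
    if mask.is_empty:
        raise ValueError("cannot build a tensor field on an empty mask")
    if pathology_map is not None:
        p = np.asarray(pathology_map, dtype=float)
        if p.shape != mask.voxels.shape:
            raise ValueError("pathology map shape does not match the mask")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("pathology amplitudes must lie in [0, 1]")
        if 1.0 + pathology_gain * p.max() <= 0 or pathology_blend * p.max() >= 1 \
                or pathology_blend * p.min() < 0 or 1.0 + pathology_gain * p.min() <= 0:
            raise ValueError("pathology scaling would produce non-positive "
                             "eigenvalues")

    tangents = _slice_tangents(mask)
    lam = tissue.lambdas
    shape = mask.voxels.shape
    tensors = np.zeros(shape + (6,))
    ax = mask.slice_axis
    for k, t in tangents.items():
        slab = np.take(mask.voxels, k, axis=ax)
        if not slab.any():
            continue
        helper = np.array([1.0, 0.0, 0.0])
        if abs(t @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        u = helper - (helper @ t) * t
        u /= np.linalg.norm(u)
        v = np.cross(t, u)
        D = lam[0] * np.outer(t, t) + lam[1] * np.outer(u, u) \
            + lam[2] * np.outer(v, v)
        d6 = pack_tensors(D)
        sel = [slice(None)] * 3
        sel[ax] = k
        plane = tensors[tuple(sel)]
        plane[slab] = d6
        tensors[tuple(sel)] = plane

    if pathology_map is not None:
        md = np.sum(tensors[..., :3], axis=-1) / 3.0
        iso = np.zeros_like(tensors)
        iso[..., :3] = md[..., None]
        blend = pathology_blend * p[..., None]
        gain = 1.0 + pathology_gain * p[..., None]
        tensors = np.where(mask.voxels[..., None],
                           gain * ((1.0 - blend) * tensors + blend * iso),
                           tensors)

    s0 = np.where(mask.voxels, tissue.s0, 0.0)
    return TensorField(tensors, s0, mask.voxels.copy(), mask.voxels.copy(),
                       mask.voxel_dims, mask.origin,
                       meta={"method": "phantom"})


def simulate_dwi(tensor_field: TensorField, s0_map: np.ndarray | None,
                 protocol: DWIProtocol, snr: float = 30.0,
                 seed=None) -> DWIVolume:
    """Simulate a DWI acquisition from a tensor field.

    Noise-free signal ``S = S0·exp(−b gᵀDg)``; with finite SNR, Rician
    noise is applied: ``S' = sqrt((S + n1)² + n2²)`` with
    ``n1, n2 ~ N(0, (S0/snr)²)`` per voxel.  ``snr = inf`` (or None) gives
    the noise-free signal.  Reproducible for a fixed seed.
    """
    s0 = tensor_field.s0 if s0_map is None else np.asarray(s0_map, dtype=float)
    if s0.shape != tensor_field.tensors.shape[:3]:
        raise ValueError("protocol/tensor grid mismatch: S0 map shape "
                         "differs from the tensor grid")
    expo = np.tensordot(tensor_field.tensors, protocol.quad_design(),
                        axes=(3, 1))                     # (X, Y, Z, n)
    signal = s0[..., None] * np.exp(-expo)
    if snr is not None and np.isfinite(snr):
        if snr <= 0:
            raise ValueError("snr must be positive")
        rng = np.random.default_rng(seed)
        sigma = (s0 / snr)[..., None]
        n1 = rng.standard_normal(signal.shape) * sigma
        n2 = rng.standard_normal(signal.shape) * sigma
        signal = np.sqrt((signal + n1) ** 2 + n2 ** 2)
    return DWIVolume(signal, protocol, tensor_field.voxel_dims,
                     tensor_field.origin)


# ---------------------------------------------------------------------------
# raters
# ---------------------------------------------------------------------------

def perturb_rater(mask: TendonMask, amplitude_mm: float, seed=None,
                  correlation_mm: float = 2.0) -> TendonMask:
    """Simulate an independent rater's segmentation of the same anatomy.

    The mask's signed distance field (positive inside) is perturbed by a
    smooth zero-mean unit-variance Gaussian random field scaled to
    ``amplitude_mm`` and re-thresholded at zero; the largest connected
    component is kept.  Amplitude 0 returns the mask unchanged.
    """
    if amplitude_mm < 0:
        raise ValueError("perturbation amplitude must be non-negative")
    if mask.is_empty:
        raise ValueError("cannot perturb an empty mask")
    if amplitude_mm == 0:
        return mask.with_voxels(mask.voxels)
    rng = np.random.default_rng(seed)
    dims = np.asarray(mask.voxel_dims)
    sdf = (ndimage.distance_transform_edt(mask.voxels, sampling=dims)
           - ndimage.distance_transform_edt(~mask.voxels, sampling=dims))
    noise = rng.standard_normal(mask.voxels.shape)
    field = ndimage.gaussian_filter(noise, sigma=correlation_mm / dims)
    field -= field.mean()
    sd = field.std()
    if sd > 0:
        field /= sd
    new = (sdf + amplitude_mm * field) > 0
    labels, n = ndimage.label(new, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        raise ValueError("perturbation erased the mask; reduce the amplitude")
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        new = labels == (int(np.argmax(sizes)) + 1)
    return mask.with_voxels(new)


def dice(a: TendonMask | np.ndarray, b: TendonMask | np.ndarray) -> float:
    """Dice overlap coefficient between two binary masks."""
    va = a.voxels if isinstance(a, TendonMask) else np.asarray(a, dtype=bool)
    vb = b.voxels if isinstance(b, TendonMask) else np.asarray(b, dtype=bool)
    denom = va.sum() + vb.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((va & vb).sum()) / float(denom)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

DTI_VOXEL_DIMS = (1.4, 1.4, 3.0)


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic test–retest cohort.

    ``true_icc_retest`` maps each limb class to the consistency ICC that
    region-mean diffusivities should attain in expectation across the two
    sessions; ``tissue_cv`` is the total coefficient of variation of the
    diffusivity scale (split into subject and session components by the
    ICC).  Inter-rater agreement is governed by ``rater_jitter_mm``.
    """

    n_subjects: int = 10
    pathology_types: tuple[str, ...] = ("tendinopathy",) * 5 + ("bptb",) * 5
    true_icc_retest: dict = field(default_factory=lambda: {
        "pathological": 0.35, "contralateral": 0.8})
    tissue_cv: float = 0.05
    anisotropy_cv: float = 0.05
    shape_cv: float = 0.08
    rater_jitter_mm: float = 0.5
    snr: float = 30.0
    seed: int = 0
    base_shape: TendonShape = field(default_factory=TendonShape)
    dti_voxel_dims: tuple[float, float, float] = DTI_VOXEL_DIMS
    pathology_amplitude: float = 0.8

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if len(self.pathology_types) != self.n_subjects:
            raise ValueError(
                f"inconsistent spec dimensions: {len(self.pathology_types)} "
                f"pathology types for {self.n_subjects} subjects"
            )
        bad = set(self.pathology_types) - {"tendinopathy", "bptb"}
        if bad:
            raise ValueError(f"unknown pathology types: {sorted(bad)}")
        for limb, rho in self.true_icc_retest.items():
            if not 0 <= rho <= 1:
                raise ValueError(f"true ICC for {limb!r} outside [0, 1]")
        if not (self.snr > 0):
            raise ValueError("SNR must be positive (inf allowed)")
        if self.rater_jitter_mm < 0 or self.tissue_cv < 0 or self.shape_cv < 0:
            raise ValueError("variability parameters must be non-negative")


@dataclass
class LimbRecord:
    """Everything simulated for one subject×limb."""

    participant_id: str
    limb: str                       # pathological | contralateral
    limb_type: str                  # tendinopathy | bptb | healthy
    true_mask: TendonMask           # anatomical (high-res) grid
    rater_masks: dict               # (session, rater) -> TendonMask
    dwis: dict                      # session -> DWIVolume
    support_mask: TendonMask        # DTI-grid fit domain
    dti_grid: GridSpec
    truth: dict = field(default_factory=dict)


@dataclass
class CohortDataset:
    spec: CohortSpec
    protocol: DWIProtocol
    limbs: list


def _dti_grid_for(mask: TendonMask,
                  dti_dims: tuple[float, float, float]) -> GridSpec:
    hi = mask.grid
    shape = tuple(int(np.ceil(n * d / dt))
                  for n, d, dt in zip(hi.shape, hi.voxel_dims, dti_dims))
    return GridSpec(shape, dti_dims, hi.origin)


def _pathology_map(mask: TendonMask, limb_type: str, amplitude: float,
                   grid: GridSpec,
                   support: np.ndarray | None = None) -> np.ndarray | None:
    """Focal pathology amplitude map on the DTI grid.

    Tendinopathy: a proximal-medial blob; graft harvest (BPTB): a band over
    the central third of the tendon width, biased proximally.  The field is
    normalized so its mask-averaged severity equals ``amplitude / 4``
    regardless of the subject's tendon geometry — whole-tendon diffusivity
    uplift is then a limb-class constant and does not leak between-subject
    variance into the retest-ICC calibration.
    """
    if limb_type == "healthy" or amplitude == 0:
        return None
    med_axis, med_sign = mask.medial_direction()
    ax = mask.slice_axis
    coords = [(np.arange(n) + 0.5) * d + o
              for n, d, o in zip(grid.shape, grid.voxel_dims, grid.origin)]
    X = np.meshgrid(*coords, indexing="ij")
    lo = [c.min() for c in coords]
    hi = [c.max() for c in coords]
    span = [max(h - l, 1e-9) for l, h in zip(lo, hi)]
    # normalized coordinates in [0, 1]; medial = 1 on the medial axis
    u = [(X[a] - lo[a]) / span[a] for a in range(3)]
    if med_sign < 0:
        u[med_axis] = 1.0 - u[med_axis]
    z = u[ax] if mask.proximal_end == "low" else 1.0 - u[ax]
    if limb_type == "tendinopathy":
        d2 = ((u[med_axis] - 0.85) / 0.35) ** 2 + ((z - 0.15) / 0.35) ** 2
        p = np.exp(-0.5 * d2)
    else:                                           # bptb central-third defect
        d2 = ((u[med_axis] - 0.5) / 0.25) ** 2 + ((z - 0.3) / 0.6) ** 2
        p = np.exp(-0.5 * d2)
    p = np.clip(amplitude * p, 0.0, 1.0)
    if support is not None and support.any():
        target = amplitude / 4.0
        for _ in range(3):                          # renormalize after clipping
            m = p[support].mean()
            if m <= 0:
                break
            p = np.clip(p * (target / m), 0.0, 1.0)
    return p


def _variance_split(rho: float, total_sd: float) -> tuple[float, float]:
    """(subject SD, session SD) with subject²/(subject²+session²) = ρ."""
    return total_sd * np.sqrt(rho), total_sd * np.sqrt(1.0 - rho)


def simulate_cohort(spec: CohortSpec) -> CohortDataset:
    """Simulate a full test–retest cohort per the study design.

    For each subject×limb: one high-resolution tendon mask, two rater
    segmentations of session 1 and one rater-1 segmentation of session 2,
    and one DWI volume per session whose underlying tissue carries the
    subject and session random effects implied by the requested true
    retest ICCs.  Fully deterministic for a fixed spec (including seed).
    """
    protocol = DWIProtocol.standard()
    ss = np.random.SeedSequence(spec.seed)
    limbs: list[LimbRecord] = []
    subject_seeds = ss.spawn(spec.n_subjects)

    for i in range(spec.n_subjects):
        pid = f"S{i + 1:02d}"
        path_side = "right" if i % 2 == 0 else "left"
        limb_seeds = subject_seeds[i].spawn(2)
        for (limb, limb_type, side), limb_seed in zip((
            ("pathological", spec.pathology_types[i], path_side),
            ("contralateral", "healthy",
             "left" if path_side == "right" else "right"),
        ), limb_seeds):
            rng = np.random.default_rng(limb_seed)
            base = spec.base_shape
            shape = TendonShape(
                n_slices=int(base.n_slices + rng.integers(-2, 3)),
                rx_mm=float(base.rx_mm * (1 + spec.shape_cv * rng.standard_normal())),
                ry_mm=float(base.ry_mm * (1 + spec.shape_cv * rng.standard_normal())),
                bow_mm=base.bow_mm, taper=base.taper,
            )
            true_mask = make_tendon_mask(shape, limb_side=side)

            rater_masks = {}
            for key in (("session1", "rater1"), ("session1", "rater2"),
                        ("session2", "rater1")):
                rater_masks[key] = perturb_rater(
                    true_mask, spec.rater_jitter_mm,
                    seed=rng.integers(0, 2**31))

            dti_grid = _dti_grid_for(true_mask, spec.dti_voxel_dims)
            from .roi_geometry import downsample_mask  # local: avoid cycle
            true_dti = downsample_mask(true_mask, dti_grid, 0.5)
            support = ndimage.binary_dilation(true_dti.voxels, iterations=2)
            support_mask = true_dti.with_voxels(support)

            rho = spec.true_icc_retest.get(limb, 1.0)
            sd_subj, sd_sess = _variance_split(rho, spec.tissue_cv)
            sd_subj_b, sd_sess_b = _variance_split(rho, spec.anisotropy_cv)
            a = sd_subj * rng.standard_normal()
            mu_subj = sd_subj_b * rng.standard_normal()
            pmap = _pathology_map(true_mask, limb_type,
                                  spec.pathology_amplitude, dti_grid,
                                  support=support)

            dwis = {}
            session_truth = {}
            for s, session in enumerate(("session1", "session2")):
                e = sd_sess * rng.standard_normal()
                mu = mu_subj + sd_sess_b * rng.standard_normal()
                scale = float(np.clip(1.0 + a + e, 0.2, None))
                mu = float(np.clip(mu, -0.3, 0.6))
                tissue = TissueParams().scaled(scale).blended(mu)
                tf = make_tensor_field(support_mask, tissue,
                                       pathology_map=pmap)
                dwis[session] = simulate_dwi(
                    tf, None, protocol, snr=spec.snr,
                    seed=rng.integers(0, 2**31))
                session_truth[session] = {"scale": scale, "blend": mu,
                                          "lambdas": tissue.lambdas.tolist()}

            limbs.append(LimbRecord(
                participant_id=pid, limb=limb, limb_type=limb_type,
                true_mask=true_mask, rater_masks=rater_masks, dwis=dwis,
                support_mask=support_mask, dti_grid=dti_grid,
                truth={"subject_scale_effect": a, "sessions": session_truth,
                       "rho": rho},
            ))
    return CohortDataset(spec=spec, protocol=protocol, limbs=limbs)
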