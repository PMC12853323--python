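"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tendondti import DWIProtocol
from tendondti.masks import TendonMask


@pytest.fixture(scope="session")
def protocol() -> DWIProtocol:
    """The emulated acquisition: b = 800 s/mm², 30 directions, 4 b = 0."""
    return DWIProtocol.standard()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_tensors(rng: np.random.Generator, n: int,
                   lam_range=(0.2e-3, 2.0e-3)) -> np.ndarray:
    """Random positive-definite tensors with eigenvalues in lam_range."""
    lams = rng.uniform(*lam_range, size=(n, 3))
    q, _ = np.linalg.qr(rng.standard_normal((n, 3, 3)))
    return np.einsum("vik,vk,vjk->vij", q, lams, q)


def make_icc_table(rng: np.random.Generator, n: int = 10, s2p: float = 3.0,
                   s2e: float = 1.0, offset: float = 0.5,
                   factor: str = "rater") -> pd.DataFrame:
    """Balanced two-rating table with known variance components."""
    levels = ("rater1", "rater2") if factor == "rater" else \
        ("session1", "session2")
    rows = []
    for i in range(n):
        u = rng.normal(0.0, np.sqrt(s2p))
        for j, lev in enumerate(levels):
            rows.append({"participant_id": f"S{i:03d}", factor: lev,
                         "value": 10.0 + u + offset * j
                         + rng.normal(0.0, np.sqrt(s2e))})
    return pd.DataFrame(rows)


def anova_consistency_icc(table: pd.DataFrame, factor: str = "rater") -> float:
    """Mean-squares two-way consistency ICC, ICC(C,1) — independent oracle."""
    piv = table.pivot(index="participant_id", columns=factor,
                      values="value").to_numpy()
    n, k = piv.shape
    grand = piv.mean()
    msb = k * ((piv.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    resid = piv - piv.mean(axis=1, keepdims=True) \
        - piv.mean(axis=0, keepdims=True) + grand
    mse = (resid ** 2).sum() / ((n - 1) * (k - 1))
    return (msb - mse) / (msb + mse)


def blob_mask(rng: np.random.Generator, shape=(16, 12, 5),
              voxel_dims=(0.5, 0.5, 0.5), n_seeds: int = 4,
              **mask_kwargs) -> TendonMask:
    """Random connected blob: union of dilated seed boxes per slice."""
    from scipy import ndimage

    vox = np.zeros(shape, dtype=bool)
    cx, cy = shape[0] // 2, shape[1] // 2
    for k in range(shape[2]):
        sl = np.zeros(shape[:2], dtype=bool)
        sl[cx, cy] = True
        for _ in range(n_seeds):
            i = int(np.clip(cx + rng.integers(-shape[0] // 3, shape[0] // 3),
                            1, shape[0] - 2))
            j = int(np.clip(cy + rng.integers(-shape[1] // 3, shape[1] // 3),
                            1, shape[1] - 2))
            sl[i, j] = True
        sl = ndimage.binary_dilation(sl, iterations=2)
        # keep one component so slices stay connected through the center
        lab, nlab = ndimage.label(sl, structure=np.ones((3, 3), dtype=int))
        sl = lab == lab[cx, cy]
        vox[:, :, k] = sl
    kwargs = dict(limb_side="right", left_direction="+x")
    kwargs.update(mask_kwargs)
    return TendonMask(vox, voxel_dims, **kwargs)
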