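"""Diffusion acquisition protocols and the 4D volumes they index.

A :class:`DWIProtocol` is the gradient table of a diffusion-weighted
acquisition: one b-value (s/mm²) and one encoding direction per volume.
Directions must be unit vectors for diffusion-weighted (b > 0) volumes and
are arbitrary (conventionally zero) for b = 0 baselines, matching the FSL
bval/bvec dialect.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "DWIProtocol",
    "DWIVolume",
    "read_fsl_gradients",
    "write_fsl_gradients",
]

_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class DWIProtocol:
    """Gradient table: per-volume b-values and encoding directions.

    Parameters
    ----------
    bvalues : (n,) array
        Diffusion weighting per volume in s/mm²; all non-negative.
    directions : (n, 3) array
        Encoding directions; unit norm (±1e-6) wherever b > 0.
    """

    bvalues: np.ndarray
    directions: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.bvalues, dtype=float).ravel()
        g = np.asarray(self.directions, dtype=float)
        if g.ndim != 2 or g.shape[1] != 3:
            raise ValueError("directions must be an (n, 3) array")
        if b.shape[0] != g.shape[0]:
            raise ValueError(
                f"gradient table length mismatch: {b.shape[0]} b-values vs "
                f"{g.shape[0]} directions"
            )
        if np.any(b < 0):
            raise ValueError("b-values must be non-negative")
        weighted = b > 0
        norms = np.linalg.norm(g[weighted], axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise ValueError("directions for b > 0 volumes must be unit vectors")
        object.__setattr__(self, "bvalues", b)
        object.__setattr__(self, "directions", g)

    def __len__(self) -> int:
        return self.bvalues.shape[0]

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvalues == 0))

    @property
    def n_weighted(self) -> int:
        return len(self) - self.n_b0

    @classmethod
    def standard(cls, n_directions: int = 30, bvalue: float = 800.0,
                 n_b0: int = 4) -> "DWIProtocol":
        """The acquisition emulated throughout this package.

        Default: b = 800 s/mm², 30 directions near-uniform on the sphere
        (deterministic Fibonacci arrangement), plus 4 interleaved b = 0
        baselines with zero direction vectors.
        """
        dirs = _fibonacci_sphere(n_directions)
        b = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(bvalue))])
        g = np.vstack([np.zeros((n_b0, 3)), dirs])
        return cls(b, g)

    def quad_design(self) -> np.ndarray:
        """(n, 6) matrix mapping unique tensor components to b·gᵀDg.

        Column order (xx, yy, zz, xy, xz, yz); cross terms carry the
        factor 2 so that q @ d equals b·gᵀDg for d the packed tensor.
        """
        g = self.directions
        b = self.bvalues
        q = np.column_stack([
            g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ])
        return b[:, None] * q

    def design_matrix(self) -> np.ndarray:
        """(n, 7) log-linear design: ln S = [1, -q] @ [ln S0, d]."""
        return np.column_stack([np.ones(len(self)), -self.quad_design()])


@dataclass
class DWIVolume:
    """A 4D diffusion-weighted dataset and the protocol indexing it."""

    data: np.ndarray                      # (X, Y, Z, n) signal
    protocol: DWIProtocol
    voxel_dims: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4D (x, y, z, volume)")
        if self.data.shape[3] != len(self.protocol):
            raise ValueError(
                f"DWI has {self.data.shape[3]} volumes but the protocol "
                f"lists {len(self.protocol)}"
            )
        self.voxel_dims = tuple(float(v) for v in self.voxel_dims)
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform unit vectors (golden-spiral arrangement)."""
    i = np.arange(n)
    z = (2 * i + 1.0) / n - 1.0
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def write_fsl_gradients(protocol: DWIProtocol, bval_path, bvec_path) -> None:
    """Write FSL-dialect gradient files.

    bval: one line of space-separated b-values. bvec: three lines holding
    the x, y, z components of every direction.
    """
    bval_path, bvec_path = Path(bval_path), Path(bvec_path)
    bval_path.write_text(" ".join(_fmt(v) for v in protocol.bvalues) + "\n")
    lines = [" ".join(_fmt(v) for v in protocol.directions[:, ax])
             for ax in range(3)]
    bvec_path.write_text("\n".join(lines) + "\n")


def read_fsl_gradients(bval_path, bvec_path) -> DWIProtocol:
    b = np.loadtxt(bval_path, dtype=float).ravel()
    g = np.loadtxt(bvec_path, dtype=float)
    if g.shape[0] != 3:
        raise ValueError("bvec file must contain exactly three rows")
    return DWIProtocol(b, g.T)


def _fmt(v: float) -> str:
    return format(float(v), ".12g")
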