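"""Diffusion-encoding schemes: b-values and gradient directions.

Internally diffusivities are in µm²/ms, so b-values are converted to
ms/µm² (b[s/mm²] / 1000) whenever they multiply a diffusivity; the
stored ``bvals`` keep the conventional s/mm² unit of bval files.

File I/O follows the FSL dialect: ``.bval`` is one whitespace-separated
row of b-values, ``.bvec`` is three rows (x, y, z components).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GradientScheme", "load_scheme", "save_scheme", "generate_scheme"]

#: b-values at or below this (s/mm²) are treated as non-diffusion-weighted.
B0_THRESHOLD = 10.0


class SchemeFormatError(ValueError):
    """bval/bvec files disagree or are malformed."""


@dataclass(frozen=True)
class GradientScheme:
    """Per-acquisition b-values (s/mm²) and unit gradient directions.

    Directions for b≈0 acquisitions may be zero-vectors; all others are
    unit length.
    """

    bvals: np.ndarray
    dirs: np.ndarray
    b0_threshold: float = B0_THRESHOLD

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        dirs = np.asarray(self.dirs, dtype=float)
        if dirs.ndim != 2 or dirs.shape[1] != 3:
            raise SchemeFormatError(f"dirs must be (n, 3), got {dirs.shape}")
        if bvals.shape[0] != dirs.shape[0]:
            raise SchemeFormatError(
                f"{bvals.shape[0]} b-values vs {dirs.shape[0]} directions"
            )
        if np.any(bvals < 0):
            raise ValueError("negative b-values")
        if not np.all(np.isfinite(bvals)):
            raise ValueError("non-finite b-values")
        norms = np.linalg.norm(dirs, axis=1)
        dw = bvals > self.b0_threshold
        bad = dw & (np.abs(norms - 1.0) > 1e-6)
        if np.any(bad):
            raise ValueError(
                f"{bad.sum()} diffusion-weighted directions are not unit length"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "dirs", dirs)

    @property
    def n_acq(self) -> int:
        return self.bvals.shape[0]

    @property
    def is_b0(self) -> np.ndarray:
        """Boolean mask of non-diffusion-weighted acquisitions."""
        return self.bvals <= self.b0_threshold

    @property
    def b_ms_um2(self) -> np.ndarray:
        """b-values in ms/µm², consistent with diffusivities in µm²/ms."""
        return self.bvals / 1000.0

    @property
    def max_b(self) -> float:
        return float(self.bvals.max())


def load_scheme(bval_path: str | Path, bvec_path: str | Path) -> GradientScheme:
    """Read an FSL-style bval/bvec pair.

    Directions whose norm deviates from 1 by less than 1e-3 are
    renormalized; zero-vectors are accepted for b≈0 rows.
    """
    bvals = np.loadtxt(bval_path, ndmin=2).ravel()
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] != 3:
        if bvecs.shape[1] == 3:  # column-wise file
            bvecs = bvecs.T
        else:
            raise SchemeFormatError(f"bvec must have 3 rows, got {bvecs.shape}")
    if bvecs.shape[1] != bvals.shape[0]:
        raise SchemeFormatError(
            f"bval has {bvals.shape[0]} entries, bvec has {bvecs.shape[1]}"
        )
    if np.any(bvals < 0):
        raise ValueError("negative b-value in bval file")
    dirs = bvecs.T.astype(float).copy()
    norms = np.linalg.norm(dirs, axis=1)
    fix = (norms > 0) & (np.abs(norms - 1.0) < 1e-3)
    dirs[fix] /= norms[fix, None]
    return GradientScheme(bvals=bvals, dirs=dirs)


def save_scheme(scheme: GradientScheme, bval_path: str | Path, bvec_path: str | Path) -> None:
    """Write an FSL-style bval/bvec pair (full float precision)."""
    with open(bval_path, "w") as fh:
        fh.write(" ".join(repr(float(b)) for b in scheme.bvals) + "\n")
    with open(bvec_path, "w") as fh:
        for row in scheme.dirs.T:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def golden_spiral_directions(n: int, hemisphere: bool = False) -> np.ndarray:
    """Quasi-uniform unit vectors via the golden-angle spiral.

    With ``hemisphere=True`` points are confined to z ≥ 0 (antipodal
    symmetry makes a hemisphere sufficient for diffusion bases).
    """
    i = np.arange(n, dtype=float)
    if hemisphere:
        z = (i + 0.5) / n  # (0, 1]
    else:
        z = 1.0 - 2.0 * (i + 0.5) / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def generate_scheme(
    n_dirs: int = 99,
    b_max: float = 3000.0,
    n_b0: int = 1,
    seed: int = 0,
    shells: int | None = None,
) -> GradientScheme:
    """Generate a multi-b acquisition scheme.

    Directions are placed quasi-uniformly on the sphere (golden spiral,
    deterministic); b-values are spread over (0, b_max]. A spectrum of
    isotropic diffusivities is only identifiable from multiple b-values,
    so the default interleaves ``n_dirs`` uniformly spaced b-values
    across the spiral; pass ``shells`` to group them into that many
    discrete shells instead.

    Parameters
    ----------
    n_dirs:
        Number of diffusion-weighted directions (≥ 6).
    b_max:
        Maximum b-value in s/mm².
    n_b0:
        Number of leading b=0 acquisitions.
    seed:
        Rotates the spiral reproducibly so distinct seeds give distinct
        (equally uniform) direction sets.
    """
    if n_dirs < 6:
        raise ValueError("need at least 6 diffusion-weighted directions")
    if b_max <= 0:
        raise ValueError("b_max must be positive")
    # hemisphere placement: +d and −d encode the same diffusion
    # measurement, so a full-sphere set would waste near-antipodal pairs
    dirs = golden_spiral_directions(n_dirs, hemisphere=True)
    rng = np.random.default_rng(seed)
    # random rotation: QR of a Gaussian matrix, sign-fixed for determinism
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    dirs = dirs @ q.T
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    if shells is None:
        b_dw = np.linspace(b_max / n_dirs, b_max, n_dirs)
        # shuffle so nearby spiral points get well-separated b-values
        b_dw = rng.permutation(b_dw)
    else:
        edges = np.linspace(b_max / shells, b_max, shells)
        b_dw = edges[np.arange(n_dirs) % shells]
    bvals = np.concatenate([np.zeros(n_b0), b_dw])
    all_dirs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientScheme(bvals=bvals, dirs=all_dirs)
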