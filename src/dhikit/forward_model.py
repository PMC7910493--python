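"""DBSI forward signal model and closed-form DTI quantities.

A voxel's normalized diffusion-weighted signal is modelled as a linear
combination of discrete anisotropic (cylindrically symmetric) tensors
and a spectrum of isotropic tensors:

    S_k/S_0 = Σ_i f_i · exp(−b_k λ⊥i) · exp(−b_k (λ∥i − λ⊥i) cos²φ_ik)
            + Σ_j f(D_j) · exp(−b_k D_j)

with b_k in ms/µm², diffusivities in µm²/ms, and φ_ik the angle between
gradient direction k and the principal axis of component i. The
isotropic spectrum integral is discretized as a weighted sum on a grid
(the weights carry the measure), matching the NNLS representation used
for fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dhikit.gradients import GradientScheme

__all__ = [
    "AnisotropicComponent",
    "IsotropicSpectrum",
    "VoxelModel",
    "predict_signal",
    "dti_closed_forms",
    "add_noise",
]

#: Default isotropic-spectrum limits (µm²/ms): covers the hindered band's
#: upper edge (2.0) with headroom for free water.
SPECTRUM_LIMITS = (0.0, 3.0)


@dataclass(frozen=True)
class AnisotropicComponent:
    """One cylindrically symmetric diffusion tensor.

    Attributes
    ----------
    f:
        Signal-intensity fraction in [0, 1].
    lambda_par, lambda_perp:
        Axial and radial diffusivity (µm²/ms), λ∥ ≥ λ⊥ ≥ 0.
    axis:
        Unit principal direction.
    """

    f: float
    lambda_par: float
    lambda_perp: float
    axis: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"fraction {self.f} outside [0, 1]")
        if not (self.lambda_par >= self.lambda_perp >= 0.0):
            raise ValueError("need lambda_par >= lambda_perp >= 0")
        axis = np.asarray(self.axis, dtype=float).ravel()
        if axis.shape != (3,) or abs(np.linalg.norm(axis) - 1.0) > 1e-6:
            raise ValueError("axis must be a unit 3-vector")
        object.__setattr__(self, "axis", axis)


@dataclass(frozen=True)
class IsotropicSpectrum:
    """Discretized isotropic diffusivity spectrum f(D) on [a, b].

    ``grid`` is strictly increasing with grid[0] ≥ 0; ``weights`` are
    nonnegative signal-intensity fractions per grid point.
    """

    grid: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float).ravel()
        weights = np.asarray(self.weights, dtype=float).ravel()
        if grid.shape != weights.shape:
            raise ValueError("grid and weights must have equal length")
        if grid.size and (np.any(np.diff(grid) <= 0) or grid[0] < 0):
            raise ValueError("grid must be strictly increasing and nonnegative")
        if np.any(weights < 0):
            raise ValueError("negative spectrum weight")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "weights", weights)

    @property
    def total(self) -> float:
        return float(self.weights.sum())

    def band_fraction(self, lo: float, hi: float, include_lo: bool = False) -> float:
        """Sum of weights with lo < D ≤ hi (or lo ≤ D ≤ hi)."""
        lo_ok = self.grid >= lo if include_lo else self.grid > lo
        return float(self.weights[lo_ok & (self.grid <= hi)].sum())

    def band_mean_d(self, lo: float, hi: float, include_lo: bool = False) -> float:
        """Weight-averaged diffusivity within a band (NaN if empty)."""
        lo_ok = self.grid >= lo if include_lo else self.grid > lo
        sel = lo_ok & (self.grid <= hi)
        w = self.weights[sel]
        if w.sum() <= 0:
            return float("nan")
        return float((w * self.grid[sel]).sum() / w.sum())


def _empty_spectrum() -> IsotropicSpectrum:
    return IsotropicSpectrum(grid=np.empty(0), weights=np.empty(0))


@dataclass(frozen=True)
class VoxelModel:
    """Ground-truth or fitted voxel composition: anisotropic components
    plus an isotropic spectrum."""

    components: tuple[AnisotropicComponent, ...] = ()
    spectrum: IsotropicSpectrum = field(default_factory=_empty_spectrum)

    @property
    def total_fraction(self) -> float:
        return float(sum(c.f for c in self.components) + self.spectrum.total)

    @property
    def fiber_fraction(self) -> float:
        return float(sum(c.f for c in self.components))

    def is_normalized(self, tol: float = 1e-6) -> bool:
        return abs(self.total_fraction - 1.0) <= tol

    def to_dict(self) -> dict:
        return {
            "components": [
                {"f": c.f, "lambda_par": c.lambda_par, "lambda_perp": c.lambda_perp,
                 "axis": c.axis.tolist()}
                for c in self.components
            ],
            "spectrum": {"grid": self.spectrum.grid.tolist(),
                         "weights": self.spectrum.weights.tolist()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VoxelModel":
        comps = tuple(
            AnisotropicComponent(f=c["f"], lambda_par=c["lambda_par"],
                                 lambda_perp=c["lambda_perp"],
                                 axis=np.asarray(c["axis"]))
            for c in d.get("components", ())
        )
        spec = d.get("spectrum", {})
        return cls(components=comps,
                   spectrum=IsotropicSpectrum(np.asarray(spec.get("grid", [])),
                                              np.asarray(spec.get("weights", []))))


def predict_signal(
    model: VoxelModel,
    scheme: GradientScheme,
    allow_unnormalized: bool = False,
) -> np.ndarray:
    """Evaluate the forward model: per-acquisition S_k/S_0.

    Raises unless the model's fractions sum to 1 (override with
    ``allow_unnormalized`` for raw fitted models).
    """
    if not allow_unnormalized and not model.is_normalized():
        raise ValueError(
            f"model fractions sum to {model.total_fraction:.6f}, not 1; "
            "pass allow_unnormalized=True to evaluate anyway"
        )
    b = scheme.b_ms_um2
    signal = np.zeros(scheme.n_acq)
    for comp in model.components:
        cos_phi = scheme.dirs @ comp.axis
        signal += comp.f * np.exp(
            -b * comp.lambda_perp
            - b * (comp.lambda_par - comp.lambda_perp) * cos_phi**2
        )
    if model.spectrum.grid.size:
        # (n_acq, n_grid) attenuation matrix times spectrum weights
        signal += np.exp(-np.outer(b, model.spectrum.grid)) @ model.spectrum.weights
    return signal


def dti_closed_forms(eigvals: np.ndarray) -> dict[str, float]:
    """Mean diffusivity and fractional anisotropy from tensor eigenvalues.

    MD = mean(λ); FA = sqrt(3/2 · Σ(λ−MD)² / Σλ²), in [0, 1].
    """
    lam = np.asarray(eigvals, dtype=float).ravel()
    if lam.shape != (3,):
        raise ValueError("expected three eigenvalues")
    if np.any(lam < 0):
        raise ValueError("negative eigenvalue")
    ssq = float((lam**2).sum())
    if ssq == 0.0:
        raise ValueError("FA undefined for an all-zero tensor")
    md = float(lam.mean())
    fa = float(np.sqrt(1.5 * ((lam - md) ** 2).sum() / ssq))
    return {"MD": md, "FA": min(fa, 1.0)}


def add_noise(
    signals: np.ndarray,
    snr: float,
    model: str = "rician",
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Add magnitude-MRI noise to normalized signals.

    ``snr`` is referenced to S_0 = 1, so the Gaussian channel noise has
    σ = 1/snr. Rician noise (the magnitude of a complex Gaussian
    perturbation) is the default for magnitude images; ``gaussian``
    adds real-valued noise only.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    signals = np.asarray(signals, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = 1.0 / snr
    if model == "rician":
        e1 = rng.normal(0.0, sigma, signals.shape)
        e2 = rng.normal(0.0, sigma, signals.shape)
        return np.sqrt((signals + e1) ** 2 + e2**2)
    if model == "gaussian":
        return signals + rng.normal(0.0, sigma, signals.shape)
    raise ValueError(f"unknown noise model {model!r}")
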