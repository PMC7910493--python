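"""Landmark-driven 2-D thin-plate-spline histology-to-MRI registration.

A TPS warp interpolating n landmark pairs decomposes into an affine
part plus radial-basis warping with kernel U(r) = r² log r² (U(0) = 0),
subject to the side conditions Σw = 0 and Σw·p = 0 that make the
bending energy finite. Coordinates are pixel-centered, origin (0, 0),
x = column index.

ROI label transfer follows the forward direction: every histology pixel
is mapped through the fitted transform into MRI voxel coordinates and
each MRI voxel takes the majority label of the histology pixels landing
in it (ties left unlabeled).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "LandmarkSet",
    "TPSTransform",
    "rgb_to_grayscale",
    "fit_tps",
    "warp",
    "transfer_rois",
    "load_landmarks",
    "save_landmarks",
]


@dataclass(frozen=True)
class LandmarkSet:
    """Index-aligned (source, target) landmark pairs in pixel coords."""

    source: np.ndarray  # (n, 2), columns x, y
    target: np.ndarray

    def __post_init__(self) -> None:
        src = np.asarray(self.source, dtype=float)
        dst = np.asarray(self.target, dtype=float)
        if src.ndim != 2 or src.shape[1] != 2 or src.shape != dst.shape:
            raise ValueError("landmarks must be matching (n, 2) arrays")
        if src.shape[0] < 3:
            raise ValueError("need at least 3 landmark pairs")
        object.__setattr__(self, "source", src)
        object.__setattr__(self, "target", dst)

    @property
    def n(self) -> int:
        return self.source.shape[0]

    def swapped(self) -> "LandmarkSet":
        return LandmarkSet(source=self.target, target=self.source)


@dataclass(frozen=True)
class TPSTransform:
    """Fitted 2-D thin-plate spline mapping source -> target coords.

    ``affine`` is (3, 2): rows are the constant, x and y coefficients
    per output axis; ``weights`` is (n, 2); ``source`` holds the
    landmark source coordinates the kernel is centred on.
    """

    affine: np.ndarray
    weights: np.ndarray
    source: np.ndarray

    def __call__(self, points: np.ndarray) -> np.ndarray:
        """Map (m, 2) points through the spline."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        k = _tps_kernel(_pairwise_dist(pts, self.source))
        out = (np.column_stack([np.ones(len(pts)), pts]) @ self.affine
               + k @ self.weights)
        return out

    def bending_energy(self) -> float:
        """w' K w, summed over the two output axes (≥ 0 up to rounding)."""
        k = _tps_kernel(_pairwise_dist(self.source, self.source))
        return float(sum(self.weights[:, i] @ k @ self.weights[:, i]
                         for i in range(2)))


def rgb_to_grayscale(image: np.ndarray) -> np.ndarray:
    """ITU-R 601 luminance: 0.299 R + 0.587 G + 0.114 B.

    8-bit input returns rounded 8-bit output; float input stays float
    in the same range.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (h, w, 3) RGB image")
    weights = np.array([0.299, 0.587, 0.114])
    gray = image.astype(float) @ weights
    if np.issubdtype(image.dtype, np.integer):
        return np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    return gray


def _pairwise_dist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    """U(r) = r² log r², with the removable singularity U(0) = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        u = r**2 * np.log(r**2)
    return np.where(r > 0, u, 0.0)


def fit_tps(landmarks: LandmarkSet, regularization: float = 0.0) -> TPSTransform:
    """Solve the TPS linear system.

    With ``regularization`` 0 the spline interpolates the landmarks
    exactly; positive values (added to the kernel diagonal) trade
    landmark fidelity for lower bending energy.
    """
    if regularization < 0:
        raise ValueError("regularization must be >= 0")
    src, dst = landmarks.source, landmarks.target
    n = landmarks.n
    d = _pairwise_dist(src, src)
    if np.any(d[~np.eye(n, dtype=bool)] < 1e-9):
        raise np.linalg.LinAlgError("duplicate source landmarks")
    k = _tps_kernel(d) + regularization * np.eye(n)
    p = np.column_stack([np.ones(n), src])
    sys = np.zeros((n + 3, n + 3))
    sys[:n, :n] = k
    sys[:n, n:] = p
    sys[n:, :n] = p.T
    rhs = np.zeros((n + 3, 2))
    rhs[:n] = dst
    try:
        sol = np.linalg.solve(sys, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular TPS system (collinear or duplicate landmarks)") from exc
    if not np.all(np.isfinite(sol)):
        raise np.linalg.LinAlgError("singular TPS system")
    return TPSTransform(affine=sol[n:], weights=sol[:n], source=src.copy())


def warp(
    image: np.ndarray,
    transform: TPSTransform,
    output_shape: tuple[int, int],
    mode: str = "bilinear",
) -> np.ndarray:
    """Resample an image through the spline by inverse mapping.

    ``transform`` must map output-grid (x, y) coordinates to input
    coordinates — fit it on (output-landmark, input-landmark) pairs.
    Label masks should use ``nearest`` (no new label values appear);
    intensity images ``bilinear``. Out-of-domain pixels become 0.
    """
    if mode not in ("nearest", "bilinear"):
        raise ValueError(f"unknown interpolation mode {mode!r}")
    h, w = output_shape
    if h <= 0 or w <= 0:
        raise ValueError("output shape must be positive")
    ys, xs = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    # snap sub-nanopixel numerical noise so exact boundary coordinates
    # are not treated as out of bounds
    mapped = np.round(transform(pts), 9)  # input-space (x, y)
    coords = np.stack([mapped[:, 1].reshape(h, w), mapped[:, 0].reshape(h, w)])
    order = 0 if mode == "nearest" else 1
    out = ndimage.map_coordinates(
        np.asarray(image, dtype=float), coords, order=order,
        mode="constant", cval=0.0)
    if mode == "nearest" and np.issubdtype(np.asarray(image).dtype, np.integer):
        return out.astype(np.asarray(image).dtype)
    return out


def transfer_rois(
    roi_masks: dict[int, np.ndarray],
    transform: TPSTransform,
    mri_shape: tuple[int, int],
    background: int = -1,
) -> np.ndarray:
    """Majority-vote transfer of histology ROI labels to the MRI grid.

    ``roi_masks`` maps class code -> boolean mask on the (shared)
    histology grid; masks must be disjoint. ``transform`` maps
    histology pixel coordinates to MRI pixel coordinates (the forward
    fit). Each MRI voxel takes the label with the most covering
    histology pixels; uncovered voxels and exact ties stay
    ``background``.
    """
    h_mri, w_mri = mri_shape
    if not roi_masks:
        return np.full(mri_shape, background, dtype=int)
    shapes = {m.shape for m in roi_masks.values()}
    if len(shapes) != 1:
        raise ValueError("ROI masks must share the histology grid")
    stacked = np.stack([np.asarray(m, bool) for m in roi_masks.values()])
    if np.any(stacked.sum(0) > 1):
        raise ValueError("overlapping ROI masks")

    classes = sorted(roi_masks)
    counts = np.zeros((len(classes), h_mri, w_mri), dtype=np.int64)
    for ci, cls in enumerate(classes):
        mask = np.asarray(roi_masks[cls], bool)
        ys, xs = np.nonzero(mask)
        if ys.size == 0:
            continue
        mapped = transform(np.column_stack([xs, ys]).astype(float))
        # nearest MRI voxel for each histology pixel center
        mx = np.rint(mapped[:, 0]).astype(int)
        my = np.rint(mapped[:, 1]).astype(int)
        ok = (mx >= 0) & (mx < w_mri) & (my >= 0) & (my < h_mri)
        np.add.at(counts[ci], (my[ok], mx[ok]), 1)

    total = counts.sum(0)
    best = counts.argmax(0)
    best_count = counts.max(0)
    # a strict majority requires the top count to be unique
    runner_up = np.sort(counts, axis=0)[-2] if len(classes) > 1 else np.zeros_like(best_count)
    labels = np.full(mri_shape, background, dtype=int)
    decided = (total > 0) & (best_count > runner_up)
    labels[decided] = np.asarray(classes)[best[decided]]
    n_ties = int(((total > 0) & ~decided).sum())
    if n_ties:
        import logging
        logging.getLogger(__name__).warning(
            "transfer_rois: %d voxels left unlabeled due to ties", n_ties)
    return labels


def load_landmarks(path: str | Path) -> LandmarkSet:
    """TSV with columns x_src y_src x_dst y_dst (header optional)."""
    raw = np.genfromtxt(path, dtype=float)
    if raw.ndim == 1:
        raw = raw[None, :]
    if np.isnan(raw[0]).any():  # header row
        raw = raw[1:]
    if raw.shape[1] != 4:
        raise ValueError("expected 4 columns: x_src y_src x_dst y_dst")
    return LandmarkSet(source=raw[:, :2], target=raw[:, 2:])


def save_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("x_src\ty_src\tx_dst\ty_dst\n")
        for (xs, ys), (xd, yd) in zip(landmarks.source, landmarks.target):
            fh.write(f"{float(xs)!r}\t{float(ys)!r}\t{float(xd)!r}\t{float(yd)!r}\n")
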