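"""Affine mapping between H&E image pixels and the MSI spot grid.

The histology image and the MSI acquisition live in different coordinate
frames: the image in 0-based pixel indices (pixel-center convention), the
MSI raster in micrometers with spot ``(i, j)`` centered at
``((i + 0.5) * pitch, (j + 0.5) * pitch)``.  An :class:`AffineTransform2D`
maps image pixels to MSI micrometers.  A coarse transform is fitted from
manual control points; it can then be refined automatically by maximizing
the spatial correlation between a reference-ion image (by default the
collagen-derived tryptic peptide at m/z 1459.688, a reliable tissue-wide
signal) and the tissue mask derived from the H&E.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates, uniform_filter

__all__ = ["AffineTransform2D", "fit_affine", "refine_by_ion_image"]


@dataclass(frozen=True)
class AffineTransform2D:
    """2-D affine map ``p_um = linear @ p_px + translation``."""

    linear: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        lin = np.asarray(self.linear, dtype=float).reshape(2, 2)
        tr = np.asarray(self.translation, dtype=float).reshape(2)
        if abs(np.linalg.det(lin)) < 1e-15:
            raise ValueError("affine transform is singular (determinant ~ 0)")
        object.__setattr__(self, "linear", lin)
        object.__setattr__(self, "translation", tr)

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.eye(2), np.zeros(2))

    @classmethod
    def scale_translate(cls, scale: float, tx: float = 0.0, ty: float = 0.0) -> "AffineTransform2D":
        return cls(np.eye(2) * scale, np.array([tx, ty]))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (N, 2) array of (x, y) points; a single point is accepted too."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.linear.T + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    def inverse(self) -> "AffineTransform2D":
        inv = np.linalg.inv(self.linear)
        return AffineTransform2D(inv, -inv @ self.translation)

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """Return self ∘ other (apply ``other`` first)."""
        return AffineTransform2D(self.linear @ other.linear,
                                 self.linear @ other.translation + self.translation)

    def shapely_params(self) -> list[float]:
        """Coefficients [a, b, d, e, xoff, yoff] for shapely.affinity.affine_transform."""
        (a, b), (d, e) = self.linear
        return [a, b, d, e, self.translation[0], self.translation[1]]

    def to_json(self) -> str:
        return json.dumps({"linear": self.linear.tolist(),
                           "translation": self.translation.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "AffineTransform2D":
        d = json.loads(text)
        return cls(np.array(d["linear"]), np.array(d["translation"]))


def fit_affine(image_points: np.ndarray, msi_points_um: np.ndarray) -> tuple[AffineTransform2D, float]:
    """Least-squares affine fit from control-point pairs.

    Parameters
    ----------
    image_points : (N, 2) pixel coordinates.
    msi_points_um : (N, 2) matching MSI coordinates in micrometers.

    Returns
    -------
    (transform, rms_residual_um)

    Raises
    ------
    ValueError if fewer than 3 pairs are given or the points are collinear.
    """
    src = np.asarray(image_points, dtype=float).reshape(-1, 2)
    dst = np.asarray(msi_points_um, dtype=float).reshape(-1, 2)
    if src.shape[0] != dst.shape[0]:
        raise ValueError("control-point lists differ in length")
    if src.shape[0] < 3:
        raise ValueError("at least 3 control-point pairs are required")
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2:
        raise ValueError("control points are collinear; affine fit is degenerate")
    design = np.hstack([src, np.ones((src.shape[0], 1))])
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    transform = AffineTransform2D(coef[:2].T, coef[2])
    residual = transform.apply(src) - dst
    rms = float(np.sqrt(np.mean(np.sum(residual**2, axis=1))))
    return transform, rms


def _rotation(theta_deg: float) -> np.ndarray:
    t = np.deg2rad(theta_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s], [s, c]])


def refine_by_ion_image(
    t0: AffineTransform2D,
    tissue_mask: np.ndarray,
    msi,
    ref_mz: float = 1459.688,
    tol_ppm: float = 20.0,
    search_radius_um: float = 60.0,
    step_um: float = 5.0,
    max_rotation_deg: float = 0.0,
    rotation_step_deg: float = 0.25,
) -> tuple[AffineTransform2D, float]:
    """Refine a coarse image→MSI transform against a reference-ion image.

    A grid of candidate translations (and optionally small rotations about
    the spot-cloud centroid) around ``t0`` is scored by the Pearson
    correlation between the per-spot reference-ion intensity and the tissue
    mask sampled at the spot centers mapped back into the image.  The
    best-scoring transform is returned together with its score.

    The reference-ion image is the per-spot maximum intensity within
    ``ref_mz * (1 ± tol_ppm * 1e-6)``.  A flat ion image (zero variance)
    leaves ``t0`` unchanged with score NaN and a warning.
    """
    mask = np.asarray(tissue_mask)
    ion = _ion_image(msi, ref_mz, tol_ppm)
    if float(np.var(ion)) == 0.0:
        warnings.warn(f"reference ion m/z {ref_mz} image is flat; refinement skipped")
        return t0, float("nan")

    centers_um = msi.spot_centers_um()
    # Average the mask over one spot footprint so center sampling sees the
    # same spatial support as the MSI spot.
    px_per_spot = max(1, int(round(msi.pitch_um / _px_size_from(t0))))
    mask_f = uniform_filter(mask.astype(np.float32), size=px_per_spot, mode="constant")

    steps = np.arange(-search_radius_um, search_radius_um + step_um / 2, step_um) \
        if search_radius_um > 0 else np.array([0.0])
    if max_rotation_deg > 0:
        thetas = np.arange(-max_rotation_deg, max_rotation_deg + rotation_step_deg / 2,
                           rotation_step_deg)
    else:
        thetas = np.array([0.0])
    pivot = centers_um.mean(axis=0)

    best = (-np.inf, t0)
    for theta in thetas:
        rot = _rotation(float(theta))
        for dy in steps:
            for dx in steps:
                # rotate about the spot-cloud centroid, then shift
                lin = rot @ t0.linear
                tr = rot @ (t0.translation - pivot) + pivot + np.array([dx, dy])
                cand = AffineTransform2D(lin, tr)
                score = _mask_ion_correlation(cand, mask_f, centers_um, ion)
                if score > best[0]:
                    best = (score, cand)
    return best[1], float(best[0])


def _px_size_from(t: AffineTransform2D) -> float:
    return float(np.sqrt(abs(np.linalg.det(t.linear))))


def _mask_ion_correlation(t: AffineTransform2D, mask_f: np.ndarray,
                          centers_um: np.ndarray, ion: np.ndarray) -> float:
    px = t.inverse().apply(centers_um)
    # map_coordinates expects (row, col) = (y, x)
    sampled = map_coordinates(mask_f, [px[:, 1], px[:, 0]], order=1,
                              mode="constant", cval=0.0)
    if np.std(sampled) == 0:
        return -np.inf
    return float(np.corrcoef(sampled, ion)[0, 1])


def _ion_image(msi, ref_mz: float, tol_ppm: float) -> np.ndarray:
    if not (msi.mz_axis[0] <= ref_mz <= msi.mz_axis[-1]):
        raise ValueError(f"reference m/z {ref_mz} outside the dataset m/z axis")
    tol = ref_mz * tol_ppm * 1e-6
    lo = np.searchsorted(msi.mz_axis, ref_mz - tol, side="left")
    hi = np.searchsorted(msi.mz_axis, ref_mz + tol, side="right")
    if hi <= lo:
        # tolerance narrower than the axis spacing: use the nearest sample
        nearest = int(np.clip(np.searchsorted(msi.mz_axis, ref_mz), 1, msi.mz_axis.size - 1))
        lo = nearest - 1 if abs(msi.mz_axis[nearest - 1] - ref_mz) < \
            abs(msi.mz_axis[nearest] - ref_mz) else nearest
        hi = lo + 1
    return msi.intensities[:, lo:hi].max(axis=1)
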