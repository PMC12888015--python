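"""MSI spectral containers, imzML I/O, normalization and peak picking.

The central container is :class:`MSIDataset`: one spectrum per measured
raster spot, on a shared m/z axis, with integer grid coordinates and the
spot pitch in micrometers.  Processing follows the conventional MALDI-MSI
chain: root-mean-square normalization of every spectrum, per-ROI mean
spectra, and S/N-thresholded peak picking on those mean spectra.

Peak picking detects local maxima of the baseline-subtracted signal and
keeps a peak when (I − B) / noise ≥ ``snr_min`` (default 6) and
(I − B) ≥ ``rel_int_min`` × base-peak height (default 0.3%).  The baseline
is a linear interpolation of windowed low percentiles; noise is a windowed
median-absolute-deviation estimate (scaled by 1.4826 to match a Gaussian
standard deviation).  Apex m/z values are refined by a three-point
parabola.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "MSIDataset", "PeakList", "read_imzml", "write_imzml",
    "rms_normalize", "mean_spectrum", "pick_peaks", "match_peaks",
    "extract_peak_intensities",
]


@dataclass
class MSIDataset:
    """Spot-indexed mass spectra on a shared m/z axis.

    ``coordinates`` holds 0-based integer grid indices (x, y); the center
    of spot (i, j) sits at ((i + 0.5) * pitch, (j + 0.5) * pitch) μm in
    the MSI frame.
    """

    coordinates: np.ndarray          # (n_spots, 2) int
    mz_axis: np.ndarray              # (n_mz,) strictly increasing
    intensities: np.ndarray          # (n_spots, n_mz) >= 0
    pitch_um: float = 20.0
    normalization: str = "none"
    resampled: bool = False

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=int).reshape(-1, 2)
        self.mz_axis = np.asarray(self.mz_axis, dtype=float)
        self.intensities = np.asarray(self.intensities)
        if self.coordinates.shape[0] == 0:
            raise ValueError("dataset has no spots")
        if np.any(np.diff(self.mz_axis) <= 0):
            raise ValueError("m/z axis must be strictly increasing")
        if self.intensities.shape != (self.coordinates.shape[0], self.mz_axis.size):
            raise ValueError("intensities shape does not match spots x m/z axis")
        seen = set(map(tuple, self.coordinates))
        if len(seen) != self.coordinates.shape[0]:
            raise ValueError("duplicate spot coordinates")

    @property
    def n_spots(self) -> int:
        return self.coordinates.shape[0]

    def spot_index(self) -> dict[tuple[int, int], int]:
        return {(int(x), int(y)): i for i, (x, y) in enumerate(self.coordinates)}

    def spot_centers_um(self) -> np.ndarray:
        return (self.coordinates + 0.5) * self.pitch_um

    def spot_set(self) -> set[tuple[int, int]]:
        return set(map(tuple, self.coordinates.tolist()))


@dataclass
class PeakList:
    """Ordered picked peaks from one (mean) spectrum."""

    mz: np.ndarray
    intensity: np.ndarray            # baseline-subtracted apex height
    snr: np.ndarray
    snr_min: float = 6.0
    rel_int_min: float = 0.003
    source_roi: str = ""

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)
        order = np.argsort(self.mz)
        self.mz, self.intensity, self.snr = self.mz[order], self.intensity[order], self.snr[order]

    def __len__(self) -> int:
        return self.mz.size

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"mz": self.mz, "intensity": self.intensity,
                      "snr": self.snr}).to_csv(path, index=False)


# ---------------------------------------------------------------- imzML I/O

def write_imzml(ds: MSIDataset, path: str | Path) -> None:
    """Write a dataset as continuous-mode imzML 1.1 (+ ibd), float64 lossless.

    Spot grid indices are stored as the 1-based imzML pixel coordinates.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    with ImzMLWriter(str(path), mode="continuous",
                     mz_dtype=np.float64, intensity_dtype=np.float64) as writer:
        for i, (x, y) in enumerate(ds.coordinates):
            writer.addSpectrum(ds.mz_axis, np.asarray(ds.intensities[i], dtype=np.float64),
                               (int(x) + 1, int(y) + 1, 1))


def read_imzml(path: str | Path, pitch_um: float = 20.0) -> MSIDataset:
    """Read an imzML 1.1 file (continuous or processed mode).

    Continuous-mode files round-trip bit-exactly when written by
    :func:`write_imzml`.  Processed-mode spectra, which carry per-spot m/z
    axes, are resampled onto the union of all axes by linear interpolation
    and flagged with ``resampled=True``.

    The imzML standard does not oblige writers to store the raster pitch,
    so it is supplied by the caller (default 20 μm).
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    ibd = path.with_suffix(".ibd")
    if not ibd.exists():
        raise FileNotFoundError(f"missing binary data file: {ibd}")
    parser = ImzMLParser(str(path))
    try:
        if len(parser.coordinates) == 0:
            raise ValueError(f"{path} contains no spectra")
        mode_params = {p[0] for p in parser.metadata.file_description.cv_params}
        continuous = "continuous" in mode_params
        coords = np.array([(x - 1, y - 1) for (x, y, _z) in parser.coordinates], dtype=int)
        if continuous:
            mz_axis, first = parser.getspectrum(0)
            intens = np.empty((len(parser.coordinates), mz_axis.size), dtype=first.dtype)
            intens[0] = first
            for i in range(1, len(parser.coordinates)):
                _, intens[i] = parser.getspectrum(i)
            return MSIDataset(coords, np.asarray(mz_axis, float), intens, pitch_um=pitch_um)
        # processed mode: union grid + linear interpolation
        spectra = [parser.getspectrum(i) for i in range(len(parser.coordinates))]
        union = np.unique(np.concatenate([mz for mz, _ in spectra]))
        intens = np.zeros((len(spectra), union.size), dtype=float)
        for i, (mz, vals) in enumerate(spectra):
            intens[i] = np.interp(union, mz, vals, left=0.0, right=0.0)
        return MSIDataset(coords, union, intens, pitch_um=pitch_um, resampled=True)
    finally:
        parser.m.close()


# ----------------------------------------------------------- normalization

def rms_normalize(ds: MSIDataset) -> MSIDataset:
    """Divide each spectrum by its own root-mean-square intensity.

    All-zero spectra are left unchanged with a warning naming the spots.
    Re-normalizing an already normalized dataset is refused.
    """
    if ds.normalization != "none":
        raise ValueError(f"dataset already normalized ({ds.normalization})")
    rms = np.sqrt(np.mean(ds.intensities.astype(np.float64) ** 2, axis=1))
    zero = rms == 0
    if np.any(zero):
        bad = [tuple(c) for c in ds.coordinates[zero]]
        warnings.warn(f"all-zero spectra left unchanged at spots {bad}")
    scale = np.where(zero, 1.0, rms)
    return replace(ds, intensities=ds.intensities / scale[:, None],
                   normalization="rms")


def mean_spectrum(ds: MSIDataset, spots) -> np.ndarray:
    """Arithmetic mean spectrum over a set of (x, y) spot indices."""
    spots = set(map(tuple, spots))
    if not spots:
        raise ValueError("empty spot set")
    index = ds.spot_index()
    missing = spots - set(index)
    if missing:
        raise ValueError(f"spots not present in dataset: {sorted(missing)[:5]}...")
    rows = sorted(index[s] for s in spots)
    return ds.intensities[rows].mean(axis=0, dtype=np.float64)


# ------------------------------------------------------------ peak picking

def _windowed_profile(mz: np.ndarray, values: np.ndarray, window_da: float,
                      reducer) -> np.ndarray:
    """Piecewise-linear profile of per-window statistics along the axis."""
    lo, hi = mz[0], mz[-1]
    n_win = max(1, int(np.ceil((hi - lo) / window_da)))
    edges = np.linspace(lo, hi, n_win + 1)
    centers, stats = [], []
    idx = np.searchsorted(mz, edges)
    for k in range(n_win):
        a, b = idx[k], max(idx[k + 1], idx[k] + 1)
        chunk = values[a:b]
        if chunk.size == 0:
            continue
        centers.append(0.5 * (edges[k] + edges[k + 1]))
        stats.append(reducer(chunk))
    return np.interp(mz, centers, stats)


def baseline_estimate(mz: np.ndarray, intensity: np.ndarray,
                      window_da: float = 50.0, percentile: float = 50.0) -> np.ndarray:
    """Baseline as interpolated per-window low percentile."""
    return _windowed_profile(mz, intensity, window_da,
                             lambda c: np.percentile(c, percentile))


def noise_estimate(mz: np.ndarray, residual: np.ndarray,
                   window_da: float = 50.0) -> np.ndarray:
    """Windowed robust noise: 1.4826 × MAD of the baseline-subtracted signal."""
    def mad(chunk):
        med = np.median(chunk)
        return 1.4826 * np.median(np.abs(chunk - med))
    return _windowed_profile(mz, residual, window_da, mad)


def pick_peaks(mz: np.ndarray, intensity: np.ndarray,
               snr_min: float = 6.0, rel_int_min: float = 0.003,
               baseline_window_da: float = 50.0, noise_window_da: float = 50.0,
               baseline_percentile: float = 50.0,
               source_roi: str = "") -> PeakList:
    """S/N- and relative-intensity-thresholded peak picking on one spectrum."""
    from scipy.signal import find_peaks

    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mz.size != intensity.size or mz.size < 3:
        raise ValueError("spectrum must have >= 3 points with matching axes")
    baseline = baseline_estimate(mz, intensity, baseline_window_da, baseline_percentile)
    residual = intensity - baseline
    if np.all(residual == residual[0]):
        return PeakList(np.array([]), np.array([]), np.array([]),
                        snr_min, rel_int_min, source_roi)
    noise = noise_estimate(mz, residual, noise_window_da)
    floor = max(1e-12, 1e-9 * float(np.max(np.abs(residual))))
    noise = np.maximum(noise, floor)

    apex, _ = find_peaks(residual)
    if apex.size == 0:
        return PeakList(np.array([]), np.array([]), np.array([]),
                        snr_min, rel_int_min, source_roi)
    height = residual[apex]
    snr = height / noise[apex]
    keep = (snr >= snr_min) & (height >= rel_int_min * residual.max())
    apex, height, snr = apex[keep], height[keep], snr[keep]

    # three-point parabolic apex refinement (index space -> m/z)
    refined = mz[apex].copy()
    for j, k in enumerate(apex):
        if 0 < k < mz.size - 1:
            y0, y1, y2 = residual[k - 1], residual[k], residual[k + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                delta = 0.5 * (y0 - y2) / denom
                delta = float(np.clip(delta, -0.5, 0.5))
                refined[j] = mz[k] + delta * 0.5 * (mz[min(k + 1, mz.size - 1)] - mz[max(k - 1, 0)])
    return PeakList(refined, height, snr, snr_min, rel_int_min, source_roi)


def match_peaks(list_a, list_b, tol_ppm: float = 20.0):
    """One-to-one greedy nearest matching of two sorted m/z lists.

    Returns (common, only_a, only_b) where ``common`` is a list of index
    pairs (i_a, i_b) and the others are index lists.  Partition sizes are
    conserved: len(common) + len(only_a) == len(list_a), same for b.
    """
    mz_a = np.asarray(list_a.mz if isinstance(list_a, PeakList) else list_a, float)
    mz_b = np.asarray(list_b.mz if isinstance(list_b, PeakList) else list_b, float)
    pairs = []
    for i, a in enumerate(mz_a):
        tol = a * tol_ppm * 1e-6
        lo = np.searchsorted(mz_b, a - tol, side="left")
        hi = np.searchsorted(mz_b, a + tol, side="right")
        for j in range(lo, hi):
            pairs.append((abs(mz_b[j] - a), i, j))
    pairs.sort()
    used_a, used_b, common = set(), set(), []
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        common.append((i, j))
    only_a = [i for i in range(mz_a.size) if i not in used_a]
    only_b = [j for j in range(mz_b.size) if j not in used_b]
    return common, only_a, only_b


# ------------------------------------------------- per-spot peak intensity

def extract_peak_intensities(ds: MSIDataset, peak_mzs, tol_ppm: float = 20.0,
                             spots=None,
                             baseline_window_da: float = 50.0,
                             baseline_percentile: float = 50.0) -> np.ndarray:
    """Per-spot intensity of each m/z feature.

    The intensity of a feature is the maximum of the baseline-subtracted
    signal within ± tol_ppm of the feature m/z in each spot's spectrum —
    the same quantity an ion image renders.  Features with no axis samples
    in their window yield 0.  Returns an (n_spots, n_features) array in the
    order of ``spots`` (defaults to dataset order).
    """
    peak_mzs = np.asarray(peak_mzs, dtype=float)
    if spots is None:
        rows = np.arange(ds.n_spots)
    else:
        index = ds.spot_index()
        rows = np.array([index[tuple(s)] for s in spots], dtype=int)
    mz = ds.mz_axis
    out = np.zeros((rows.size, peak_mzs.size), dtype=float)
    # per-spot baselines via the shared windowed-percentile profile
    for r_out, r in enumerate(rows):
        spec = ds.intensities[r].astype(np.float64)
        resid = spec - baseline_estimate(mz, spec, baseline_window_da, baseline_percentile)
        for f, pm in enumerate(peak_mzs):
            tol = pm * tol_ppm * 1e-6
            lo = np.searchsorted(mz, pm - tol, side="left")
            hi = np.searchsorted(mz, pm + tol, side="right")
            if hi <= lo:
                # tolerance narrower than the axis spacing: fall back to
                # the nearest axis sample so the feature is still read
                nearest = int(np.clip(np.searchsorted(mz, pm), 1, mz.size - 1))
                lo = nearest - 1 if abs(mz[nearest - 1] - pm) < abs(mz[nearest] - pm) else nearest
                hi = lo + 1
            out[r_out, f] = max(0.0, float(resid[lo:hi].max()))
    return out
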