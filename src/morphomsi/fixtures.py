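"""Synthetic paired H&E + MALDI-MSI fixtures with planted ground truth.

Real thyroid TMA datasets pair a high-resolution H&E scan with a 20 μm
MSI raster; the tissue alternates cell-rich follicular rims with smooth,
colloid-filled lumens.  Colloid suppresses tryptic-peptide signal and
promotes matrix (HCCA) cluster adducts, which is exactly the contrast the
morphology-guided ROI selection is meant to exploit.  This module builds a
desk-scale phantom of that situation:

* an RGB H&E-like raster at 0.44 μm/px — hematoxylin-dominant, highly
  textured follicle rims (cell-rich); smooth eosin-pale lumens (colloid);
  intermediate inter-follicular tissue — plus pixel-exact ground-truth
  masks;
* training annotations (cell_rich / non_cell_rich) and deliberately coarse
  pathologist-style diagnosis polygons that engulf the colloid lumens, as
  real subcore annotations do;
* an imzML spectral cube on the MSI grid in which per-diagnosis peptide
  peaks scale with the cell-rich fraction of each spot footprint,
  HCCA-adduct interferents scale with 1 + enrichment × colloid fraction,
  and trypsin-autolysis peaks are spatially uniform;
* a planted affine transform between the two frames, emitted as ground
  truth for registration tests.

Every output is a pure function of (phantom, model, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import Point, box
from shapely.ops import unary_union

from .annotations import AnnotationSet
from .registration import AffineTransform2D
from .spectra import MSIDataset, write_imzml

# Interferent panel observed in HCCA-matrix tryptic MSI: matrix cluster
# adducts plus trypsin autolysis products.
HCCA_ADDUCT_MZ = (839.08, 845.09, 855.05, 861.06, 867.08,
                  1036.13, 1044.09, 1054.08, 1060.06, 1066.08)
TRYPSIN_AUTOLYSIS_MZ = (842.51, 1045.56, 1220.64)


@dataclass
class Follicle:
    center_um: tuple[float, float]   # relative to core center
    lumen_radius_um: float
    rim_thickness_um: float

    @property
    def outer_radius_um(self) -> float:
        return self.lumen_radius_um + self.rim_thickness_um


@dataclass
class CorePhantom:
    center_um: tuple[float, float]
    radius_um: float
    diagnosis_label: str
    follicles: list[Follicle] = field(default_factory=list)
    class_signature: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class SpectrumModel:
    """Generative model for per-spot spectra.

    Peptide amplitudes scale with the cell-rich fraction of the spot;
    interferents with (1 + colloid_enrichment × colloid fraction); trypsin
    peaks are uniform; reference peaks (e.g. the collagen-derived peptide
    used for registration) scale with total tissue fraction.
    """

    peptide_peaks: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    shared_peptide_peaks: list[tuple[float, float]] = field(default_factory=list)
    reference_peaks: list[tuple[float, float]] = field(default_factory=list)
    interferent_peaks: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(mz, 8.0, 4.0) for mz in HCCA_ADDUCT_MZ])
    trypsin_peaks: list[tuple[float, float]] = field(
        default_factory=lambda: [(mz, 12.0) for mz in TRYPSIN_AUTOLYSIS_MZ])
    peak_sigma_da: float = 0.08
    baseline_level: float = 3.0
    noise_sd: float = 1.0

    def __post_init__(self):
        amps = ([a for peaks in self.peptide_peaks.values() for _, a in peaks]
                + [a for _, a in self.shared_peptide_peaks]
                + [a for _, a in self.reference_peaks]
                + [a for _, a, _ in self.interferent_peaks]
                + [a for _, a in self.trypsin_peaks])
        if any(a < 0 for a in amps):
            raise ValueError("peak amplitudes must be >= 0")
        if self.peak_sigma_da <= 0:
            raise ValueError("peak_sigma_da must be > 0")
        if any(e < 1.0 for _, _, e in self.interferent_peaks):
            raise ValueError("colloid enrichment factors must be >= 1")

    def all_peak_mzs(self) -> list[float]:
        return sorted({mz for peaks in self.peptide_peaks.values() for mz, _ in peaks}
                      | {mz for mz, _ in self.shared_peptide_peaks}
                      | {mz for mz, _ in self.reference_peaks}
                      | {mz for mz, _, _ in self.interferent_peaks}
                      | {mz for mz, _ in self.trypsin_peaks})


@dataclass
class FixturePhantom:
    cores: list[CorePhantom] = field(default_factory=list)
    image_px_size_um: float = 0.44
    msi_pitch_um: float = 20.0
    mz_range: tuple[float, float] = (700.0, 3000.0)
    mz_spacing_da: float = 0.05
    seed: int = 0
    image_size_um: tuple[float, float] | None = None
    planted_transform: AffineTransform2D | None = None
    max_image_px: int = 4096

    def __post_init__(self):
        if self.msi_pitch_um / self.image_px_size_um <= 1:
            raise ValueError("MSI pitch must be coarser than the image pixel size")
        if self.planted_transform is None:
            self.planted_transform = AffineTransform2D.scale_translate(self.image_px_size_um)
        if self.image_size_um is None:
            margin = 40.0
            ext = max((c.center_um[0] + c.radius_um for c in self.cores), default=200.0)
            eyt = max((c.center_um[1] + c.radius_um for c in self.cores), default=200.0)
            self.image_size_um = (ext + margin, eyt + margin)
        for core in self.cores:
            for dim, c in zip(self.image_size_um, core.center_um):
                if c - core.radius_um < 0 or c + core.radius_um > dim:
                    raise ValueError(f"core at {core.center_um} exceeds image bounds")

    @property
    def image_shape_px(self) -> tuple[int, int]:
        w = int(round(self.image_size_um[0] / self.image_px_size_um))
        h = int(round(self.image_size_um[1] / self.image_px_size_um))
        return h, w

    def mz_axis(self) -> np.ndarray:
        lo, hi = self.mz_range
        n = int(round((hi - lo) / self.mz_spacing_da)) + 1
        return lo + np.arange(n) * self.mz_spacing_da


@dataclass
class HEScene:
    """Rendered H&E raster plus pixel-exact ground truth."""

    image: np.ndarray                       # H x W x 3 uint8
    masks: dict[str, np.ndarray]            # cell_rich / colloid / tissue, bool
    core_id_map: np.ndarray                 # H x W int, -1 = background
    training: AnnotationSet
    pathologist: AnnotationSet
    px_size_um: float


# ------------------------------------------------------------ H&E rendering

_REGION_COLORS = {
    # (RGB base, per-pixel noise SD): cell-rich is hematoxylin-dominant and
    # strongly textured, colloid is smooth eosin-pale, inter-follicular
    # tissue is intermediate.
    "cell_rich": ((112, 78, 152), 30.0),
    "colloid": ((238, 200, 216), 2.0),
    "tissue_other": ((208, 158, 188), 5.0),
    "background": ((246, 246, 248), 1.5),
}


def render_he_image(phantom: FixturePhantom,
                    n_training_per_class: int = 15,
                    training_box_um: float = 8.0) -> HEScene:
    """Render the H&E-like raster, masks and both annotation sets."""
    h, w = phantom.image_shape_px
    if h > phantom.max_image_px or w > phantom.max_image_px:
        raise ValueError(
            f"image of {h}x{w} px exceeds the fixture cap of {phantom.max_image_px}; "
            "shrink the phantom or raise max_image_px")
    px = phantom.image_px_size_um
    ys, xs = np.mgrid[0:h, 0:w]
    xum = xs * px
    yum = ys * px

    cell = np.zeros((h, w), dtype=bool)
    colloid = np.zeros((h, w), dtype=bool)
    tissue = np.zeros((h, w), dtype=bool)
    core_id = np.full((h, w), -1, dtype=np.int16)
    for ci, core in enumerate(phantom.cores):
        cx, cy = core.center_um
        in_core = (xum - cx) ** 2 + (yum - cy) ** 2 <= core.radius_um ** 2
        tissue |= in_core
        core_id[in_core] = ci
        for fol in core.follicles:
            fx, fy = cx + fol.center_um[0], cy + fol.center_um[1]
            d2 = (xum - fx) ** 2 + (yum - fy) ** 2
            lum = d2 <= fol.lumen_radius_um ** 2
            rim = (d2 <= fol.outer_radius_um ** 2) & ~lum
            colloid |= lum & in_core
            cell |= rim & in_core
    cell &= ~colloid  # lumen wins where follicles of one core overlap

    rng = np.random.default_rng([phantom.seed, 0])
    image = np.empty((h, w, 3), dtype=np.float64)
    base, sd = _REGION_COLORS["background"]
    image[:] = base
    noise = rng.normal(0.0, 1.0, size=(h, w, 3))
    sd_map = np.full((h, w), sd)
    other = tissue & ~cell & ~colloid
    for name, mask in (("tissue_other", other), ("colloid", colloid), ("cell_rich", cell)):
        base, sd = _REGION_COLORS[name]
        image[mask] = base
        sd_map[mask] = sd
    image += noise * sd_map[..., None]
    image = np.clip(image, 0, 255).astype(np.uint8)

    if phantom.cores:
        training = _sample_training_annotations(
            cell, colloid, other, px, rng, n_training_per_class, training_box_um)
        pathologist = _pathologist_annotations(phantom)
    else:
        training = AnnotationSet(provenance="training")
        pathologist = AnnotationSet(provenance="pathologist")
    masks = {"cell_rich": cell, "colloid": colloid, "tissue": tissue}
    return HEScene(image, masks, core_id, training, pathologist, px)


def _sample_training_annotations(cell, colloid, other, px, rng,
                                 n_per_class, box_um) -> AnnotationSet:
    """Small square annotations fully inside each class's ground truth."""
    from scipy.ndimage import uniform_filter

    half_px = box_um / 2.0 / px
    k = max(3, int(2 * half_px) + 1)
    out = AnnotationSet(provenance="training")

    def sample(mask, label, n):
        interior = uniform_filter(mask.astype(np.float32), size=k, mode="constant") > 0.999
        rows, cols = np.nonzero(interior)
        if rows.size == 0:
            raise ValueError(f"no room for {label} training annotations")
        pick = rng.choice(rows.size, size=min(n, rows.size), replace=False)
        for p in pick:
            cx, cy = float(cols[p]), float(rows[p])
            out.add(box(cx - half_px, cy - half_px, cx + half_px, cy + half_px), label)

    sample(cell, "cell_rich", n_per_class)
    sample(colloid, "non_cell_rich", n_per_class // 2)
    sample(other, "non_cell_rich", n_per_class - n_per_class // 2)
    return out


def _pathologist_annotations(phantom: FixturePhantom) -> AnnotationSet:
    """Coarse per-core diagnosis polygons engulfing the colloid lumens.

    Mimics manual subcore annotation: the union of follicle outer circles
    is morphologically closed and smoothed, so lumens end up inside the
    annotated region even though they are not cell-rich.
    """
    px = phantom.image_px_size_um
    out = AnnotationSet(provenance="pathologist")
    for core in phantom.cores:
        cx, cy = core.center_um
        circles = [Point(cx + f.center_um[0], cy + f.center_um[1]).buffer(f.outer_radius_um, 32)
                   for f in core.follicles]
        if not circles:
            continue
        blob = unary_union(circles).buffer(14.0, 16).buffer(-8.0, 16)
        blob = blob.intersection(Point(cx, cy).buffer(core.radius_um, 64)).simplify(1.0)
        from shapely import affinity
        blob_px = affinity.scale(blob, xfact=1 / px, yfact=1 / px, origin=(0, 0))
        out.add(blob_px, core.diagnosis_label)
    return out


# ------------------------------------------------------------- MSI rendering

def spot_fractions(phantom: FixturePhantom, scene: HEScene):
    """Per-MSI-spot tissue / cell-rich / colloid area fractions.

    Every image pixel center is mapped through the planted affine into the
    MSI frame and binned into its 20 μm grid cell; fractions are pixel
    counts over the nominal pixels-per-cell.  Returns (coords, fractions
    dict, core assignment) for spots overlapping tissue.
    """
    t = phantom.planted_transform
    h, w = scene.masks["tissue"].shape
    ys, xs = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(np.float64)
    um = pts @ t.linear.T + t.translation
    pitch = phantom.msi_pitch_um
    ix = np.floor(um[:, 0] / pitch).astype(np.int64)
    iy = np.floor(um[:, 1] / pitch).astype(np.int64)

    tissue = scene.masks["tissue"].ravel()
    if not tissue.any():
        raise ValueError(
            "no MSI spots overlap tissue: the image/MSI registration or the "
            "tissue footprint leaves nothing under the spot grid")
    x0, x1 = ix[tissue].min(), ix[tissue].max()
    y0, y1 = iy[tissue].min(), iy[tissue].max()
    nx, ny = int(x1 - x0 + 1), int(y1 - y0 + 1)
    key = (ix - x0) * ny + (iy - y0)
    inside = (ix >= x0) & (ix <= x1) & (iy >= y0) & (iy <= y1)

    def bincount(mask):
        return np.bincount(key[inside & mask], minlength=nx * ny).astype(np.float64)

    # denominator: pixels actually mapping into each cell (the pixel grid
    # does not divide the 20 um cell evenly, so the count varies per cell)
    total = np.bincount(key[inside], minlength=nx * ny).astype(np.float64)
    counts = {name: bincount(scene.masks[name].ravel()) for name in
              ("tissue", "cell_rich", "colloid")}
    keep = counts["tissue"] > 0
    if not keep.any():
        raise ValueError(
            "no MSI spots overlap tissue: the planted transform places the "
            "grid outside the tissue footprint")
    flat = np.nonzero(keep)[0]
    coords = np.column_stack([flat // ny + x0, flat % ny + y0]).astype(int)
    fracs = {name: counts[name][flat] / total[flat] for name in counts}

    core_ids = scene.core_id_map.ravel()
    n_cores = len(phantom.cores)
    per_core = np.zeros((nx * ny, n_cores))
    for ci in range(n_cores):
        per_core[:, ci] = np.bincount(key[inside & (core_ids == ci)], minlength=nx * ny)
    core_of_spot = per_core[flat].argmax(axis=1)
    return coords, fracs, core_of_spot


def render_msi_cube(phantom: FixturePhantom, model: SpectrumModel,
                    scene: HEScene | None = None):
    """Synthesize the spectral cube on the MSI grid.

    Returns (MSIDataset, ground_truth) where ground_truth maps each spot to
    its planted area fractions, core index and diagnosis label.
    """
    scene = scene or render_he_image(phantom)
    mz = phantom.mz_axis()
    lo, hi = phantom.mz_range
    for pm in model.all_peak_mzs():
        if not (lo <= pm <= hi):
            raise ValueError(f"planted peak m/z {pm} outside mz_range {phantom.mz_range}")

    coords, fracs, core_of_spot = spot_fractions(phantom, scene)
    n = coords.shape[0]
    diag = np.array([phantom.cores[c].diagnosis_label for c in core_of_spot])

    intens = np.full((n, mz.size), model.baseline_level, dtype=np.float64)

    def add_peak(center_mz, amp_vec):
        s = model.peak_sigma_da
        a = np.searchsorted(mz, center_mz - 6 * s)
        b = np.searchsorted(mz, center_mz + 6 * s, side="right")
        if b <= a:
            return
        profile = np.exp(-0.5 * ((mz[a:b] - center_mz) / s) ** 2)
        intens[:, a:b] += np.outer(amp_vec, profile)

    cellf, colf, tisf = fracs["cell_rich"], fracs["colloid"], fracs["tissue"]
    for label, peaks in model.peptide_peaks.items():
        sel = (diag == label).astype(float)
        for pm, amp in peaks:
            add_peak(pm, amp * cellf * sel)
    for pm, amp in model.shared_peptide_peaks:
        add_peak(pm, amp * cellf)
    for pm, amp in model.reference_peaks:
        add_peak(pm, amp * tisf)
    for pm, base, enrich in model.interferent_peaks:
        add_peak(pm, base * (1.0 + enrich * colf))
    for pm, amp in model.trypsin_peaks:
        add_peak(pm, np.full(n, amp))

    if model.noise_sd > 0:
        rng = np.random.default_rng([phantom.seed, 1])
        intens += rng.normal(0.0, model.noise_sd, size=intens.shape)
        np.clip(intens, 0.0, None, out=intens)

    ds = MSIDataset(coords, mz, intens, pitch_um=phantom.msi_pitch_um)
    ground_truth = {
        "cell_fraction": cellf, "colloid_fraction": colf, "tissue_fraction": tisf,
        "core_index": core_of_spot, "diagnosis": diag,
        "transform": phantom.planted_transform,
    }
    return ds, ground_truth


# ------------------------------------------------------------ default fixture

def default_spectrum_model() -> SpectrumModel:
    """The study-condition spectral model for the default fixture.

    One discriminative tryptic-peptide peak per diagnosis, two shared
    cell-rich peptides, the collagen-derived registration reference at
    m/z 1459.688, the HCCA-adduct interferent panel (colloid-enriched)
    and the trypsin autolysis triplet.  Amplitudes are kept a modest
    multiple of the baseline so that peaks contribute little to a
    spectrum's total RMS, as in real profile-mode acquisitions.
    """
    return SpectrumModel(
        peptide_peaks={
            "PTC": [(1104.54, 40.0)],
            "FVPTC": [(1296.68, 40.0)],
            "NIFTP": [(1379.74, 40.0)],
            "FA": [(1521.80, 40.0)],
        },
        shared_peptide_peaks=[(945.45, 22.0), (1198.70, 30.0)],
        reference_peaks=[(1459.688, 35.0)],
    )


def _base_follicle_layout(core_radius_um: float = 120.0) -> list[Follicle]:
    """A fixed, densely packed follicle layout shared by all default cores.

    Thyroid cores are predominantly follicular, so follicles sit on a
    jittered hexagonal lattice covering most of the core.  Sharing one
    layout (rotated per core) equalizes colloid and cell-rich area
    fractions across diagnoses, so interferent load is not confounded
    with class.
    """
    rng = np.random.default_rng(20240917)
    placed: list[Follicle] = []
    # central macrofollicle: a large colloid lake, so the core contains
    # spots lying fully in colloid
    jx, jy = rng.uniform(-2.0, 2.0, size=2)
    placed.append(Follicle((float(jx), float(jy)), 45.0, 12.0))
    # ring of regular follicles around it
    n_ring, ring_r = 7, 95.0
    for k in range(n_ring):
        theta = 2 * np.pi * k / n_ring + float(rng.uniform(-0.04, 0.04))
        lumen = float(rng.uniform(16.0, 22.0))
        rim = float(rng.uniform(9.0, 13.0))
        cx = ring_r * np.cos(theta)
        cy = ring_r * np.sin(theta)
        if np.hypot(cx, cy) <= core_radius_um - (lumen + rim) - 2.0:
            placed.append(Follicle((float(cx), float(cy)), lumen, rim))
    return placed


def default_phantom(seed: int = 0) -> FixturePhantom:
    """2×2 TMA phantom, one core per diagnosis, desk-scale m/z range.

    The m/z window [700, 1600] covers every planted signal (peptides,
    interferent panel, trypsin triplet and the m/z 1459.688 reference)
    while keeping the cube small enough for fast tests.
    """
    radius = 150.0
    layout = _base_follicle_layout(radius)
    model = default_spectrum_model()
    centers = [(200.0, 200.0), (560.0, 200.0), (200.0, 560.0), (560.0, 560.0)]
    labels = ["PTC", "FVPTC", "NIFTP", "FA"]
    cores = []
    for i, (center, label) in enumerate(zip(centers, labels)):
        ang = i * np.pi / 2
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        follicles = [Follicle(tuple(rot @ np.array(f.center_um)),
                              f.lumen_radius_um, f.rim_thickness_um)
                     for f in layout]
        cores.append(CorePhantom(center, radius, label, follicles,
                                 class_signature=list(model.peptide_peaks[label])))
    return FixturePhantom(cores=cores, mz_range=(700.0, 1600.0), seed=seed)


# ------------------------------------------------- peak-picking benchmark

def peak_picking_benchmark(n_spectra: int = 200, seed: int = 0,
                           mz_lo: float = 700.0, mz_hi: float = 1100.0,
                           step_da: float = 0.05, sigma_da: float = 0.08,
                           baseline: float = 5.0, noise_sd: float = 1.0,
                           n_strong: int = 6, snr_range=(10.0, 30.0),
                           weak_snr: float = 3.0, weak_every: int = 4):
    """Synthetic spectra with peaks planted at known S/N for picker scoring.

    Each spectrum carries ``n_strong`` Gaussian peaks with amplitude
    ``snr * noise_sd`` (S/N drawn uniformly from ``snr_range``) at random
    positions at least 5 Da apart; every ``weak_every``-th spectrum also
    carries one sub-threshold peak at S/N ``weak_snr``.  Yields tuples
    ``(mz, intensity, strong_mzs, weak_mzs)``.
    """
    rng = np.random.default_rng(seed)
    mz = np.arange(mz_lo, mz_hi + step_da / 2, step_da)
    for i in range(n_spectra):
        n_weak = 1 if (i % weak_every == 0) else 0
        positions = []
        while len(positions) < n_strong + n_weak:
            cand = float(rng.uniform(mz_lo + 10, mz_hi - 10))
            if all(abs(cand - p) > 5.0 for p in positions):
                positions.append(cand)
        strong = positions[:n_strong]
        weak = positions[n_strong:]
        y = np.full(mz.size, baseline)
        for p in strong:
            amp = float(rng.uniform(*snr_range)) * noise_sd
            y += amp * np.exp(-0.5 * ((mz - p) / sigma_da) ** 2)
        for p in weak:
            y += weak_snr * noise_sd * np.exp(-0.5 * ((mz - p) / sigma_da) ** 2)
        y += rng.normal(0.0, noise_sd, mz.size)
        yield mz, y, np.array(strong), np.array(weak)


def score_peak_benchmark(n_spectra: int = 200, seed: int = 0,
                         snr_min: float = 6.0, rel_int_min: float = 0.003,
                         match_tol_da: float = 0.1, **kwargs) -> dict:
    """Run the picker over the benchmark and score it against the plants.

    Returns sensitivity (strong peaks recovered), false-discovery rate
    (reported peaks matching no plant), and the number of sub-threshold
    plants that were (wrongly) reported.
    """
    from .spectra import pick_peaks

    n_strong_total = n_found = n_reported = n_false = n_weak_reported = 0
    for mz, y, strong, weak in peak_picking_benchmark(n_spectra, seed, **kwargs):
        pl = pick_peaks(mz, y, snr_min=snr_min, rel_int_min=rel_int_min)
        n_strong_total += strong.size
        n_reported += len(pl)
        for p in strong:
            if len(pl) and np.abs(pl.mz - p).min() <= match_tol_da:
                n_found += 1
        for p in weak:
            if len(pl) and np.abs(pl.mz - p).min() <= match_tol_da:
                n_weak_reported += 1
        planted = np.concatenate([strong, weak])
        for reported in pl.mz:
            if np.abs(planted - reported).min() > 1.5 * match_tol_da:
                n_false += 1
    return {
        "sensitivity": n_found / n_strong_total,
        "fdr": n_false / n_reported if n_reported else 0.0,
        "weak_reported": n_weak_reported,
        "n_reported": n_reported,
        "n_planted_strong": n_strong_total,
    }


# --------------------------------------------------------------- file export

def write_fixture(phantom: FixturePhantom, model: SpectrumModel, outdir: str | Path):
    """Write the fixture to disk: PNG + GeoJSON + imzML + manifest JSON."""
    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scene = render_he_image(phantom)
    ds, gt = render_msi_cube(phantom, model, scene)

    Image.fromarray(scene.image).save(outdir / "he_image.png")
    for name, mask in scene.masks.items():
        Image.fromarray(mask.astype(np.uint8) * 255).save(outdir / f"mask_{name}.png")
    scene.training.to_geojson(outdir / "annotations_training.geojson")
    scene.pathologist.to_geojson(outdir / "annotations_pathologist.geojson")
    write_imzml(ds, outdir / "msi_cube.imzML")

    import pandas as pd
    pd.DataFrame({
        "spot_x": ds.coordinates[:, 0], "spot_y": ds.coordinates[:, 1],
        "tissue_fraction": gt["tissue_fraction"],
        "cell_fraction": gt["cell_fraction"],
        "colloid_fraction": gt["colloid_fraction"],
        "core_index": gt["core_index"], "diagnosis": gt["diagnosis"],
    }).to_csv(outdir / "ground_truth_spots.csv", index=False)
    manifest = {
        "seed": phantom.seed,
        "image_px_size_um": phantom.image_px_size_um,
        "msi_pitch_um": phantom.msi_pitch_um,
        "mz_range": list(phantom.mz_range),
        "planted_transform": json.loads(phantom.planted_transform.to_json()),
        "cores": [{"center_um": list(c.center_um), "radius_um": c.radius_um,
                   "diagnosis": c.diagnosis_label,
                   "class_signature": [list(p) for p in c.class_signature]}
                  for c in phantom.cores],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return scene, ds, gt
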