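"""TMA dearraying, diagnosis label transfer, and ROI rasterization.

Three labeled region-of-interest types are built per TMA core, mirroring
standard MSI practice:

* **FC** (full core) — every measured MSI spot inside the core circle,
  labeled with the core-level diagnosis;
* **PAT** — spots whose centers fall inside the pathologist's subcore
  annotation polygons, labeled per polygon;
* **PC** — pixel-classifier detections, labeled by overlap with the
  pathologist annotations, slightly buffered and tiled onto the 20 μm MSI
  grid.

Spot membership uses the center-in-polygon rule throughout; all geometry
is done in micrometers in the MSI frame, reached from image pixels through
the registration affine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely import affinity
from shapely.geometry import Point, box
from shapely.ops import unary_union

from .annotations import AnnotationSet
from .classifier import Detection, DetectionSet
from .features import rgb_to_od
from .registration import AffineTransform2D
from .spectra import MSIDataset

ROW_LABELS = "ABCDEFGHJKLMNPQRSTUVWXYZ"


@dataclass
class TMACore:
    row_label: str
    col_label: str
    center_px: tuple[float, float]
    radius_px: float
    valid: bool = True


@dataclass
class TMAGrid:
    cores: list[TMACore] = field(default_factory=list)
    grid_matches_expected: bool = True

    def __len__(self):
        return len(self.cores)

    def valid_cores(self) -> list[TMACore]:
        return [c for c in self.cores if c.valid]


@dataclass
class ROISet:
    """Diagnosis-labeled MSI spot sets for one ROI type (FC | PAT | PC)."""

    roi_type: str
    entries: dict[str, set[tuple[int, int]]] = field(default_factory=dict)
    provenance: dict[tuple[int, int], str] = field(default_factory=dict)

    def __post_init__(self):
        if self.roi_type not in ("FC", "PAT", "PC"):
            raise ValueError(f"roi_type must be FC, PAT or PC, got {self.roi_type!r}")
        self._check_disjoint()

    def _check_disjoint(self):
        seen: set[tuple[int, int]] = set()
        for label, spots in self.entries.items():
            overlap = seen & spots
            if overlap:
                raise ValueError(f"spot sets overlap across labels (e.g. {next(iter(overlap))})")
            seen |= spots

    def all_spots(self) -> set[tuple[int, int]]:
        out: set[tuple[int, int]] = set()
        for spots in self.entries.values():
            out |= spots
        return out

    def n_spots(self) -> int:
        return sum(len(s) for s in self.entries.values())

    def to_dataframe(self):
        import pandas as pd
        rows = [(x, y, self.roi_type, label, self.provenance.get((x, y), ""))
                for label, spots in sorted(self.entries.items())
                for x, y in sorted(spots)]
        return pd.DataFrame(rows, columns=["spot_x", "spot_y", "roi_type", "label", "core"])


# -------------------------------------------------------------------- dearray

def dearray(he_image: np.ndarray, px_size_um: float,
            expected_rows: int, expected_cols: int,
            od_threshold: float = 0.04, min_core_area_um2: float = 5000.0,
            center_overrides: dict[str, tuple[float, float]] | None = None) -> TMAGrid:
    """Locate TMA cores on the H&E image and assign row/column labels.

    Tissue is segmented by thresholding the mean optical density; large
    connected components are candidate cores; row/column structure comes
    from 1-D clustering of the component centers.  Labels run row-major
    ("A1", "A2", ..., "B1", ...).  ``center_overrides`` maps a core label
    to a replacement (x, y) pixel center, applied verbatim.
    """
    from scipy.ndimage import binary_closing
    from skimage import measure

    od = rgb_to_od(he_image).mean(axis=2)
    tissue = od > od_threshold
    if not tissue.any():
        raise ValueError("no tissue found on the image; cannot dearray")
    tissue = binary_closing(tissue, structure=np.ones((5, 5)))
    labeled = measure.label(tissue, connectivity=2)
    min_px = min_core_area_um2 / px_size_um**2
    regions = [r for r in measure.regionprops(labeled) if r.area >= min_px]
    if not regions:
        raise ValueError("no tissue components large enough to be TMA cores")

    centers = np.array([(r.centroid[1], r.centroid[0]) for r in regions])  # (x, y)
    radii = np.sqrt(np.array([r.area for r in regions]) / np.pi)

    col_of = _cluster_1d(centers[:, 0], expected_cols)
    row_of = _cluster_1d(centers[:, 1], expected_rows)
    matches = (len(set(col_of)) == expected_cols and len(set(row_of)) == expected_rows
               and len(regions) == expected_rows * expected_cols)
    if not matches:
        warnings.warn(
            f"detected grid ({len(set(row_of))}x{len(set(col_of))}, {len(regions)} cores) "
            f"differs from expected {expected_rows}x{expected_cols}; best-effort assignment")

    cores = []
    for i, region in enumerate(regions):
        label_r = ROW_LABELS[row_of[i]]
        label_c = str(col_of[i] + 1)
        cx, cy = centers[i]
        if center_overrides and f"{label_r}{label_c}" in center_overrides:
            cx, cy = center_overrides[f"{label_r}{label_c}"]
        cores.append(TMACore(label_r, label_c, (float(cx), float(cy)), float(radii[i])))
    cores.sort(key=lambda c: (c.row_label, int(c.col_label)))
    return TMAGrid(cores, grid_matches_expected=matches)


def _cluster_1d(values: np.ndarray, k: int) -> list[int]:
    """Assign each value to one of k clusters by splitting at the largest gaps."""
    order = np.argsort(values)
    k = min(k, values.size)
    if k <= 1:
        return [0] * values.size
    gaps = np.diff(values[order])
    split_after = np.sort(np.argsort(gaps)[-(k - 1):])
    assign = np.zeros(values.size, dtype=int)
    group = 0
    for pos, idx in enumerate(order):
        assign[idx] = group
        if pos in split_after:
            group += 1
    return assign.tolist()


def mark_valid(grid: TMAGrid, transform: AffineTransform2D, msi: MSIDataset) -> TMAGrid:
    """A core is valid iff at least one measured MSI spot maps inside it."""
    centers = msi.spot_centers_um()
    for core in grid.cores:
        c_um = transform.apply(np.array(core.center_px))
        r_um = core.radius_px * _scale_of(transform)
        d2 = np.sum((centers - c_um) ** 2, axis=1)
        core.valid = bool(np.any(d2 <= r_um**2))
    return grid


def _scale_of(t: AffineTransform2D) -> float:
    return float(np.sqrt(abs(np.linalg.det(t.linear))))


# ------------------------------------------------------------- label transfer

def transfer_labels(detections: DetectionSet, pat: AnnotationSet,
                    min_area_px2: float = 1e-6) -> DetectionSet:
    """Assign pathologist labels to detections, splitting across boundaries.

    Each detection polygon is intersected with the pathologist annotations
    in lexicographic label order; every resulting piece carries the label
    of the annotation it falls in (so a detection straddling two
    annotations is split along the boundary).  Area already claimed by an
    earlier label is not claimed again, which makes exact ties resolve to
    the lexicographically smallest label.  Detections outside every
    annotation are dropped.
    """
    if len(pat) == 0:
        warnings.warn("empty pathologist annotation set: all detections dropped")
        return DetectionSet([], detections.px_size_um)

    by_label: dict[str, list] = {}
    for ann in pat:
        by_label.setdefault(ann.label, []).append(ann.geometry)
    merged = {label: unary_union(geoms) for label, geoms in by_label.items()}

    out: list[Detection] = []
    for det in detections:
        claimed = None
        for label in sorted(merged):
            region = merged[label] if claimed is None else merged[label].difference(claimed)
            piece = det.geometry.intersection(region)
            if piece.is_empty or piece.area <= min_area_px2:
                continue
            claimed = region if claimed is None else claimed.union(merged[label])
            for geom in getattr(piece, "geoms", [piece]):
                if geom.geom_type == "Polygon" and geom.area > min_area_px2:
                    out.append(Detection(geom, det.class_name,
                                         geom.area * detections.px_size_um**2,
                                         label=label))
    return DetectionSet(out, detections.px_size_um)


# ----------------------------------------------------------------- MSI tiling

def _spots_in_polygon(geom, pitch: float) -> set[tuple[int, int]]:
    """Grid spots whose centers lie inside ``geom`` (μm frame)."""
    minx, miny, maxx, maxy = geom.bounds
    i0, i1 = int(np.floor(minx / pitch)), int(np.ceil(maxx / pitch))
    j0, j1 = int(np.floor(miny / pitch)), int(np.ceil(maxy / pitch))
    ii, jj = np.meshgrid(np.arange(i0, i1 + 1), np.arange(j0, j1 + 1), indexing="ij")
    cx = (ii + 0.5) * pitch
    cy = (jj + 0.5) * pitch
    inside = shapely.contains_xy(geom, cx.ravel(), cy.ravel())
    return set(zip(ii.ravel()[inside].tolist(), jj.ravel()[inside].tolist()))


def tile_to_msi(labeled: DetectionSet, transform: AffineTransform2D,
                pitch_um: float = 20.0, buffer_um: float = 4.0,
                msi: MSIDataset | None = None) -> ROISet:
    """Tile labeled detections onto the MSI grid (PC ROI type).

    Each detection polygon is mapped into the MSI μm frame, buffered
    outward by ``buffer_um`` (recovering rim spots lost to the resolution
    gap), and converted to the set of spots whose centers it contains.
    Labels are processed in lexicographic order and a spot claimed by an
    earlier label is not reassigned, keeping label sets disjoint.  When
    ``msi`` is given, spots absent from the measured dataset are dropped.
    """
    if abs(np.linalg.det(transform.linear)) < 1e-15:
        raise ValueError("degenerate image->MSI transform")
    params = transform.shapely_params()
    measured = msi.spot_set() if msi is not None else None

    per_label: dict[str, set[tuple[int, int]]] = {}
    for det in labeled:
        label = det.label or det.class_name
        geom_um = affinity.affine_transform(det.geometry, params)
        if buffer_um > 0:
            geom_um = geom_um.buffer(buffer_um)
        per_label.setdefault(label, set()).update(_spots_in_polygon(geom_um, pitch_um))

    claimed: set[tuple[int, int]] = set()
    entries: dict[str, set[tuple[int, int]]] = {}
    for label in sorted(per_label):
        spots = per_label[label] - claimed
        if measured is not None:
            spots &= measured
        if spots:
            entries[label] = spots
            claimed |= spots
    return ROISet("PC", entries)


def tiles_as_polygons(roiset: ROISet, pitch_um: float = 20.0) -> AnnotationSet:
    """Merged axis-aligned 20 μm tile polygons per label, for export.

    Replacing the high-vertex-count detection outlines with merged grid
    squares drastically reduces vertices, which is what downstream MSI
    software needs for efficient ROI import.
    """
    out = AnnotationSet(provenance="detection")
    for label, spots in sorted(roiset.entries.items()):
        squares = [box(i * pitch_um, j * pitch_um, (i + 1) * pitch_um, (j + 1) * pitch_um)
                   for i, j in sorted(spots)]
        out.add(unary_union(squares).simplify(0.0), label)
    return out


# ------------------------------------------------------------- ROI assembly

def core_diagnosis_labels(grid: TMAGrid, pat: AnnotationSet,
                          transform: AffineTransform2D) -> dict[str, str]:
    """Core-level diagnosis = pathologist label with maximal overlap."""
    labels = {}
    for core in grid.cores:
        circle = Point(core.center_px).buffer(core.radius_px, 64)
        best, best_area = None, 0.0
        for label in sorted({a.label for a in pat}):
            area = sum(circle.intersection(a.geometry).area
                       for a in pat.by_label(label))
            if area > best_area:
                best, best_area = label, area
        if best is not None:
            labels[f"{core.row_label}{core.col_label}"] = best
    return labels


def build_roi_types(grid: TMAGrid, pat: AnnotationSet, labeled: DetectionSet,
                    transform: AffineTransform2D, msi: MSIDataset,
                    buffer_um: float = 4.0,
                    core_labels: dict[str, str] | None = None) -> dict[str, ROISet]:
    """Build the FC, PAT and PC spot sets restricted to measured spots."""
    mark_valid(grid, transform, msi)
    valid = grid.valid_cores()
    if not valid:
        raise ValueError("no valid cores: no MSI spots map inside any core")
    pitch = msi.pitch_um
    measured = msi.spot_set()
    centers = msi.spot_centers_um()
    if core_labels is None:
        core_labels = core_diagnosis_labels(grid, pat, transform)

    # FC: measured spots inside each valid core circle
    fc_entries: dict[str, set] = {}
    fc_prov: dict[tuple[int, int], str] = {}
    for core in valid:
        cid = f"{core.row_label}{core.col_label}"
        label = core_labels.get(cid)
        if label is None:
            warnings.warn(f"core {cid} has no diagnosis label; skipped in FC")
            continue
        c_um = transform.apply(np.array(core.center_px))
        r_um = core.radius_px * _scale_of(transform)
        d2 = np.sum((centers - c_um) ** 2, axis=1)
        spots = set(map(tuple, msi.coordinates[d2 <= r_um**2].tolist()))
        spots -= set().union(*fc_entries.values()) if fc_entries else set()
        fc_entries.setdefault(label, set()).update(spots)
        for s in spots:
            fc_prov[s] = cid
    fc = ROISet("FC", fc_entries, fc_prov)

    # PAT: spot centers inside pathologist polygons (mapped px -> μm)
    params = transform.shapely_params()
    pat_entries: dict[str, set] = {}
    claimed: set[tuple[int, int]] = set()
    for label in sorted({a.label for a in pat}):
        geom_um = unary_union([affinity.affine_transform(a.geometry, params)
                               for a in pat.by_label(label)])
        spots = (_spots_in_polygon(geom_um, pitch) & measured) - claimed
        if spots:
            pat_entries[label] = spots
            claimed |= spots
    pat_roi = ROISet("PAT", pat_entries,
                     {s: fc_prov.get(s, "") for s in claimed})

    # PC: tiled detections, kept within the full-core footprint
    pc = tile_to_msi(labeled, transform, pitch, buffer_um, msi)
    fc_spots = fc.all_spots()
    pc.entries = {label: spots & fc_spots
                  for label, spots in pc.entries.items() if spots & fc_spots}
    pc.provenance = {s: fc_prov.get(s, "") for s in pc.all_spots()}
    return {"FC": fc, "PAT": pat_roi, "PC": pc}
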