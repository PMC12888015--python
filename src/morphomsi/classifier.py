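"""The 32-parameter pixel classifier and its detection post-processing.

The classifier is deliberately tiny: a single linear layer mapping the 16
standardized multiscale features to 2 classes through a softmax — 16 × 2 =
32 parameters with the bias disabled (a biased or hidden-layer variant is
available through the constructor but is not the default).  It is trained
by full-batch gradient descent on the pixels under a handful of manual
annotations per class, which is enough because the features already
linearly separate textured hematoxylin-rich tissue from smooth material.

The probability map is binarized at 0.5 and cleaned morphologically:
8-connected objects smaller than ``min_object_um2`` (default 7 μm²) are
removed and 4-connected holes smaller than ``min_hole_um2`` (default
7 μm²) are filled, after which the surviving components are vectorized to
polygons (holes preserved).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon
from skimage import measure, morphology

from .annotations import AnnotationSet
from .features import FeatureConfig, FeatureStack

DEFAULT_CLASS_ORDER = ("cell_rich", "non_cell_rich")


@dataclass
class PixelClassifierModel:
    weights: np.ndarray                  # (F, C)
    bias: np.ndarray | None              # (C,) or None
    class_order: tuple[str, ...]
    feature_names: list[str]
    feature_mean: np.ndarray             # (F,)
    feature_sd: np.ndarray               # (F,)
    train_accuracy: float = float("nan")

    @property
    def n_parameters(self) -> int:
        n = int(np.prod(self.weights.shape))
        if self.bias is not None:
            n += self.bias.size
        return n

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "weights": self.weights.tolist(),
            "bias": None if self.bias is None else self.bias.tolist(),
            "class_order": list(self.class_order),
            "feature_names": self.feature_names,
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "train_accuracy": self.train_accuracy,
        }
        text = json.dumps(d)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PixelClassifierModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(np.array(d["weights"]),
                   None if d["bias"] is None else np.array(d["bias"]),
                   tuple(d["class_order"]), list(d["feature_names"]),
                   np.array(d["feature_mean"]), np.array(d["feature_sd"]),
                   d.get("train_accuracy", float("nan")))


@dataclass
class Detection:
    geometry: Polygon
    class_name: str
    area_um2: float
    label: str | None = None


@dataclass
class DetectionSet:
    detections: list[Detection] = field(default_factory=list)
    px_size_um: float = 0.44

    def __len__(self):
        return len(self.detections)

    def __iter__(self):
        return iter(self.detections)

    def to_annotation_set(self, use_label: bool = False) -> AnnotationSet:
        out = AnnotationSet(provenance="detection")
        for d in self.detections:
            out.add(d.geometry, d.label if (use_label and d.label) else d.class_name)
        return out

    def to_geojson(self, path=None) -> dict:
        return self.to_annotation_set(use_label=True).to_geojson(path)


# ------------------------------------------------------------------ training

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _annotation_pixels(features: FeatureStack, annotations: AnnotationSet,
                       class_order) -> tuple[np.ndarray, np.ndarray]:
    """Collect (X, y) for pixels under the annotation polygons."""
    from skimage.draw import polygon as draw_polygon

    h, w = features.data.shape[:2]
    xs, ys, labels = [], [], []
    for ann in annotations:
        if ann.label not in class_order:
            raise ValueError(f"annotation label {ann.label!r} not in classes {class_order}")
        geoms = getattr(ann.geometry, "geoms", [ann.geometry])
        for geom in geoms:
            col, row = np.asarray(geom.exterior.coords).T
            rr, cc = draw_polygon(row, col, shape=(h, w))
            if rr.size == 0:
                continue
            xs.append(rr)
            ys.append(cc)
            labels.append(np.full(rr.size, class_order.index(ann.label)))
    if not xs:
        raise ValueError("annotations do not intersect the image")
    rr = np.concatenate(xs)
    cc = np.concatenate(ys)
    y = np.concatenate(labels)
    X = features.data[rr, cc].astype(np.float64)
    return X, y


def train(features: FeatureStack, annotations: AnnotationSet,
          learning_rate: float = 0.5, epochs: int = 500, seed: int = 0,
          class_order=DEFAULT_CLASS_ORDER, use_bias: bool = False,
          max_pixels_per_class: int = 20000) -> PixelClassifierModel:
    """Train the linear-softmax pixel classifier on annotated pixels.

    Training is deterministic given ``seed``: pixels are subsampled with a
    seeded generator and weights start at zero (the loss is convex, so no
    random initialization is needed).
    """
    X, y = _annotation_pixels(features, annotations, tuple(class_order))
    present = np.unique(y)
    if present.size < 2:
        raise ValueError("annotations must cover at least two classes")

    rng = np.random.default_rng(seed)
    keep = []
    for c in present:
        idx = np.nonzero(y == c)[0]
        if idx.size > max_pixels_per_class:
            idx = rng.choice(idx, size=max_pixels_per_class, replace=False)
        keep.append(idx)
    keep = np.concatenate(keep)
    X, y = X[keep], y[keep]

    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    Xs = (X - mean) / sd

    n, f = Xs.shape
    c = len(class_order)
    W = np.zeros((f, c))
    b = np.zeros(c) if use_bias else None
    onehot = np.eye(c)[y]
    for _ in range(epochs):
        z = Xs @ W + (b if b is not None else 0.0)
        p = _softmax(z)
        grad = Xs.T @ (p - onehot) / n
        W -= learning_rate * grad
        if b is not None:
            b -= learning_rate * (p - onehot).mean(axis=0)

    pred = (Xs @ W + (b if b is not None else 0.0)).argmax(axis=1)
    acc = float((pred == y).mean())
    if acc < 0.6:
        warnings.warn(f"pixel classifier is near-degenerate (train accuracy {acc:.2f}); "
                      "the annotated classes may be inseparable")
    return PixelClassifierModel(W, b, tuple(class_order), list(features.feature_names),
                                mean, sd, train_accuracy=acc)


def predict_map(model: PixelClassifierModel, features: FeatureStack) -> np.ndarray:
    """Per-pixel class probabilities, shape H × W × C (sums to 1)."""
    if list(features.feature_names) != list(model.feature_names):
        raise ValueError(
            "feature configuration mismatch: model expects "
            f"{model.feature_names}, got {features.feature_names}")
    h, w = features.data.shape[:2]
    Xs = (features.flat().astype(np.float64) - model.feature_mean) / model.feature_sd
    z = Xs @ model.weights
    if model.bias is not None:
        z += model.bias
    return _softmax(z).reshape(h, w, len(model.class_order))


# ------------------------------------------------------------ postprocessing

def _px_threshold(area_um2: float, px_size_um: float) -> int:
    """Smallest pixel count whose area reaches ``area_um2``."""
    return int(np.ceil(area_um2 / px_size_um**2))


def clean_mask(mask: np.ndarray, px_size_um: float,
               min_object_um2: float = 7.0, min_hole_um2: float = 7.0) -> np.ndarray:
    """Remove sub-threshold 8-connected objects and fill 4-connected holes."""
    # max_size removes components <= value; the rule is "area < threshold"
    out = morphology.remove_small_objects(
        mask.astype(bool), max_size=_px_threshold(min_object_um2, px_size_um) - 1,
        connectivity=2)
    out = morphology.remove_small_holes(
        out, max_size=_px_threshold(min_hole_um2, px_size_um) - 1, connectivity=1)
    return out


def vectorize_mask(mask: np.ndarray, px_size_um: float,
                   class_name: str = "cell_rich") -> DetectionSet:
    """Trace each connected component into a polygon (holes preserved)."""
    dets: list[Detection] = []
    labeled = measure.label(mask, connectivity=2)
    for region in measure.regionprops(labeled):
        r0, c0, r1, c1 = region.bbox
        sub = np.pad(labeled[r0:r1, c0:c1] == region.label, 1)
        contours = measure.find_contours(sub.astype(float), 0.5)
        if not contours:
            continue
        rings = []
        for cont in contours:
            # (row, col) -> (x, y); undo the 1 px pad
            xy = np.column_stack([cont[:, 1] - 1 + c0, cont[:, 0] - 1 + r0])
            poly = Polygon(xy)
            if poly.is_valid and poly.area > 0:
                rings.append(poly)
        if not rings:
            continue
        shell = max(rings, key=lambda p: p.area)
        holes = [r.exterior.coords for r in rings
                 if r is not shell and shell.contains(r.representative_point())]
        poly = Polygon(shell.exterior.coords, holes)
        if not poly.is_valid:
            poly = poly.buffer(0)
        dets.append(Detection(poly, class_name, float(region.area) * px_size_um**2))
    return DetectionSet(dets, px_size_um)


def postprocess(prob_map: np.ndarray, px_size_um: float,
                min_object_um2: float = 7.0, min_hole_um2: float = 7.0,
                threshold: float = 0.5, class_index: int = 0,
                class_name: str = "cell_rich") -> DetectionSet:
    """Binarize the probability map and emit cleaned detection polygons."""
    prob = prob_map[..., class_index] if prob_map.ndim == 3 else prob_map
    mask = clean_mask(prob >= threshold, px_size_um, min_object_um2, min_hole_um2)
    return vectorize_mask(mask, px_size_um, class_name)


def rasterize_detections(dets: DetectionSet, shape: tuple[int, int]) -> np.ndarray:
    """Paint detection polygons back onto a pixel grid (oracle helper)."""
    from skimage.draw import polygon as draw_polygon

    out = np.zeros(shape, dtype=bool)
    for det in dets:
        geoms = getattr(det.geometry, "geoms", [det.geometry])
        for geom in geoms:
            col, row = np.asarray(geom.exterior.coords).T
            rr, cc = draw_polygon(row, col, shape=shape)
            out[rr, cc] = True
            for interior in geom.interiors:
                col, row = np.asarray(interior.coords).T
                rr, cc = draw_polygon(row, col, shape=shape)
                out[rr, cc] = False
    return out
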