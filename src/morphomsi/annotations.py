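"""Labeled 2-D polygon annotations with GeoJSON (QuPath dialect) I/O.

Annotations are polygons in image pixel coordinates carrying a class label:
training annotations (cell_rich / non_cell_rich), pathologist diagnosis
annotations (PTC / FVPTC / NIFTP / FA / normal / stroma), or detections
emitted by the pixel classifier.  GeoJSON files use the QuPath convention
of a ``classification: {"name": ...}`` property per feature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

DIAGNOSIS_LABELS = ("PTC", "FVPTC", "NIFTP", "FA")
TISSUE_LABELS = DIAGNOSIS_LABELS + ("normal", "stroma")


@dataclass
class Annotation:
    geometry: BaseGeometry
    label: str


@dataclass
class AnnotationSet:
    """A collection of labeled polygons sharing one coordinate frame.

    ``provenance`` records where the set came from: "training",
    "pathologist", or "detection".
    """

    annotations: list[Annotation] = field(default_factory=list)
    provenance: str = "unknown"

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self):
        return iter(self.annotations)

    def labels(self) -> set[str]:
        return {a.label for a in self.annotations}

    def by_label(self, label: str) -> list[Annotation]:
        return [a for a in self.annotations if a.label == label]

    def add(self, geometry: BaseGeometry, label: str) -> None:
        self.annotations.append(Annotation(geometry, label))

    def to_geojson(self, path: str | Path | None = None) -> dict:
        features = []
        for ann in self.annotations:
            features.append({
                "type": "Feature",
                "geometry": mapping(ann.geometry),
                "properties": {
                    "objectType": "annotation",
                    "classification": {"name": ann.label},
                },
            })
        fc = {"type": "FeatureCollection", "features": features,
              "morphomsi:provenance": self.provenance}
        if path is not None:
            Path(path).write_text(json.dumps(fc))
        return fc

    @classmethod
    def from_geojson(cls, source: str | Path | dict,
                     provenance: str | None = None) -> "AnnotationSet":
        if isinstance(source, dict):
            fc = source
        else:
            fc = json.loads(Path(source).read_text())
        out = cls(provenance=provenance or fc.get("morphomsi:provenance", "unknown"))
        for feat in fc.get("features", []):
            props = feat.get("properties") or {}
            cls_prop = props.get("classification") or {}
            label = cls_prop.get("name") or props.get("name") or "unclassified"
            out.add(shape(feat["geometry"]), label)
        return out
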