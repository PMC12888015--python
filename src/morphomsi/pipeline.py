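"""End-to-end orchestration: fixture or real inputs through to ROC reports.

``run_all`` wires the stages together — simulate (optional) → features →
pixel-classifier train/predict → dearray → register → label transfer and
tiling → FC/PAT/PC ROI assembly → RMS normalization → mean spectra → peak
picking → interferent scoring, PCA and ROC — writing every intermediate
product plus a provenance manifest (config echo, input hashes, seed) into
the output directory.  The run is deterministic for a fixed seed and
config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifier, discriminate, features, fixtures, registration, rois, spectra
from .annotations import DIAGNOSIS_LABELS

log = logging.getLogger("morphomsi")


@dataclass
class RunConfig:
    """All stage parameters with the study's defaults, plus input paths.

    With ``simulate=True`` the synthetic fixture replaces the on-disk
    inputs; otherwise ``image_path``, ``imzml_path``, the annotation
    GeoJSONs and the control-point CSV must exist.
    """

    simulate: bool = True
    seed: int = 0
    image_path: str | None = None
    imzml_path: str | None = None
    training_annotations_path: str | None = None
    pathologist_annotations_path: str | None = None
    control_points_path: str | None = None
    panel_path: str | None = None

    image_px_size_um: float = 0.44
    msi_pitch_um: float = 20.0
    sigmas: tuple[float, ...] = (2.0, 4.0)
    min_object_um2: float = 7.0
    min_hole_um2: float = 7.0
    buffer_um: float = 4.0
    expected_rows: int = 2
    expected_cols: int = 2
    snr_min: float = 6.0
    rel_int_min: float = 0.003
    tol_ppm: float = 20.0
    ref_mz: float = 1459.688
    auc_hi: float = 0.7
    auc_lo: float = 0.3
    pca_components: int = 5
    refine_registration: bool = True
    epochs: int = 500
    learning_rate: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "sigmas" in data:
            data["sigmas"] = tuple(data["sigmas"])
        return cls(**data)

    def validate(self) -> None:
        if not self.simulate:
            for name in ("image_path", "imzml_path", "training_annotations_path",
                         "pathologist_annotations_path", "control_points_path"):
                value = getattr(self, name)
                if value is None:
                    raise ValueError(f"config field {name} is required when simulate=false")
                if not Path(value).exists():
                    raise ValueError(f"config field {name}: no such file {value}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline; returns the summary dict it also writes."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    stage_log: list[dict] = []

    def stage(name):
        log.info("stage %s", name)
        stage_log.append({"stage": name, "t": round(time.time() - t_start, 2)})

    try:
        # ------------------------------------------------ inputs / simulate
        stage("inputs")
        if config.simulate:
            phantom = fixtures.default_phantom(seed=config.seed)
            model_spec = fixtures.default_spectrum_model()
            scene = fixtures.render_he_image(phantom)
            ds_raw, ground_truth = fixtures.render_msi_cube(phantom, model_spec, scene)
            image = scene.image
            training = scene.training
            pathologist = scene.pathologist
            transform0 = phantom.planted_transform
            px_size = phantom.image_px_size_um
        else:
            from PIL import Image
            from .annotations import AnnotationSet
            image = np.asarray(Image.open(config.image_path).convert("RGB"))
            ds_raw = spectra.read_imzml(config.imzml_path, pitch_um=config.msi_pitch_um)
            training = AnnotationSet.from_geojson(config.training_annotations_path,
                                                  provenance="training")
            pathologist = AnnotationSet.from_geojson(config.pathologist_annotations_path,
                                                     provenance="pathologist")
            pts = pd.read_csv(config.control_points_path)
            transform0, rms = registration.fit_affine(
                pts[["img_x", "img_y"]].to_numpy(), pts[["msi_x_um", "msi_y_um"]].to_numpy())
            log.info("control-point fit RMS residual %.2f um", rms)
            ground_truth = None
            px_size = config.image_px_size_um

        # --------------------------------------------------------- features
        stage("features")
        feat_cfg = features.FeatureConfig(sigmas=tuple(config.sigmas))
        stack = features.compute_features(image, feat_cfg, px_size_um=px_size)

        # --------------------------------------------------- train / predict
        stage("pixel_classifier")
        model = classifier.train(stack, training, learning_rate=config.learning_rate,
                                 epochs=config.epochs, seed=config.seed)
        model.to_json(outdir / "pixel_classifier.json")
        prob = classifier.predict_map(model, stack)
        detections = classifier.postprocess(prob, px_size,
                                            config.min_object_um2, config.min_hole_um2)

        # ---------------------------------------------------------- dearray
        stage("dearray")
        grid = rois.dearray(image, px_size, config.expected_rows, config.expected_cols)

        # ------------------------------------------------------ registration
        stage("registration")
        tissue_mask = features.rgb_to_od(image).mean(axis=2) > 0.04
        if config.refine_registration:
            transform, score = registration.refine_by_ion_image(
                transform0, tissue_mask, spectra.rms_normalize(ds_raw),
                ref_mz=config.ref_mz, tol_ppm=config.tol_ppm)
            log.info("refined registration score %.3f", score)
        else:
            transform, score = transform0, float("nan")
        (outdir / "transform.json").write_text(transform.to_json())

        # --------------------------------------------- label transfer + ROIs
        stage("rois")
        labeled = rois.transfer_labels(detections, pathologist)
        roi_sets = rois.build_roi_types(grid, pathologist, labeled, transform,
                                        ds_raw, buffer_um=config.buffer_um)
        pd.concat([r.to_dataframe() for r in roi_sets.values()]).to_csv(
            outdir / "roi_spots.csv", index=False)

        # ------------------------------------------- normalize, mean spectra
        stage("spectra")
        ds = spectra.rms_normalize(ds_raw)
        peak_lists = {}
        for rt, roi in roi_sets.items():
            mean = spectra.mean_spectrum(ds, roi.all_spots())
            pd.DataFrame({"mz": ds.mz_axis, "intensity": mean}).to_csv(
                outdir / f"mean_spectrum_{rt}.csv.gz", index=False)
            pl = spectra.pick_peaks(ds.mz_axis, mean, snr_min=config.snr_min,
                                    rel_int_min=config.rel_int_min, source_roi=rt)
            pl.to_csv(outdir / f"peaks_{rt}.csv")
            peak_lists[rt] = pl

        # --------------------------------------------------- discrimination
        stage("discriminate")
        panel = (discriminate.InterferentPanel.from_csv(config.panel_path, config.tol_ppm)
                 if config.panel_path else discriminate.InterferentPanel(tol_ppm=config.tol_ppm))
        panel_matrices = {rt: discriminate.build_feature_matrix(ds, roi, panel.all_mz,
                                                                config.tol_ppm)
                          for rt, roi in roi_sets.items()}
        mz_range = (float(ds.mz_axis[0]), float(ds.mz_axis[-1]))
        interferent_table = discriminate.score_interferents(panel_matrices, panel, mz_range)
        interferent_table.to_csv(outdir / "interferents.csv", index=False)

        matrices = {rt: discriminate.build_feature_matrix(ds, roi_sets[rt], peak_lists[rt],
                                                          config.tol_ppm)
                    for rt in roi_sets}
        pca_results, roc_tables, counts = {}, {}, {}
        for rt, matrix in matrices.items():
            diag = np.isin(matrix.labels, DIAGNOSIS_LABELS)
            sub = discriminate.FeatureMatrix(matrix.values[diag], matrix.mz,
                                             [s for s, d in zip(matrix.spots, diag) if d],
                                             matrix.labels[diag], rt)
            pca_results[rt] = discriminate.pca(sub, config.pca_components)
            roc = discriminate.roc_analysis(sub, auc_hi=config.auc_hi, auc_lo=config.auc_lo)
            roc.to_csv(outdir / f"roc_{rt}.csv", index=False)
            roc_tables[rt] = roc
            counts[rt] = discriminate.count_discriminatory(roc)[0]

        # ----------------------------------------------------------- summary
        stage("summary")
        class_pairs = sorted({(a, b) for rt in roc_tables
                              for a, b in roc_tables[rt][["class_a", "class_b"]]
                              .itertuples(index=False)})
        summary = {
            "seed": config.seed,
            "roi_types": sorted(roi_sets),
            "spot_counts": {rt: roi_sets[rt].n_spots() for rt in roi_sets},
            "peak_counts": {rt: len(peak_lists[rt]) for rt in roi_sets},
            "discriminatory_counts": counts,
            "class_pairs": [list(p) for p in class_pairs],
            "pca_explained_variance": {
                rt: pca_results[rt].explained_variance_ratio.tolist() for rt in pca_results},
            "interferent_pct_change_PC_vs_FC": _mean_col(interferent_table, "pct_change_PC_vs_FC"),
            "interferent_pct_change_PC_vs_PAT": _mean_col(interferent_table, "pct_change_PC_vs_PAT"),
            "hcca_pct_change_PC_vs_FC": _mean_col(
                interferent_table[interferent_table["kind"] == "hcca"], "pct_change_PC_vs_FC"),
            "hcca_pct_change_PC_vs_PAT": _mean_col(
                interferent_table[interferent_table["kind"] == "hcca"], "pct_change_PC_vs_PAT"),
            "registration_score": None if np.isnan(score) else score,
            "stages": stage_log,
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
        manifest = {
            "config": {f.name: _jsonable(getattr(config, f.name))
                       for f in dataclasses.fields(config)},
            "input_hashes": {name: _sha256(Path(p)) for name, p in (
                ("image", config.image_path), ("imzml", config.imzml_path))
                if p and Path(p).exists()},
            "seed": config.seed,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return summary
    except Exception as err:
        name = stage_log[-1]["stage"] if stage_log else "setup"
        raise RuntimeError(f"pipeline failed in stage '{name}': {err}") from err


def _mean_col(df: pd.DataFrame, col: str):
    if col not in df or df[col].dropna().empty:
        return None
    return float(df[col].dropna().mean())


def _jsonable(v):
    if isinstance(v, tuple):
        return list(v)
    return v
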