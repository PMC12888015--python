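"""Spectral comparison of ROI types: interferents, PCA, ROC/AUC.

The point of morphology-guided ROI selection is that restricting spectra
to cell-rich regions suppresses non-biological signal — HCCA matrix
cluster adducts (enriched in colloid) and trypsin autolysis products —
while concentrating tryptic-peptide signal.  This module quantifies that:

* :func:`score_interferents` — mean per-spot intensity of an interferent
  panel per ROI type, with the percent change of the pixel-classifier ROI
  against the full-core and pathologist ROIs;
* :func:`pca` — unit-variance-scaled principal components of per-spot
  feature intensities (default 5 components);
* :func:`roc_analysis` — per-feature, per-class-pair AUC by the
  tie-corrected rank-sum (Mann–Whitney) formulation; a feature is
  *discriminatory* when AUC > 0.7 or AUC < 0.3;
* :func:`count_discriminatory` — features discriminatory in ≥ 1 pair.

No multiple-testing correction is applied to the AUC flags; the flags are
screening output, not inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .fixtures import HCCA_ADDUCT_MZ, TRYPSIN_AUTOLYSIS_MZ
from .spectra import MSIDataset, PeakList, extract_peak_intensities

AUC_HI = 0.7
AUC_LO = 0.3


@dataclass
class InterferentPanel:
    """Reference m/z values of known non-biological peaks."""

    hcca_mz: tuple[float, ...] = HCCA_ADDUCT_MZ
    trypsin_mz: tuple[float, ...] = TRYPSIN_AUTOLYSIS_MZ
    tol_ppm: float = 20.0

    def __post_init__(self):
        self.hcca_mz = tuple(sorted(self.hcca_mz))
        self.trypsin_mz = tuple(sorted(self.trypsin_mz))
        allmz = np.array(sorted(self.hcca_mz + self.trypsin_mz))
        if allmz.size > 1:
            rel = np.diff(allmz) / allmz[:-1]
            if np.any(rel <= 2 * self.tol_ppm * 1e-6):
                raise ValueError("panel m/z values overlap within tolerance")

    @property
    def all_mz(self) -> np.ndarray:
        return np.array(sorted(self.hcca_mz + self.trypsin_mz))

    @classmethod
    def from_csv(cls, path, tol_ppm: float = 20.0) -> "InterferentPanel":
        df = pd.read_csv(path)
        kind = df["kind"].str.lower() if "kind" in df else pd.Series(["hcca"] * len(df))
        return cls(tuple(df.loc[kind == "hcca", "mz"]),
                   tuple(df.loc[kind == "trypsin", "mz"]), tol_ppm)


@dataclass
class FeatureMatrix:
    """Per-spot intensities of a peak list's m/z features within one ROI type."""

    values: np.ndarray               # (n_spots, n_features)
    mz: np.ndarray                   # (n_features,)
    spots: list[tuple[int, int]]
    labels: np.ndarray               # (n_spots,) diagnosis label per spot
    roi_type: str = ""

    def __post_init__(self):
        self.values = np.nan_to_num(np.asarray(self.values, float), nan=0.0)
        self.mz = np.asarray(self.mz, float)
        self.labels = np.asarray(self.labels)

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"{m:.4f}" for m in self.mz])
        df.insert(0, "label", self.labels)
        df.insert(0, "spot_y", [s[1] for s in self.spots])
        df.insert(0, "spot_x", [s[0] for s in self.spots])
        return df


def build_feature_matrix(ds: MSIDataset, roiset, peak_mzs,
                         tol_ppm: float = 20.0) -> FeatureMatrix:
    """Extract the per-spot intensity matrix for one ROI set."""
    mzs = np.asarray(peak_mzs.mz if isinstance(peak_mzs, PeakList) else peak_mzs, float)
    spots, labels = [], []
    for label, spot_set in sorted(roiset.entries.items()):
        for s in sorted(spot_set):
            spots.append(s)
            labels.append(label)
    values = extract_peak_intensities(ds, mzs, tol_ppm, spots=spots)
    return FeatureMatrix(values, mzs, spots, np.array(labels), roiset.roi_type)


# --------------------------------------------------------------- interferents

def score_interferents(matrices: dict[str, FeatureMatrix],
                       panel: InterferentPanel,
                       mz_range: tuple[float, float] | None = None) -> pd.DataFrame:
    """Mean relative interferent intensity per ROI type and PC percent change.

    For each panel m/z the mean over spots is computed per ROI type and
    scaled so the maximum across ROI types is 1; percent change columns
    compare PC against each other ROI type as 100 · (PC − other) / other.
    Panel entries outside ``mz_range`` are excluded with a warning.
    """
    panel_mz = panel.all_mz
    kinds = np.where(np.isin(panel_mz, panel.hcca_mz), "hcca", "trypsin")
    if mz_range is not None:
        inside = (panel_mz >= mz_range[0]) & (panel_mz <= mz_range[1])
        if not inside.all():
            warnings.warn(f"panel m/z outside dataset range excluded: "
                          f"{panel_mz[~inside].tolist()}")
        panel_mz, kinds = panel_mz[inside], kinds[inside]

    rows = []
    roi_types = sorted(matrices)
    for pm, kind in zip(panel_mz, kinds):
        means = {}
        for rt in roi_types:
            m = matrices[rt]
            col = np.argmin(np.abs(m.mz - pm))
            if abs(m.mz[col] - pm) > pm * panel.tol_ppm * 1e-6:
                means[rt] = np.nan
            else:
                means[rt] = float(m.values[:, col].mean())
        top = np.nanmax(list(means.values())) or np.nan
        row = {"mz": pm, "kind": kind}
        for rt in roi_types:
            row[f"mean_{rt}"] = means[rt]
            row[f"rel_{rt}"] = means[rt] / top if top else np.nan
        if "PC" in means:
            for rt in roi_types:
                if rt != "PC" and means.get(rt):
                    row[f"pct_change_PC_vs_{rt}"] = 100.0 * (means["PC"] - means[rt]) / means[rt]
        rows.append(row)
    return pd.DataFrame(rows)


# ------------------------------------------------------------------------ PCA

@dataclass
class PCAResult:
    scores: np.ndarray               # (n_spots, k)
    loadings: np.ndarray             # (n_features_kept, k)
    explained_variance_ratio: np.ndarray
    kept_mz: np.ndarray
    labels: np.ndarray


def pca(matrix: FeatureMatrix, n_components: int = 5) -> PCAResult:
    """Unit-variance PCA of the per-spot intensity matrix.

    Columns are mean-centered and scaled to unit variance (zero-variance
    columns dropped with a warning).  The sign of each component is fixed
    so its largest-magnitude loading is positive.
    """
    from sklearn.decomposition import PCA as SKPCA

    X = matrix.values.astype(np.float64)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 spots")
    sd = X.std(axis=0)
    keep = sd > 1e-12
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance feature(s) "
                      f"at m/z {matrix.mz[~keep].tolist()}")
    X = X[:, keep]
    if X.shape[1] < n_components:
        n_components = X.shape[1]
    Xs = (X - X.mean(axis=0)) / sd[keep]
    model = SKPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(Xs)
    loadings = model.components_.T.copy()
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    return PCAResult(scores, loadings, model.explained_variance_ratio_.copy(),
                     matrix.mz[keep], matrix.labels)


# ------------------------------------------------------------------------ ROC

def auc_mannwhitney(negatives: np.ndarray, positives: np.ndarray) -> float:
    """Tie-corrected AUC: P(X_pos > X_neg) + ½ P(X_pos = X_neg)."""
    neg = np.asarray(negatives, float)
    pos = np.asarray(positives, float)
    if neg.size == 0 or pos.size == 0:
        raise ValueError("both samples must be non-empty")
    ranks = rankdata(np.concatenate([neg, pos]))
    r_pos = ranks[neg.size:].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (neg.size * pos.size))


def roc_analysis(matrix: FeatureMatrix,
                 class_pairs: list[tuple[str, str]] | None = None,
                 auc_hi: float = AUC_HI, auc_lo: float = AUC_LO) -> pd.DataFrame:
    """Per-feature AUC for each class pair, spots as observations.

    For the pair (a, b), sorted lexicographically, AUC is the probability
    that a spot of class b shows higher intensity than a spot of class a
    (ties counted ½).  A feature is flagged discriminatory when AUC >
    ``auc_hi`` or AUC < ``auc_lo``.
    """
    labels = matrix.labels
    present = sorted(set(labels))
    if class_pairs is None:
        class_pairs = list(combinations(present, 2))
    rows = []
    for a, b in class_pairs:
        a, b = sorted((a, b))
        ia, ib = labels == a, labels == b
        if not ia.any() or not ib.any():
            raise ValueError(f"class pair ({a}, {b}) has an empty class in {matrix.roi_type}")
        for f in range(matrix.mz.size):
            auc = auc_mannwhitney(matrix.values[ia, f], matrix.values[ib, f])
            rows.append({"mz": matrix.mz[f], "class_a": a, "class_b": b,
                         "auc": auc, "n_a": int(ia.sum()), "n_b": int(ib.sum()),
                         "discriminatory": bool(auc > auc_hi or auc < auc_lo)})
    return pd.DataFrame(rows)


def count_discriminatory(roc: pd.DataFrame) -> tuple[int, dict[tuple[str, str], int]]:
    """Count features discriminatory in ≥ 1 class pair (+ per-pair breakdown)."""
    if roc.empty:
        raise ValueError("empty ROC results")
    flagged = roc[roc["discriminatory"]]
    total = flagged["mz"].nunique()
    per_pair = {pair: int(grp["discriminatory"].sum())
                for pair, grp in roc.groupby(["class_a", "class_b"])}
    return int(total), per_pair
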