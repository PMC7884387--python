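"""Lithic attribute analysis: morphological indices, normalization, ordination.

Stone-tool attribute tables carry metric variables (maximum, axial and
platform dimensions, mm; platform angle, degrees) and categorical
variables (blank type, scar pattern, core typology) per artefact, plus
assemblage and class labels. The analysis chain computes the standard
point/core morphological indices, applies a rank-based normal-scores
("ordered quantile") normalization per metric column, centres and scales,
and ordinates by PCA; convex-hull overlap in the score plane summarises
whether a focal class falls within a reference class's variability.

Indices (all from calliper measurements):
  elongation     = length / width
  proximal_shape = proximal width / medial width
  distal_shape   = medial width / distal width
  flattening     = medial width / medial thickness
  tcsa           = distal width × distal thickness  (mm²; tip cross-sectional
                   area as defined here — the conventional 0.5·max width ·
                   max thickness variant is available as ``tcsa_half``)
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Point, Polygon
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA as _SkPCA
from sklearn.utils.validation import check_is_fitted

from .gmm import OrdinationModel

__all__ = [
    "INDEX_DEFINITIONS",
    "compute_indices",
    "OrderedQuantileNormalizer",
    "normalize_table",
    "pca_table",
    "assemblage_overlap",
]

INDEX_DEFINITIONS = {
    "elongation": ("length", "width"),
    "proximal_shape": ("proximal_width", "medial_width"),
    "distal_shape": ("medial_width", "distal_width"),
    "flattening": ("medial_width", "medial_thickness"),
}

LABEL_COLUMNS = ("assemblage", "class")


def _ratio(num: pd.Series, den: pd.Series, name: str) -> pd.Series:
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    bad = den.notna() & (den == 0)
    if bad.any():
        warnings.warn(
            f"{name}: zero denominator in {int(bad.sum())} row(s); index set to missing"
        )
        out[bad] = np.nan
    return out


def compute_indices(table: pd.DataFrame, half_tcsa: bool = False) -> pd.DataFrame:
    """Morphological indices per artefact row.

    Missing inputs propagate as missing indices; zero denominators warn
    and yield missing values rather than aborting a batch. Label columns
    (assemblage, class) are carried over when present.
    """
    out = pd.DataFrame(index=table.index)
    for col in LABEL_COLUMNS:
        if col in table.columns:
            out[col] = table[col]
    for name, (num, den) in INDEX_DEFINITIONS.items():
        if num in table.columns and den in table.columns:
            out[name] = _ratio(table[num], table[den], name)
        else:
            out[name] = np.nan
    if {"distal_width", "distal_thickness"} <= set(table.columns):
        out["tcsa"] = table["distal_width"] * table["distal_thickness"]
        if half_tcsa:
            out["tcsa_half"] = 0.5 * out["tcsa"]
    else:
        out["tcsa"] = np.nan
    return out


class OrderedQuantileNormalizer(BaseEstimator, TransformerMixin):
    """Rank-based normal-scores transform per column, then centre/scale.

    Each training column's empirical quantiles are mapped onto standard
    normal quantiles at rank positions ``(r - 0.5) / n``; held-out values
    are transformed by monotone interpolation between the stored
    (value, normal score) pairs, so row ordering within a column is always
    preserved. After the normal-scores step every column is centred to
    mean 0 and scaled to SD 1 on the training data. Constant columns are
    dropped with a warning.
    """

    def __init__(self, min_values: int = 3):
        self.min_values = min_values

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        self.columns_ = []
        self.maps_ = {}
        self.loc_ = {}
        self.scale_ = {}
        for col in X.columns:
            vals = X[col].dropna().to_numpy(float)
            if len(vals) < self.min_values:
                raise ValueError(
                    f"column {col!r} has {len(vals)} non-missing values; "
                    f"need at least {self.min_values}"
                )
            if np.ptp(vals) == 0:
                warnings.warn(f"column {col!r} is constant; dropped from normalization")
                continue
            order = np.sort(vals)
            # average normal scores over tied values so the map is a function
            ranks = sps.rankdata(order, method="average")
            scores = sps.norm.ppf((ranks - 0.5) / len(order))
            uniq, idx = np.unique(order, return_index=True)
            grouped = np.array(
                [scores[order == u].mean() for u in uniq]
            )
            z = np.interp(vals, uniq, grouped)
            self.columns_.append(col)
            self.maps_[col] = (uniq, grouped)
            self.loc_[col] = float(z.mean())
            self.scale_[col] = float(z.std(ddof=0)) or 1.0
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "columns_")
        X = pd.DataFrame(X)
        out = {}
        for col in self.columns_:
            uniq, grouped = self.maps_[col]
            v = X[col].to_numpy(float)
            # linear extrapolation beyond the training range keeps monotonicity
            z = np.interp(v, uniq, grouped)
            lo, hi = uniq[0], uniq[-1]
            if len(uniq) > 1:
                slope_lo = (grouped[1] - grouped[0]) / (uniq[1] - uniq[0])
                slope_hi = (grouped[-1] - grouped[-2]) / (uniq[-1] - uniq[-2])
                below, above = v < lo, v > hi
                z[below] = grouped[0] + slope_lo * (v[below] - lo)
                z[above] = grouped[-1] + slope_hi * (v[above] - hi)
            z[np.isnan(v)] = np.nan
            out[col] = (z - self.loc_[col]) / self.scale_[col]
        return pd.DataFrame(out, index=X.index)


def normalize_table(
    table: pd.DataFrame, columns=None
) -> tuple[pd.DataFrame, OrderedQuantileNormalizer]:
    """Normalize the metric columns of a table; labels are carried through.

    Returns the transformed table plus the fitted normalizer (reusable on
    held-out rows).
    """
    if columns is None:
        columns = [
            c
            for c in table.columns
            if c not in LABEL_COLUMNS and pd.api.types.is_numeric_dtype(table[c])
        ]
    est = OrderedQuantileNormalizer().fit(table[columns])
    out = est.transform(table[columns])
    for col in LABEL_COLUMNS:
        if col in table.columns:
            out[col] = table[col]
    return out, est


def pca_table(table: pd.DataFrame, columns=None) -> OrdinationModel:
    """PCA of (already normalized) metric columns, complete-case.

    Rows with any missing selected value are excluded; the exclusion
    count is recorded on the returned model as ``.n_excluded``.
    """
    if columns is None:
        columns = [
            c
            for c in table.columns
            if c not in LABEL_COLUMNS and pd.api.types.is_numeric_dtype(table[c])
        ]
    sub = table[list(columns)]
    complete = sub.notna().all(axis=1)
    n_excluded = int((~complete).sum())
    data = sub[complete].to_numpy(float)
    if len(data) < 3:
        raise ValueError(f"only {len(data)} complete rows; PCA needs at least 3")
    p = _SkPCA()
    scores = p.fit_transform(data)
    # prefer a label column that actually distinguishes groups
    labels = None
    for col in ("class", "assemblage"):
        if col in table.columns:
            cand = table.loc[complete, col].to_numpy()
            if labels is None or len(np.unique(cand)) > 1:
                labels = cand
            if len(np.unique(cand)) > 1:
                break
    model = OrdinationModel(
        kind="pca",
        axes=p.components_,
        scores=scores,
        explained=p.explained_variance_ratio_,
        center=p.mean_,
        group_labels=labels,
        estimator=p,
    )
    model.n_excluded = n_excluded
    model.columns = list(columns)
    model.index = sub.index[complete]
    return model


def _hull_polygon(points: np.ndarray) -> Polygon | None:
    try:
        hull = ConvexHull(points)
    except QhullError:
        return None
    return Polygon(points[hull.vertices])


def assemblage_overlap(scores: np.ndarray, labels, axes: int = 2) -> pd.DataFrame:
    """Pairwise convex-hull overlap in the leading score plane.

    For each ordered label pair (focal, reference): the intersection-
    over-union of the two convex hulls, the centroid distance, and a
    ``falls_within`` flag that is true when every focal point lies inside
    the reference hull. Labels with fewer than 3 points have no hull and
    are reported with missing overlap.
    """
    pts = np.asarray(scores, float)[:, :axes]
    if axes != 2:
        raise ValueError("hull overlap is defined on a 2D score plane")
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 labels")
    polys = {}
    for u in uniq:
        p = pts[labels == u]
        polys[u] = _hull_polygon(p) if len(p) >= 3 else None
    rows = []
    for a in uniq:
        for b in uniq:
            if a == b:
                continue
            pa, pb = pts[labels == a], pts[labels == b]
            cdist = float(np.linalg.norm(pa.mean(axis=0) - pb.mean(axis=0)))
            if polys[a] is None or polys[b] is None:
                rows.append((a, b, np.nan, cdist, None, "hull undefined (<3 points)"))
                continue
            inter = polys[a].intersection(polys[b]).area
            union = polys[a].union(polys[b]).area
            frac = inter / union if union > 0 else (1.0 if inter == 0 else 0.0)
            ref = polys[b].buffer(1e-9)  # tolerance for boundary points
            within = bool(all(ref.covers(Point(q[0], q[1])) for q in pa))
            rows.append((a, b, frac, cdist, within, ""))
    return pd.DataFrame(
        rows,
        columns=["focal", "reference", "overlap_fraction", "centroid_distance",
                 "falls_within", "note"],
    )
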