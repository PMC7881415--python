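"""Per-animal respiratory descriptors, PCA, and pre/post effect distance.

Each animal/condition recording is summarized by 48 features: for each
of 12 base respiratory metrics, the mean, the coefficient of variation,
and the Poincare short- and long-axis dispersions SD1/SD2 of the
per-breath series. PCA (on z-scored features) embeds the animals, and
the treatment effect per animal is the Euclidean distance between its
pre- and post-treatment projections across the retained components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "BASE_METRICS",
    "FEATURE_STATS",
    "PoincareFeatures",
    "PcaModel",
    "EffectDistance",
    "poincare_features",
    "assemble_feature_vectors",
    "feature_names",
    "fit_pca",
    "project",
    "effect_distance",
]

#: The 12 base per-breath metrics (BreathTable columns) entering the
#: 48-feature descriptor, in fixed order.
BASE_METRICS = ("freq_bpm", "vt", "ve", "ti_s", "te_s", "pif", "pef",
                "ef50", "eip_ms", "eep_ms", "pau", "penh")
FEATURE_STATS = ("mean", "cv", "sd1", "sd2")


@dataclass(frozen=True)
class PoincareFeatures:
    """Dispersion of a per-breath series along the Poincare plot axes.

    SD1 (perpendicular to identity) captures breath-to-breath
    variability, SD2 (along identity) longer-term variability.
    """

    sd1: float
    sd2: float
    sd_ratio: float


def poincare_features(series) -> PoincareFeatures:
    """SD1/SD2 from successive pairs (x_n, x_n+1).

    SD1 = population std of (x_{n+1} - x_n)/sqrt(2);
    SD2 = population std of (x_{n+1} + x_n)/sqrt(2).
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("poincare_features needs at least 3 finite values")
    d = (x[1:] - x[:-1]) / np.sqrt(2.0)
    s = (x[1:] + x[:-1]) / np.sqrt(2.0)
    sd1 = float(np.std(d))
    sd2 = float(np.std(s))
    ratio = sd1 / sd2 if sd2 > 0 else np.nan
    return PoincareFeatures(sd1=sd1, sd2=sd2, sd_ratio=ratio)


def feature_names(metrics: Sequence[str] = BASE_METRICS) -> list[str]:
    """Globally ordered, stable feature names (metric-major order)."""
    return [f"{m}_{s}" for m in metrics for s in FEATURE_STATS]


def _features_for_table(breaths: pd.DataFrame, metrics: Sequence[str]) -> np.ndarray:
    out = []
    for m in metrics:
        x = breaths[m].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        if x.size < 3:
            raise ValueError(f"metric '{m}' has fewer than 3 finite per-breath values")
        mean = float(np.mean(x))
        std = float(np.std(x))
        # a constant series has no variability even at mean 0
        cv = std / abs(mean) if mean != 0 else (0.0 if std == 0 else np.nan)
        pc = poincare_features(x)
        out.extend([mean, cv, pc.sd1, pc.sd2])
    return np.asarray(out)


def assemble_feature_vectors(tables: Mapping[tuple, pd.DataFrame],
                             metrics: Sequence[str] = BASE_METRICS) -> pd.DataFrame:
    """Build the per-animal descriptor matrix.

    Parameters
    ----------
    tables : mapping
        ``{(animal_id, condition): BreathTable}``; every animal must have
        both a "pre" and a "post" condition entry.
    metrics : sequence of str
        Base metrics; the default 12 give the 48-feature schema
        (12 metrics x {mean, CV, SD1, SD2}).

    Returns
    -------
    DataFrame indexed by (animal_id, condition) with one column per
    feature, metric-major fixed order.
    """
    animals = sorted({a for (a, _) in tables})
    for a in animals:
        if (a, "pre") not in tables or (a, "post") not in tables:
            raise ValueError(f"animal {a!r} is missing a pre or post recording")
    names = feature_names(metrics)
    rows, index = [], []
    for a in animals:
        for cond in ("pre", "post"):
            vec = _features_for_table(tables[(a, cond)], metrics)
            bad = np.flatnonzero(~np.isfinite(vec))
            if bad.size:
                raise ValueError(
                    f"non-finite feature {names[bad[0]]!r} for animal {a!r} ({cond})")
            rows.append(vec)
            index.append((a, cond))
    return pd.DataFrame(rows, columns=names,
                        index=pd.MultiIndex.from_tuples(index, names=["animal", "condition"]))


@dataclass(frozen=True)
class PcaModel:
    """Standardization parameters plus an orthonormal loading matrix."""

    feature_names: tuple
    mean_: np.ndarray
    scale_: np.ndarray
    components_: np.ndarray          # (n_components, n_features)
    explained_variance_ratio_: np.ndarray
    n_components: int


def fit_pca(matrix: pd.DataFrame, standardize: bool = True) -> PcaModel:
    """Fit PCA on the feature matrix (z-scored columns by default).

    Constant columns cannot be z-scored and are dropped with a warning.
    All components with nonzero variance are retained (at most
    min(n_rows - 1, n_features)); they are orthonormal and sorted by
    explained variance, descending.
    """
    if len(matrix) < 2:
        raise ValueError("PCA needs at least 2 rows")
    X = matrix.to_numpy(dtype=float)
    names = list(matrix.columns)
    sd = X.std(axis=0)
    if standardize:
        keep = sd > 0
        if not np.all(keep):
            dropped = [n for n, k in zip(names, keep) if not k]
            warnings.warn(f"dropping constant feature(s) before standardization: {dropped}",
                          stacklevel=2)
            X = X[:, keep]
            names = [n for n, k in zip(names, keep) if k]
            sd = sd[keep]
        mean, scale = X.mean(axis=0), X.std(axis=0)
    else:
        mean, scale = X.mean(axis=0), np.ones(X.shape[1])
    Z = (X - mean) / scale
    pca = PCA(svd_solver="full")
    pca.fit(Z)
    nz = pca.explained_variance_ > max(1e-12, 1e-12 * pca.explained_variance_[0])
    k = int(np.sum(nz))
    return PcaModel(
        feature_names=tuple(names),
        mean_=mean,
        scale_=scale,
        components_=pca.components_[:k].copy(),
        explained_variance_ratio_=pca.explained_variance_ratio_[:k].copy(),
        n_components=k,
    )


def _as_vector(model: PcaModel, vec) -> np.ndarray:
    if isinstance(vec, pd.Series):
        missing = [n for n in model.feature_names if n not in vec.index]
        if missing:
            raise ValueError(f"feature schema mismatch; missing {missing[:3]}...")
        arr = vec.loc[list(model.feature_names)].to_numpy(dtype=float)
    else:
        arr = np.asarray(vec, dtype=float)
        if arr.shape != (len(model.feature_names),):
            raise ValueError("feature schema mismatch: wrong vector length")
    return arr


def project(model: PcaModel, vec) -> np.ndarray:
    """Center/scale a feature vector by the model and project onto the
    retained components."""
    z = (_as_vector(model, vec) - model.mean_) / model.scale_
    return model.components_ @ z


@dataclass(frozen=True)
class EffectDistance:
    animal_id: object
    distance: float
    n_dims_used: int


def effect_distance(model: PcaModel, pre, post,
                    animal_id=None, n_dims: Optional[int] = None) -> EffectDistance:
    """Euclidean distance between pre- and post-treatment projections.

    With all components retained this equals the l2 distance in the
    standardized feature space (orthogonal projection is an isometry on
    the span). ``n_dims`` restricts the distance to the leading
    components.
    """
    p_pre = project(model, pre)
    p_post = project(model, post)
    k = model.n_components if n_dims is None else int(n_dims)
    if not (1 <= k <= model.n_components):
        raise ValueError("n_dims out of range")
    d = float(np.linalg.norm(p_pre[:k] - p_post[:k]))
    return EffectDistance(animal_id=animal_id, distance=d, n_dims_used=k)
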