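"""Multichannel fluorescence image quantification.

Nuclei segmentation (Otsu + distance-transform watershed), K-means
isolation of a spatial domain from object centroids, per-object
intensity/Haralick/shape features under the segmentation mask,
marker-positivity counting, proliferation fractions, dual-pulse S-phase
estimation, maximum-intensity projection, LoG puncta counting and ROI
mean gray value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import polygon2mask
from skimage.feature import blob_log, graycomatrix, graycoprops, peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as sk_label, regionprops, regionprops_table
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed
from sklearn.cluster import KMeans

__all__ = [
    "PulseLabelCounts",
    "SPhaseEstimate",
    "DomainAssignment",
    "segment_nuclei",
    "kmeans_domain",
    "extract_features",
    "classify_marker_positive",
    "proliferation_metrics",
    "estimate_s_phase",
    "max_projection",
    "count_puncta",
    "roi_mean_gray",
]

GLCM_PROPS = ("contrast", "correlation", "energy", "homogeneity")
DEFAULT_GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_nuclei(image: np.ndarray,
                   sigma_px: float = 2.0,
                   min_area_px: int = 30,
                   split_touching: bool = True,
                   min_distance_px: Optional[int] = None):
    """Segment nuclei in a single-channel 2-D image.

    Gaussian smoothing -> Otsu global threshold -> hole filling ->
    distance-transform watershed split of touching nuclei -> size
    filter. Fully deterministic. An image with nothing above threshold
    yields an empty label map (not an error).

    Returns
    -------
    (labels, objects)
        ``labels`` : int32 label image, background 0, labels 1..N;
        ``objects`` : DataFrame skeleton with label, centroid and area.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment_nuclei expects a single-channel 2-D image")
    sm = gaussian(img, sigma=sigma_px, preserve_range=True) if sigma_px > 0 else img
    if np.all(sm == sm.flat[0]):
        return np.zeros(img.shape, np.int32), _skeleton_table(np.zeros(img.shape, np.int32))
    mask = sm > threshold_otsu(sm)
    mask = ndi.binary_fill_holes(mask)
    mask = remove_small_objects(mask, max_size=int(min_area_px) - 1)
    if not mask.any():
        return np.zeros(img.shape, np.int32), _skeleton_table(np.zeros(img.shape, np.int32))

    if split_touching:
        comps = sk_label(mask)
        if min_distance_px is None:
            # expected nucleus radius from the median component area
            areas = np.bincount(comps.ravel())[1:]
            min_distance_px = max(3, int(round(np.sqrt(np.median(areas) / np.pi))))
        distance = ndi.distance_transform_edt(mask)
        # smoothing leaves one maximum per convex blob (EDT ridges are flat)
        coords = peak_local_max(ndi.gaussian_filter(distance, 2.0),
                                min_distance=int(min_distance_px),
                                labels=comps, exclude_border=False)
        markers = np.zeros(mask.shape, dtype=np.int32)
        markers[tuple(coords.T)] = np.arange(1, coords.shape[0] + 1)
        labels = watershed(-distance, markers, mask=mask)
    else:
        labels = sk_label(mask)
    labels = remove_small_objects(labels, max_size=int(min_area_px) - 1)
    labels = _relabel(labels)  # contiguous 1..N
    return labels.astype(np.int32), _skeleton_table(labels)


def _relabel(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(ids, start=1):
        out[labels == old] = new
    return out


def _skeleton_table(labels: np.ndarray) -> pd.DataFrame:
    if labels.max() == 0:
        return pd.DataFrame(columns=["label", "centroid_row", "centroid_col", "area_px"])
    props = regionprops_table(labels, properties=("label", "centroid", "area"))
    return pd.DataFrame({
        "label": props["label"],
        "centroid_row": props["centroid-0"],
        "centroid_col": props["centroid-1"],
        "area_px": props["area"],
    })


# ---------------------------------------------------------------------------
# domain isolation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainAssignment:
    cluster: np.ndarray       # cluster id per object
    domain_cluster: int       # the selected domain of interest
    in_domain: np.ndarray     # boolean mask per object


def kmeans_domain(objects: pd.DataFrame, k: int, seed: int = 0,
                  feature_columns: Sequence[str] = ("centroid_row", "centroid_col"),
                  anchor: str = "ventral-extreme",
                  axis_column: str = "centroid_row",
                  direction: int = +1,
                  n_init: int = 10) -> DomainAssignment:
    """K-means on object centroids; pick the anatomically extreme cluster.

    The domain of interest is the cluster whose mean ``axis_column``
    coordinate is extreme along ``direction`` (+1 = largest, e.g. the
    ventral-most cluster when rows grow ventrally). Deterministic per
    seed; cluster relabeling cannot change the selected membership
    because selection is by position, not label.
    """
    if k < 1 or k > len(objects):
        raise ValueError("k must satisfy 1 <= k <= n_objects")
    X = objects.loc[:, list(feature_columns)].to_numpy(dtype=float)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    cluster = km.fit_predict(X)
    axis = objects[axis_column].to_numpy(dtype=float)
    means = np.array([axis[cluster == c].mean() for c in range(k)])
    domain = int(np.argmax(direction * means))
    return DomainAssignment(cluster=cluster, domain_cluster=domain,
                            in_domain=cluster == domain)


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def _quantize_masked(values: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    """Quantize in-mask intensities to 1..levels (per-object min-max);
    out-of-mask pixels get 0 so they can be excluded from co-occurrence."""
    q = np.zeros(values.shape, dtype=np.uint8)
    inside = values[mask]
    lo, hi = inside.min(), inside.max()
    if hi > lo:
        q[mask] = 1 + np.minimum(
            (levels * (values[mask] - lo) / (hi - lo)).astype(int), levels - 1)
    else:
        q[mask] = 1
    return q


def _glcm_features(values: np.ndarray, mask: np.ndarray, levels: int,
                   distances: Sequence[int], angles: Sequence[float]) -> dict:
    q = _quantize_masked(values, mask, levels)
    glcm = graycomatrix(q, distances=list(distances), angles=list(angles),
                        levels=levels + 1, symmetric=True, normed=False)
    glcm = glcm[1:, 1:, :, :].astype(float)   # drop pairs touching outside-mask
    totals = glcm.sum(axis=(0, 1), keepdims=True)
    totals[totals == 0] = 1.0
    glcm /= totals
    return {p: float(np.mean(graycoprops(glcm, p))) for p in GLCM_PROPS}


def extract_features(labels: np.ndarray,
                     channels: Mapping[str, np.ndarray],
                     glcm_levels: int = 32,
                     glcm_distances: Sequence[int] = (1,),
                     glcm_angles: Sequence[float] = DEFAULT_GLCM_ANGLES) -> pd.DataFrame:
    """Per-object intensity, Haralick texture and shape features.

    All measurements are taken strictly under the object's mask (pixels
    outside an object never influence its features): mean intensity over
    the mask per channel; Haralick statistics (contrast, correlation,
    energy, homogeneity) of the mask-restricted, 32-level quantized
    gray-level co-occurrence matrix averaged over the offsets; shape from
    the mask's second moments (area, eccentricity, orientation).
    """
    labels = np.asarray(labels)
    for name, ch in channels.items():
        if np.asarray(ch).shape != labels.shape:
            raise ValueError(f"channel {name!r} geometry does not match the label map")
    rows = []
    for rp in regionprops(labels):
        row = {
            "label": rp.label,
            "centroid_row": rp.centroid[0],
            "centroid_col": rp.centroid[1],
            "area_px": rp.area,
            "eccentricity": rp.eccentricity,
            "orientation_rad": rp.orientation,
        }
        sl = rp.slice
        mask = rp.image
        for name, ch in channels.items():
            patch = np.asarray(ch, dtype=float)[sl]
            row[f"{name}_mean"] = float(patch[mask].mean())
            glcm = _glcm_features(patch, mask, glcm_levels, glcm_distances, glcm_angles)
            for p, val in glcm.items():
                row[f"{name}_glcm_{p}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# marker positivity / proliferation / S-phase
# ---------------------------------------------------------------------------

def classify_marker_positive(objects: pd.DataFrame, channel: str,
                             method: str = "otsu",
                             threshold: Optional[float] = None):
    """Call objects positive for a marker from their mean intensities.

    ``method="otsu"`` thresholds the per-object mean-intensity
    distribution by Otsu's criterion; ``method="fixed"`` uses
    ``threshold``. Returns (positive bool array, n_positive).
    """
    col = f"{channel}_mean" if f"{channel}_mean" in objects.columns else channel
    x = objects[col].to_numpy(dtype=float)
    if method == "otsu":
        if np.all(x == x[0]):
            raise ValueError("all intensities identical; Otsu is undefined - "
                             "use method='fixed' with an explicit threshold")
        thr = threshold_otsu(x)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown method {method!r}")
    pos = x > thr
    return pos, int(pos.sum())


@dataclass(frozen=True)
class PulseLabelCounts:
    """Nucleus counts for the dual-pulse assay in one region.

    ``n_brdu_pos`` counts CldU+ nuclei (CldU is detected with an
    anti-BrdU antibody, so tables keep the BrdU name).
    """

    n_dapi: int
    n_brdu_pos: int
    n_edu_pos: int
    n_brdu_pos_edu_neg: int
    region_id: object = None

    def __post_init__(self) -> None:
        if min(self.n_dapi, self.n_brdu_pos, self.n_edu_pos, self.n_brdu_pos_edu_neg) < 0:
            raise ValueError("counts must be nonnegative")
        if max(self.n_brdu_pos, self.n_edu_pos) > self.n_dapi:
            raise ValueError("marker counts cannot exceed n_dapi")
        if self.n_brdu_pos_edu_neg > self.n_brdu_pos:
            raise ValueError("n_brdu_pos_edu_neg cannot exceed n_brdu_pos")


def proliferation_metrics(counts) -> pd.DataFrame:
    """Proliferation fractions per region, plus z-scored versions.

    Accepts one PulseLabelCounts or a sequence. Returns a DataFrame with
    ``brdu_frac`` (= BrdU+/DAPI), ``edu_frac`` and, when more than one
    region is supplied, ``brdu_frac_scaled`` / ``edu_frac_scaled``
    (z-scored across regions, as used for KDE comparison plots).
    """
    if isinstance(counts, PulseLabelCounts):
        counts = [counts]
    counts = list(counts)
    for c in counts:
        if c.n_dapi == 0:
            raise ValueError("n_dapi must be > 0")
    df = pd.DataFrame({
        "region_id": [c.region_id for c in counts],
        "brdu_frac": [c.n_brdu_pos / c.n_dapi for c in counts],
        "edu_frac": [c.n_edu_pos / c.n_dapi for c in counts],
    })
    if len(df) > 1:
        for col in ("brdu_frac", "edu_frac"):
            sd = df[col].std(ddof=0)
            df[f"{col}_scaled"] = (df[col] - df[col].mean()) / sd if sd > 0 else 0.0
    return df


@dataclass(frozen=True)
class SPhaseEstimate:
    t_s_h: float
    interval_h: float
    edu_window_h: float
    n_edu_pos: int
    n_brdu_pos_edu_neg: int


def estimate_s_phase(counts: PulseLabelCounts,
                     interval_h: float = 2.0,
                     edu_window_h: float = 0.0) -> SPhaseEstimate:
    """Dual-pulse S-phase duration estimate.

    T_S = interval_h * n_edu_pos / n_brdu_pos_edu_neg - edu_window_h.
    The EdU+ cohort occupies S during the short final window of length
    ``edu_window_h``, so its steady-state share is (T_S + window)/T_c
    rather than T_S/T_c; subtracting the window corrects that bias when
    the assay's second-pulse-to-collection time is supplied (0.5 h in
    the default schedule). The leaving cohort (CldU+ EdU-) exited S
    during the ``interval_h`` between injections.
    """
    if counts.n_brdu_pos_edu_neg == 0:
        raise ValueError("no CldU+ EdU- (leaving) cells: S-phase estimate undefined")
    if interval_h <= 0 or edu_window_h < 0:
        raise ValueError("interval_h must be > 0 and edu_window_h >= 0")
    t_s = interval_h * counts.n_edu_pos / counts.n_brdu_pos_edu_neg - edu_window_h
    return SPhaseEstimate(t_s_h=float(t_s), interval_h=interval_h,
                          edu_window_h=edu_window_h,
                          n_edu_pos=counts.n_edu_pos,
                          n_brdu_pos_edu_neg=counts.n_brdu_pos_edu_neg)


# ---------------------------------------------------------------------------
# projections, puncta, ROI
# ---------------------------------------------------------------------------

def max_projection(stack, n_planes: Optional[int] = None) -> np.ndarray:
    """Per-pixel maximum-intensity projection over the leading axis."""
    planes = [np.asarray(p) for p in stack]
    if len(planes) < 1:
        raise ValueError("need at least one plane")
    shape = planes[0].shape
    if any(p.shape != shape for p in planes):
        raise ValueError("plane shape mismatch")
    if n_planes is not None:
        planes = planes[:n_planes]
    return np.maximum.reduce(planes)


def count_puncta(image: np.ndarray, log_sigma_px: float = 2.0,
                 threshold: float = 0.2):
    """Count diffraction-limited puncta by Laplacian-of-Gaussian blobs.

    ``threshold`` is relative to the image maximum (the image is
    normalized first), so uniformly rescaling intensities does not change
    the count. Returns (count, centroids array of shape (n, 2)).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("count_puncta expects a 2-D image")
    peak = img.max()
    if peak <= img.min():
        return 0, np.empty((0, 2))
    norm = (img - img.min()) / (peak - img.min())
    blobs = blob_log(norm, min_sigma=log_sigma_px * 0.7, max_sigma=log_sigma_px * 1.5,
                     num_sigma=5, threshold=threshold * 0.3)
    return blobs.shape[0], blobs[:, :2]


def roi_mean_gray(image: np.ndarray, roi) -> float:
    """Mean pixel value inside an ROI (boolean mask or polygon vertices
    as (row, col) pairs)."""
    img = np.asarray(image, dtype=float)
    roi = np.asarray(roi)
    if roi.dtype == bool:
        mask = roi
        if mask.shape != img.shape:
            raise ValueError("mask shape mismatch")
    else:
        if roi.ndim != 2 or roi.shape[1] != 2:
            raise ValueError("polygon ROI must be an (n, 2) array of (row, col)")
        if roi.min() < 0 or np.any(roi.max(axis=0) > np.asarray(img.shape)):
            raise ValueError("ROI outside image bounds")
        mask = polygon2mask(img.shape, roi)
    if not mask.any():
        raise ValueError("empty ROI")
    return float(img[mask].mean())
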