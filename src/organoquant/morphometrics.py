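"""Cell-shape, nucleus-shape, marker-intensity and organoid-morphology metrics.

The measurements mirror how they are made on real organoid images: cell axes
come from annotated line segments (a human draws the lateral/apical/basal/
width lines on junction staining; the synthetic generator emits the same
table from ground truth), nucleus circularity is 4*pi*A/P^2 on a traced
outline, proliferation is the fraction of nuclei whose marker mean exceeds a
threshold, and budding versus spherical organoids are separated by silhouette
solidity.  Automatic junction tracing is deliberately out of scope — manual
(or ground-truth) annotations are the input contract.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from shapely.geometry import Polygon as _ShapelyPolygon
from skimage.filters import threshold_otsu
from skimage.measure import perimeter_crofton, regionprops
from skimage.segmentation import watershed

from .segmentation import LabelMap, _as_labels

logger = logging.getLogger(__name__)

__all__ = [
    "measure_cell_axes",
    "nucleus_circularity",
    "per_cell_marker_intensity",
    "positive_fraction_2d",
    "count_nuclei_3d",
    "classify_budding",
    "BUDDING_SOLIDITY_THRESHOLD",
]

#: solidity below this calls an organoid silhouette "budding"; calibrated on
#: the synthetic silhouette suite so disks and lobed shapes separate cleanly
BUDDING_SOLIDITY_THRESHOLD = 0.92


def measure_cell_axes(annotations: pd.DataFrame, pixel_size: float) -> pd.DataFrame:
    """Per-cell axis lengths from labelled line segments.

    ``annotations`` columns: image, cell_id, role in {lateral, apical, basal,
    width}, x0, y0, x1, y1 (pixel coordinates), optional boolean ``excluded``
    marking dividing/rounded cells not integrated into the epithelial sheet
    (these are dropped and logged).  Each segment length is the Euclidean
    endpoint distance times ``pixel_size``; length/width = lateral / width.
    Missing roles leave the corresponding statistic NaN for that cell.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    df = annotations.copy()
    if "excluded" in df.columns:
        dropped = df.loc[df["excluded"].astype(bool), ["image", "cell_id"]].drop_duplicates()
        if len(dropped):
            logger.info(
                "measure_cell_axes: excluding %d flagged cells: %s",
                len(dropped), dropped.to_dict("records"),
            )
        excluded_cells = set(map(tuple, dropped.to_numpy()))
        df = df[~df.apply(lambda r: (r["image"], r["cell_id"]) in excluded_cells, axis=1)]
    df = df.copy()
    df["length_um"] = np.hypot(df["x1"] - df["x0"], df["y1"] - df["y0"]) * pixel_size
    wide = df.pivot_table(index=["image", "cell_id"], columns="role",
                          values="length_um", aggfunc="first").reset_index()
    wide.columns.name = None
    for role in ("lateral", "apical", "basal", "width"):
        if role not in wide.columns:
            wide[role] = np.nan
    wide = wide.rename(columns={r: f"{r}_um" for r in ("lateral", "apical", "basal", "width")})
    wide["length_width"] = wide["lateral_um"] / wide["width_um"]
    missing = wide[["lateral_um", "apical_um", "basal_um"]].isna().any(axis=1)
    if missing.any():
        logger.info("measure_cell_axes: %d cells missing one or more roles",
                    int(missing.sum()))
    return wide


def _polygon_area_perimeter(poly: np.ndarray):
    r, c = poly[:, 0], poly[:, 1]
    area = 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))
    perimeter = float(np.sum(np.hypot(np.diff(r, append=r[:1]), np.diff(c, append=c[:1]))))
    return float(area), perimeter


def _find_self_intersection(poly: np.ndarray):
    """Return (i, j) indices of a properly intersecting edge pair, or None."""
    n = len(poly)
    segs = [(poly[i], poly[(i + 1) % n]) for i in range(n)]

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent around the wrap
            p1, p2 = segs[i]
            p3, p4 = segs[j]
            d1, d2 = cross(p3, p4, p1), cross(p3, p4, p2)
            d3, d4 = cross(p1, p2, p3), cross(p1, p2, p4)
            if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
                return i, j
    return None


def nucleus_circularity(outline, method: str = "crofton") -> float:
    """Circularity 4*pi*Area/Perimeter^2 of a traced nucleus outline or mask.

    Polygon input (N >= 8 vertices, (row, col)): shoelace area and exact
    vertex-chain perimeter; self-intersecting polygons are rejected naming
    the offending edge pair.  Mask input: pixel-count area with a Crofton
    4-direction perimeter estimator (the naive pixel-edge count overestimates
    perimeters and can push circularity above 1).
    """
    outline = np.asarray(outline)
    if outline.ndim == 2 and outline.shape[1] == 2 and outline.dtype != bool:
        if len(outline) < 8:
            raise ValueError(f"polygon needs >= 8 vertices, got {len(outline)}")
        if not _ShapelyPolygon(outline).is_simple:
            pair = _find_self_intersection(outline)
            raise ValueError(f"self-intersecting polygon: edges {pair[0]} and {pair[1]} cross")
        area, perim = _polygon_area_perimeter(outline)
        if perim == 0:
            raise ValueError("degenerate polygon with zero perimeter")
        return 4 * np.pi * area / perim**2
    mask = outline.astype(bool)
    area = float(mask.sum())
    if area == 0:
        raise ValueError("empty mask")
    if method == "crofton":
        perim = float(perimeter_crofton(mask, directions=4))
    else:
        raise ValueError(f"unknown perimeter method {method!r}")
    return 4 * np.pi * area / perim**2


def per_cell_marker_intensity(
    marker: np.ndarray, nuclei, rings
) -> pd.DataFrame:
    """Per-cell marker score: mean nuclear + mean ring intensity.

    This is the per-cell quantity used for phospho-marker (pERK/pAKT)
    comparisons; raw integrated sums over each compartment are also emitted
    for transparency.  A cell whose ring was fully contested (no ring
    pixels) gets its nuclear-only value and a ``ring_missing`` flag.
    """
    lab_n = _as_labels(nuclei)
    lab_r = _as_labels(rings)
    ids = np.unique(lab_n[lab_n > 0])
    rows = []
    for k in ids:
        nmask = lab_n == k
        rmask = lab_r == k
        nuc_mean = float(marker[nmask].mean())
        nuc_sum = float(marker[nmask].sum())
        if rmask.any():
            ring_mean = float(marker[rmask].mean())
            ring_sum = float(marker[rmask].sum())
            missing = False
        else:
            ring_mean, ring_sum, missing = 0.0, 0.0, True
        rows.append(
            {
                "cell_id": int(k),
                "nuclear_mean": nuc_mean,
                "ring_mean": ring_mean,
                "per_cell_intensity": nuc_mean + ring_mean,
                "nuclear_sum": nuc_sum,
                "ring_sum": ring_sum,
                "ring_missing": missing,
            }
        )
    if any(r["ring_missing"] for r in rows):
        logger.info("per_cell_marker_intensity: %d cells lack a ring; nuclear-only values",
                    sum(r["ring_missing"] for r in rows))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PositivityResult:
    positives: int
    total: int
    fraction: float
    threshold: float
    per_nucleus: pd.DataFrame


def positive_fraction_2d(marker: np.ndarray, nuclei, threshold=None) -> PositivityResult:
    """Fraction of nuclei whose mean marker intensity exceeds a threshold.

    ``threshold`` is a fixed intensity, or None for Otsu over the per-nucleus
    means.  With zero nuclei the fraction is reported missing (NaN).
    """
    lab = _as_labels(nuclei)
    ids = np.unique(lab[lab > 0])
    if ids.size == 0:
        logger.warning("positive_fraction_2d: no nuclei; fraction undefined")
        return PositivityResult(0, 0, float("nan"), float("nan"),
                                pd.DataFrame(columns=["cell_id", "marker_mean", "positive"]))
    means = np.asarray(ndi.mean(marker, labels=lab, index=ids), dtype=float)
    if threshold is None:
        thr = float(threshold_otsu(means)) if np.unique(means).size > 1 else float(means[0])
    else:
        thr = float(threshold)
    positive = means > thr
    table = pd.DataFrame({"cell_id": ids, "marker_mean": means, "positive": positive})
    n_pos = int(positive.sum())
    return PositivityResult(n_pos, int(ids.size), n_pos / ids.size, thr, table)


@dataclass(frozen=True)
class Counts3D:
    total: int
    positives: int | None
    labels: np.ndarray


def count_nuclei_3d(
    volume: np.ndarray,
    marker: np.ndarray | None = None,
    z_ratio: float = 1.0,
    threshold: float | None = None,
    min_volume: int = 27,
    watershed_split: bool = False,
    marker_threshold: float | None = None,
) -> Counts3D:
    """Count nuclei (and marker-positive nuclei) in a (Z, Y, X) volume.

    Per-plane thresholding (Otsu on the whole volume unless ``threshold``),
    3-D connected components, minimum-volume filter; optional watershed
    splitting of touching nuclei on the anisotropy-aware distance transform
    (``z_ratio`` = z-step / pixel size).  A single-plane volume falls back to
    2-D counting with a warning.  Positivity uses volumetric marker means,
    as in the 2-D scorer.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError(f"expected (Z, Y, X) volume, got shape {vol.shape}")
    if vol.shape[0] == 1:
        warnings.warn("single-plane volume: falling back to 2-D counting", stacklevel=2)
    thr = float(threshold_otsu(vol)) if threshold is None else threshold
    fg = vol > thr
    fg = ndi.binary_fill_holes(fg)
    if watershed_split:
        dist = ndi.distance_transform_edt(fg, sampling=(z_ratio, 1.0, 1.0))
        from skimage.feature import peak_local_max

        coords = peak_local_max(dist, min_distance=2, labels=fg)
        markers = np.zeros(fg.shape, dtype=np.int32)
        markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
        labels = watershed(-dist, markers, mask=fg)
    else:
        labels, _ = ndi.label(fg)
    sizes = np.bincount(labels.ravel())
    keep = np.flatnonzero(sizes >= min_volume)
    keep = keep[keep > 0]
    relabel = np.zeros(sizes.size, dtype=np.int32)
    relabel[keep] = np.arange(1, keep.size + 1)
    labels = relabel[labels]
    total = int(labels.max())
    positives = None
    if marker is not None and total > 0:
        ids = np.arange(1, total + 1)
        means = np.asarray(ndi.mean(marker, labels=labels, index=ids), dtype=float)
        if marker_threshold is None:
            mthr = float(threshold_otsu(means)) if np.unique(means).size > 1 else float(means[0])
        else:
            mthr = marker_threshold
        positives = int((means > mthr).sum())
    elif marker is not None:
        positives = 0
    return Counts3D(total, positives, labels)


def classify_budding(mask: np.ndarray, threshold: float = BUDDING_SOLIDITY_THRESHOLD,
                     manual_label: str | None = None):
    """Classify an organoid silhouette as spherical or budding by solidity.

    Solidity = area / convex-hull area; budding iff solidity < ``threshold``.
    The cut is a calibrated surrogate for manual phenotype counting — when a
    manual label is supplied it overrides the automatic call, which is still
    reported alongside.  A disconnected mask is classified by its largest
    component with a warning.

    Returns (label, solidity).
    """
    m = np.asarray(mask).astype(bool)
    labels, n = ndi.label(m)
    if n == 0:
        raise ValueError("empty silhouette mask")
    if n > 1:
        warnings.warn(f"disconnected mask ({n} components); classifying the largest",
                      stacklevel=2)
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        m = labels == int(np.argmax(sizes))
    solidity = float(regionprops(m.astype(np.uint8))[0].solidity)
    auto = "budding" if solidity < threshold else "spherical"
    return (manual_label if manual_label is not None else auto), solidity
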