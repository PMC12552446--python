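"""Image obscurity and capture-rate diagnostics.

Wearable chest-camera images are frequently dark or obscured (indoor low
light, clothing over the lens), which degrades both human annotation and
model predictions.  This module computes per-image brightness (mean grey
intensity, 0-255) and pixel variation (population standard deviation),
flags the darkest p% of a cohort for stratified evaluation, and clusters
per-participant median capture intervals — devices in these studies were
erroneously configured at a handful of distinct base capture rates, which
shows up as clusters in the per-participant median delta-t distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Standard luma weights for grey conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def brightness_and_variation(image) -> tuple[float, float]:
    """Mean and population standard deviation of the grey-scale pixels.

    Accepts a 2-D grey array or a 3-D colour array (last axis RGB or RGBA;
    alpha is ignored); pixel values are expected in [0, 255].
    """
    arr = np.asarray(image, dtype=float)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.ndim == 3:
        if arr.shape[-1] < 3:
            raise ValueError("colour image must have >= 3 channels")
        arr = arr[..., :3] @ LUMA_WEIGHTS
    elif arr.ndim != 2:
        raise ValueError(f"expected 2-D or 3-D pixel grid, got shape {arr.shape}")
    return float(arr.mean()), float(arr.std())


def image_quality_table(manifest: pd.DataFrame, image_col: str = "path",
                        loader=None) -> pd.DataFrame:
    """Brightness/variation for every image in a manifest.

    ``manifest`` carries participant_id, timestamp and a path (or array)
    column; ``loader`` defaults to PIL for path entries.
    """
    if loader is None:
        from PIL import Image

        def loader(p):
            with Image.open(p) as im:
                return np.asarray(im)
    rows = []
    for _, row in manifest.iterrows():
        item = row[image_col]
        arr = item if isinstance(item, np.ndarray) else loader(item)
        b, v = brightness_and_variation(arr)
        rows.append({"participant_id": row.get("participant_id"),
                     "timestamp": row.get("timestamp"),
                     "brightness": b, "variation": v})
    return pd.DataFrame(rows)


def darkness_percentile_flags(brightness, p: float = 5.0) -> np.ndarray:
    """Boolean flags for the darkest p% of a cohort.

    True iff brightness <= the cohort's p-th percentile (linear
    interpolation).  With constant brightness every image sits at the
    percentile and all are flagged — degenerate but documented.
    """
    vals = np.asarray(brightness, dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one brightness value")
    if not 0 < p < 100:
        raise ValueError("percentile must be in (0, 100)")
    threshold = np.percentile(vals, p)
    return vals <= threshold


@dataclass
class CaptureRateClusters:
    """1-D clustering of per-participant median capture intervals."""
    centres: np.ndarray          # sorted, seconds
    labels: np.ndarray           # cluster index per participant (centre order)
    counts: np.ndarray           # participants per cluster
    histogram: tuple             # (counts, bin_edges) of the raw medians


def capture_rate_clusters(medians, k: int = 4,
                          random_state: int = 0) -> CaptureRateClusters:
    """Descriptive k-means grouping of per-participant median delta-t values.

    ``k`` defaults to 4 (the number of distinct base capture rates observed
    across the two studies); it is reduced with a warning when there are
    fewer distinct participants than clusters.
    """
    from sklearn.cluster import KMeans

    vals = np.asarray(medians, dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one participant median")
    k_eff = min(k, len(np.unique(vals)))
    if k_eff < k:
        warnings.warn(f"reducing k from {k} to {k_eff}: too few distinct "
                      "participant medians", stacklevel=2)
    km = KMeans(n_clusters=k_eff, n_init=10, random_state=random_state)
    raw_labels = km.fit_predict(vals[:, None])
    order = np.argsort(km.cluster_centers_.ravel())
    rank = np.empty_like(order)
    rank[order] = np.arange(k_eff)
    labels = rank[raw_labels]
    centres = np.sort(km.cluster_centers_.ravel())
    counts = np.bincount(labels, minlength=k_eff)
    hist = np.histogram(vals, bins="auto")
    return CaptureRateClusters(centres, labels, counts, hist)
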