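"""Tissue-mode spatial analyses.

Grid-binned region clustering of decoded signals (k-means on Gaussian-smoothed
per-marker layers, default pixel size and smoothing of 20) and hierarchical
clustering of per-cell profiles with optional subsampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.cluster import KMeans

__all__ = ["RegionMap", "points_to_regions", "cluster_cells"]


@dataclass
class RegionMap:
    pixel_size: float
    smoothing: float
    labels: np.ndarray  # per-grid-cell region label; -1 where empty
    counts: np.ndarray  # (grid_h, grid_w, n_markers) raw binned counts
    markers: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        gy, gx = np.nonzero(self.labels >= 0)
        rows = {"grid_y": gy, "grid_x": gx, "region": self.labels[gy, gx]}
        for i, m in enumerate(self.markers):
            rows[m] = self.counts[gy, gx, i]
        return pd.DataFrame(rows)


def points_to_regions(
    signals: pd.DataFrame,
    pixel_size: float = 20.0,
    smoothing: float = 20.0,
    k: int = 4,
    seed: int = 0,
) -> RegionMap:
    """Cluster decoded signals into coarse spatial regions.

    Signals are binned per marker onto a grid of ``pixel_size`` px, each
    marker layer is Gaussian-smoothed with scale ``smoothing`` (px; converted
    to grid units internally), and grid cells are k-means-clustered on their
    marker vectors.  Only non-empty grid cells receive a label.
    """
    if signals.empty:
        raise ValueError("no signals to cluster")
    markers = tuple(sorted(signals["marker"].dropna().unique()))
    gx = (signals["x"].to_numpy(float) // pixel_size).astype(int)
    gy = (signals["y"].to_numpy(float) // pixel_size).astype(int)
    gh, gw = gy.max() + 1, gx.max() + 1

    counts = np.zeros((gh, gw, len(markers)))
    for i, m in enumerate(markers):
        sel = (signals["marker"] == m).to_numpy()
        np.add.at(counts[:, :, i], (gy[sel], gx[sel]), 1.0)

    sigma = smoothing / pixel_size
    smoothed = np.stack(
        [ndi.gaussian_filter(counts[:, :, i], sigma) for i in range(len(markers))], axis=-1
    )

    nonempty = counts.sum(axis=-1) > 0
    n_cells = int(nonempty.sum())
    if n_cells < k:
        raise ValueError(f"only {n_cells} non-empty grid cells for k={k}")
    feats = smoothed[nonempty]
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels_flat = km.fit_predict(feats)
    labels = np.full((gh, gw), -1, dtype=int)
    labels[nonempty] = labels_flat
    return RegionMap(
        pixel_size=pixel_size, smoothing=smoothing, labels=labels, counts=counts, markers=markers
    )


def cluster_cells(
    profiles: pd.DataFrame,
    max_n: int = 10_000,
    seed: int = 0,
    method: str = "average",
    metric: str = "euclidean",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Agglomerative clustering of per-cell marker-count vectors.

    If more than ``max_n`` profiles are given, a uniform random subsample is
    drawn (seeded).  Returns (linkage matrix, leaf order, sampled positional
    indices); the leaf order indexes into the sampled rows.
    """
    if len(profiles) < 2:
        raise ValueError("hierarchical clustering requires at least 2 profiles")
    rng = np.random.default_rng(seed)
    idx = np.arange(len(profiles))
    if len(profiles) > max_n:
        idx = np.sort(rng.choice(idx, size=max_n, replace=False))
    data = profiles.iloc[idx].select_dtypes("number").to_numpy(float)
    z = linkage(data, method=method, metric=metric)
    order = leaves_list(z)
    return z, order, idx
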