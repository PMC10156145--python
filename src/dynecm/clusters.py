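"""Cluster ROIs from corrected statistic maps and their temporal variability.

Significant clusters of the static group analysis (FWE p < alpha) are turned
into integer-labelled ROIs by 26-connected component labelling; clusters of
10 voxels or fewer are dropped as unreliable.  Within each cluster the
dynamic EC series is averaged across voxels per window, and temporal SD and
range are computed from that average series (same definition as for
networks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .dualreg import temporal_variability
from .dynamic import DynamicCentralitySeries
from .io_volumes import AnalysisMask, insert_maps

__all__ = [
    "ClusterMaskSet",
    "label_significant_clusters",
    "cluster_timeseries",
    "cluster_variability",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=int)


@dataclass
class ClusterMaskSet:
    """Per-voxel integer cluster labels over a mask (0 = no cluster)."""

    mask: AnalysisMask
    labels: np.ndarray  # n_voxels int, 0 = none
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.intp)
        if self.labels.shape != (self.mask.n_voxels,):
            raise ValueError("labels length must equal mask size")
        ids = np.unique(self.labels[self.labels > 0])
        if len(ids) and not np.array_equal(ids, np.arange(1, len(ids) + 1)):
            raise ValueError("cluster ids must be contiguous from 1")
        for i in ids:
            self.names.setdefault(int(i), f"cluster_{int(i)}")

    @property
    def cluster_ids(self) -> list[int]:
        return [int(i) for i in np.unique(self.labels[self.labels > 0])]

    def cluster_size(self, cid: int) -> int:
        return int((self.labels == cid).sum())


def label_significant_clusters(
    fwe_p: np.ndarray,
    mask: AnalysisMask,
    alpha: float = 0.05,
    min_size: int = 10,
) -> ClusterMaskSet:
    """26-connected components of {voxels with corrected p < alpha}.

    Components with ``min_size`` voxels or fewer are discarded.  Surviving
    clusters are relabelled 1..k in decreasing size order.
    """
    p = np.asarray(fwe_p, dtype=float)
    if p.shape != (mask.n_voxels,):
        raise ValueError("fwe_p must be one value per mask voxel")
    sig = insert_maps((p < alpha).astype(float), mask)[..., 0] > 0
    lab, n = ndimage.label(sig, structure=_STRUCT_26)
    labels_in_mask = lab.reshape(-1)[mask.flat_indices]
    out = np.zeros(mask.n_voxels, dtype=np.intp)
    if n:
        sizes = np.bincount(labels_in_mask, minlength=n + 1)[1:]
        keep = np.nonzero(sizes > min_size)[0] + 1  # strictly more than min_size
        keep = keep[np.argsort(-sizes[keep - 1], kind="stable")]
        for new_id, old_id in enumerate(keep, start=1):
            out[labels_in_mask == old_id] = new_id
    return ClusterMaskSet(mask=mask, labels=out)


def cluster_timeseries(
    dyn: DynamicCentralitySeries, clusters: ClusterMaskSet
) -> dict[str, np.ndarray]:
    """Unweighted within-cluster mean of the dynamic EC series, per window."""
    if clusters.mask != dyn.mask:
        raise ValueError("clusters and dynamic series must share a mask")
    out: dict[str, np.ndarray] = {}
    for cid in clusters.cluster_ids:
        sel = clusters.labels == cid
        if not sel.any():
            raise ValueError(f"cluster {cid} is empty")
        out[clusters.names[cid]] = dyn.values[sel].mean(axis=0)
    return out


def cluster_variability(series: dict[str, np.ndarray]) -> pd.DataFrame:
    """Temporal SD and range per cluster series (shared definition with networks)."""
    rows = []
    for name, vals in series.items():
        sd, rng = temporal_variability(np.asarray(vals))
        rows.append({"cluster": name, "sd": sd, "range": rng})
    return pd.DataFrame(rows)
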