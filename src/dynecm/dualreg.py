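"""Dual regression of dynamic centrality onto canonical network templates.

Stage 1 regresses each window's EC map on the full set of network template
maps simultaneously (multiple spatial regression, intercept included),
yielding one EC time course per network.  Stage 2 regresses each voxel's EC
time series on all network time courses simultaneously, yielding
subject-specific spatial maps.  Temporal variability of a network is the
sample SD and max-min range of its stage-1 time course across windows.

Both stages demean their regressors and include an intercept.  Stage-2 time
courses are additionally variance-normalized (default on) so spatial-map
magnitudes are comparable across networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamic import DynamicCentralitySeries, WindowScheme
from .io_volumes import AnalysisMask

__all__ = [
    "TemplateSet",
    "NetworkTimecourses",
    "SubjectSpatialMaps",
    "CollinearityError",
    "dual_regression_stage1",
    "dual_regression_stage2",
    "network_variability",
    "template_mean_timecourses",
    "temporal_variability",
]


class CollinearityError(ValueError):
    """Design matrix is rank deficient."""


@dataclass
class TemplateSet:
    """K spatial network maps over a shared mask (n_voxels x K weights)."""

    mask: AnalysisMask
    maps: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if self.maps.ndim != 2 or self.maps.shape[0] != self.mask.n_voxels:
            raise ValueError("maps must be n_voxels x K")
        if self.maps.shape[1] < 1:
            raise ValueError("need at least one template")
        self.names = tuple(str(n) for n in self.names)
        if len(self.names) != self.maps.shape[1]:
            raise ValueError("one name per template required")
        zero = ~self.maps.any(axis=0)
        if zero.any():
            bad = [self.names[k] for k in np.nonzero(zero)[0]]
            raise ValueError(f"all-zero template column(s): {bad}")

    @property
    def n_networks(self) -> int:
        return self.maps.shape[1]


@dataclass
class NetworkTimecourses:
    """Per-network EC time courses (n_windows x K), column order = templates."""

    subject_id: str
    values: np.ndarray
    scheme: WindowScheme
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.scheme.n_windows, len(self.names)):
            raise ValueError("values must be n_windows x K")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite time course values")


@dataclass
class SubjectSpatialMaps:
    """Stage-2 regression coefficients (n_voxels x K), column order = templates."""

    subject_id: str
    maps: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if self.maps.ndim != 2 or self.maps.shape[1] != len(self.names):
            raise ValueError("maps must be n_voxels x K")
        if not np.isfinite(self.maps).all():
            raise ValueError("non-finite map values")


def _design(columns: np.ndarray, names: Sequence[str], normalize: bool) -> np.ndarray:
    """Intercept + demeaned (optionally variance-normalized) regressors."""
    X = columns - columns.mean(axis=0, keepdims=True)
    if normalize:
        sd = X.std(axis=0, ddof=1)
        flat = sd == 0
        if flat.any():
            bad = [names[k] for k in np.nonzero(flat)[0]]
            raise CollinearityError(
                f"constant regressor(s) collinear with intercept: {bad}"
            )
        X = X / sd
    D = np.column_stack([np.ones(X.shape[0]), X])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        corr = np.corrcoef(X.T) if X.shape[1] > 1 else np.ones((1, 1))
        pairs = [
            (names[i], names[j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
            if abs(corr[i, j]) > 0.999
        ]
        raise CollinearityError(f"rank-deficient design; collinear: {pairs or names}")
    return D


def dual_regression_stage1(
    dyn: DynamicCentralitySeries, templates: TemplateSet
) -> NetworkTimecourses:
    """Spatial regression: window EC maps -> per-network time courses."""
    if templates.mask != dyn.mask:
        raise ValueError("templates and dynamic series must share a mask")
    if templates.n_networks >= dyn.mask.n_voxels:
        raise ValueError("need K < n_voxels")
    D = _design(templates.maps, templates.names, normalize=False)
    coef, *_ = np.linalg.lstsq(D, dyn.values, rcond=None)  # (K+1) x n_windows
    return NetworkTimecourses(
        subject_id="",
        values=coef[1:].T,
        scheme=dyn.scheme,
        names=templates.names,
    )


def dual_regression_stage2(
    dyn: DynamicCentralitySeries,
    tcs: NetworkTimecourses,
    normalize_timecourses: bool = True,
) -> SubjectSpatialMaps:
    """Temporal regression: network time courses -> subject spatial maps."""
    if tcs.scheme.to_dict() != dyn.scheme.to_dict():
        raise ValueError("time courses and dynamic series must share windows")
    D = _design(tcs.values, tcs.names, normalize=normalize_timecourses)
    coef, *_ = np.linalg.lstsq(D, dyn.values.T, rcond=None)  # (K+1) x n_voxels
    return SubjectSpatialMaps(
        subject_id=tcs.subject_id, maps=coef[1:].T, names=tcs.names
    )


def temporal_variability(values: np.ndarray) -> tuple[float, float]:
    """Sample SD (ddof=1) and max-min range of a window series."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a 1D series of at least 2 windows")
    if v.max() == v.min():  # constant: exactly zero, no mean-subtraction dust
        return 0.0, 0.0
    return float(v.std(ddof=1)), float(v.max() - v.min())


def network_variability(tcs: NetworkTimecourses) -> pd.DataFrame:
    """Per-network temporal SD and range of the stage-1 time courses."""
    if tcs.scheme.n_windows < 2:
        raise ValueError("variability needs at least 2 windows")
    rows = []
    for k, name in enumerate(tcs.names):
        sd, rng = temporal_variability(tcs.values[:, k])
        rows.append({"network": name, "sd": sd, "range": rng})
    return pd.DataFrame(rows)


def template_mean_timecourses(
    dyn: DynamicCentralitySeries,
    templates: TemplateSet,
    binarize_fraction: float = 0.5,
) -> NetworkTimecourses:
    """Alternative network time courses: mean dynamic EC inside each template.

    Each template is binarized at ``binarize_fraction`` of its maximum weight
    and the unweighted in-mask mean EC is taken per window.  Provided as the
    mask-mean alternative to the stage-1 (regression) time courses.
    """
    if templates.mask != dyn.mask:
        raise ValueError("templates and dynamic series must share a mask")
    out = np.empty((dyn.n_windows, templates.n_networks))
    for k in range(templates.n_networks):
        col = templates.maps[:, k]
        sel = col >= binarize_fraction * col.max()
        if not sel.any():
            raise ValueError(f"template {templates.names[k]} binarizes to empty")
        out[:, k] = dyn.values[sel].mean(axis=0)
    return NetworkTimecourses(
        subject_id="", values=out, scheme=dyn.scheme, names=templates.names
    )
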