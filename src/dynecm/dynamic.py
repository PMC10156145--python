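"""Sliding-window ("dynamic") eigenvector centrality.

The full series is segmented into partially overlapping windows; ECM is run
per window and the per-window maps are concatenated into a voxel x window
matrix — the dynamic centrality time series.  The reference configuration is
100 windows of 100 volumes over a 200-volume (TR = 2 s) acquisition.

Window starts are the rounded even spacing over [0, T - length]: for any
(T, length, n_windows) this reproduces the window count deterministically,
and for the reference configuration gives starts 0, 1, 2, ... 100 with a
double step every ~100/99 windows.  Each window is z-scored on its own so
that its connectivity matrix is that window's true correlation matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ecm import CentralityMap, fast_ecm, zscore_rows
from .io_volumes import AnalysisMask, MaskedSeries

__all__ = [
    "WindowScheme",
    "DynamicCentralitySeries",
    "build_window_scheme",
    "dynamic_ecm",
]

# shorter windows risk mistaking slow-wavelength signal for dynamics
MIN_WINDOW_SECONDS = 100.0


@dataclass(frozen=True)
class WindowScheme:
    """Deterministic description of sliding-window starts and length.

    Windows are half-open ``[s, s + length)`` in volume index.
    """

    T: int
    length: int
    starts: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (2 <= self.length <= self.T):
            raise ValueError("need 2 <= length <= T")
        starts = tuple(int(s) for s in self.starts)
        object.__setattr__(self, "starts", starts)
        if len(starts) == 0:
            raise ValueError("at least one window required")
        if any(s < 0 or s + self.length > self.T for s in starts):
            raise ValueError("every window must fit in [0, T)")
        if any(b < a for a, b in zip(starts, starts[1:])):
            raise ValueError("starts must be non-decreasing")
        if starts[0] != 0:
            raise ValueError("first window must start at 0")
        if len(starts) > 1 and starts[-1] != self.T - self.length:
            raise ValueError("last window must end at T")

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    def to_dict(self) -> dict:
        return {"T": self.T, "length": self.length, "starts": list(self.starts)}

    @classmethod
    def from_dict(cls, d: dict) -> "WindowScheme":
        return cls(T=int(d["T"]), length=int(d["length"]), starts=tuple(d["starts"]))


@dataclass
class DynamicCentralitySeries:
    """Per-window EC maps as an n_voxels x n_windows matrix."""

    mask: AnalysisMask
    values: np.ndarray
    scheme: WindowScheme

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = (self.mask.n_voxels, self.scheme.n_windows)
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} != (n_voxels, n_windows) {expected}"
            )

    @property
    def n_windows(self) -> int:
        return self.scheme.n_windows

    def window_map(self, j: int) -> CentralityMap:
        return CentralityMap(
            mask=self.mask, values=self.values[:, j], iterations=0, residual=0.0
        )


def build_window_scheme(T: int, length: int, n_windows: int) -> WindowScheme:
    """Evenly spaced (then rounded) window starts over [0, T - length].

    ``n_windows=1`` with ``length=T`` is the static case.  Duplicate starts
    can only arise when more windows are requested than distinct start
    positions exist (``T - length < n_windows - 1``); they are permitted then,
    with a warning, and are an error otherwise (the rounding of an even grid
    over at least ``n_windows`` positions cannot collide).
    """
    if not (2 <= length <= T):
        raise ValueError(f"need 2 <= length <= T, got length={length}, T={T}")
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    if n_windows > 1 and length >= T:
        raise ValueError("multiple windows require length < T")
    if n_windows == 1:
        return WindowScheme(T=T, length=length, starts=(0,))
    starts = np.rint(np.linspace(0.0, T - length, n_windows)).astype(int)
    n_unique = np.unique(starts).size
    if n_unique < n_windows:
        if T - length >= n_windows - 1:
            raise ValueError(
                f"duplicate window starts for T={T}, length={length}, "
                f"n_windows={n_windows}"
            )
        warnings.warn(
            f"only {T - length + 1} distinct start positions for "
            f"{n_windows} windows; duplicates retained",
            stacklevel=2,
        )
    return WindowScheme(T=T, length=length, starts=tuple(int(s) for s in starts))


def dynamic_ecm(
    series: MaskedSeries,
    scheme: WindowScheme,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> DynamicCentralitySeries:
    """ECM within each sliding window of a raw (un-z-scored) series.

    Column j is ``fast_ecm`` applied to the per-window z-scored sub-series of
    window j.  Warns when the window is shorter than 100 s of acquisition
    (window fluctuations below the slowest BOLD wavelength are suspect).
    """
    if scheme.T != series.n_timepoints:
        raise ValueError(
            f"scheme T={scheme.T} != series T={series.n_timepoints}"
        )
    if scheme.length * series.tr_seconds < MIN_WINDOW_SECONDS:
        warnings.warn(
            f"window length {scheme.length} x TR {series.tr_seconds}s = "
            f"{scheme.length * series.tr_seconds:.0f}s < {MIN_WINDOW_SECONDS:.0f}s; "
            "window EC fluctuations may be spurious",
            stacklevel=2,
        )
    out = np.empty((series.n_voxels, scheme.n_windows))
    for j, s in enumerate(scheme.starts):
        sub = MaskedSeries(
            mask=series.mask,
            data=series.data[:, s : s + scheme.length],
            tr_seconds=series.tr_seconds,
        )
        try:
            out[:, j] = fast_ecm(zscore_rows(sub), tol=tol, max_iter=max_iter).values
        except Exception as exc:
            raise RuntimeError(
                f"ECM failed in window {j} (start {s}): {exc}"
            ) from exc
    return DynamicCentralitySeries(mask=series.mask, values=out, scheme=scheme)
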