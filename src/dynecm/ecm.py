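"""Matrix-free voxel-wise eigenvector centrality (ECM).

Eigenvector centrality scores a voxel highly when it is strongly connected to
other highly scored voxels: the score vector is the leading eigenvector of the
connectivity matrix.  Here connectivity is the voxel-by-voxel Pearson
correlation matrix ``C`` of the in-mask time series, mapped to
``A = (C + 1) / 2`` so that A is entrywise positive and the Perron-Frobenius
theorem guarantees a unique nonnegative leading eigenvector.

With row-z-scored data ``M`` (n_voxels x T), ``C = M M^T / (T - 1)``, so the
matrix-vector product needed by power iteration factors as

    A v = ( M (M^T v) / (T - 1) + 1 * sum(v) ) / 2

which never materialises the n x n correlation matrix — at ~50k grey-matter
voxels that matrix would not fit in memory, while the factored product costs
two skinny mat-vecs.  ``dense_ecm_oracle`` builds C explicitly and solves the
eigenproblem directly; it exists to cross-check the matrix-free path on small
problems and is memory-guarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_volumes import AnalysisMask, MaskedSeries

__all__ = [
    "CentralityMap",
    "ConvergenceError",
    "zscore_rows",
    "fast_ecm",
    "static_ecm",
    "dense_ecm_oracle",
]

DENSE_ORACLE_MAX_VOXELS = 3000


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass
class CentralityMap:
    """Unit-norm nonnegative eigenvector centrality over a mask."""

    mask: AnalysisMask
    values: np.ndarray  # n_voxels, >= 0, ||.||_2 = 1
    iterations: int
    residual: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.mask.n_voxels,):
            raise ValueError("values length must equal mask size")
        if (self.values < -1e-12).any():
            raise ValueError("centrality values must be nonnegative")
        nrm = np.linalg.norm(self.values)
        if abs(nrm - 1.0) > 1e-9:
            raise ValueError(f"values must have unit Euclidean norm, got {nrm}")


def zscore_rows(series: MaskedSeries) -> MaskedSeries:
    """Z-score each voxel's time series (mean 0, unit *sample* variance).

    With ddof=1 scaling, ``row_i . row_j / (T - 1)`` is exactly the Pearson
    correlation of the raw rows.  Constant rows cannot be z-scored; they are
    mapped to all-zero rows and flagged in ``zero_variance`` rather than
    raising — such voxels still take part in centrality through the +1
    offset of the connectivity transform.
    """
    data = series.data
    mean = data.mean(axis=1, keepdims=True)
    centered = data - mean
    sd = centered.std(axis=1, ddof=1, keepdims=True)
    flat = (sd[:, 0] == 0.0) | ~np.isfinite(sd[:, 0])
    safe = np.where(flat[:, None], 1.0, sd)
    z = centered / safe
    z[flat] = 0.0
    return MaskedSeries(
        mask=series.mask,
        data=z,
        tr_seconds=series.tr_seconds,
        zero_variance=flat,
    )


def _check_zscored(series: MaskedSeries) -> None:
    data = series.data
    mx = np.abs(data.mean(axis=1)).max()
    if mx > 1e-8:
        raise ValueError(
            "series must be row z-scored (use zscore_rows); "
            f"max |row mean| = {mx:.3g}"
        )


def fast_ecm(
    series: MaskedSeries,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> CentralityMap:
    """Power iteration for the leading eigenvector of A = (C + 1)/2.

    Expects a z-scored series.  Starts from the uniform positive vector
    1/sqrt(n) (any positive start converges to the Perron vector of a
    positive matrix; uniform makes the run deterministic).  Convergence is
    declared when the L2 difference of successive unit-norm iterates drops
    below ``tol``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    _check_zscored(series)
    M = series.data
    n, T = M.shape
    if n < 2:
        raise ValueError("need at least 2 voxels")
    row_norms = np.einsum("ij,ij->i", M, M)
    if (row_norms == 0).all():
        raise ValueError("all voxels have zero variance; no signal to analyse")

    v = np.full(n, 1.0 / np.sqrt(n))
    residual = np.inf
    for it in range(1, max_iter + 1):
        w = M @ (M.T @ v) / (T - 1)
        w = (w + v.sum()) / 2.0
        w /= np.linalg.norm(w)
        residual = float(np.linalg.norm(w - v))
        v = w
        if residual < tol:
            np.maximum(v, 0.0, out=v)
            v /= np.linalg.norm(v)
            return CentralityMap(
                mask=series.mask, values=v, iterations=it, residual=residual
            )
    raise ConvergenceError(
        f"power iteration did not converge in {max_iter} iterations "
        f"(last residual {residual:.3g})",
        residual=residual,
    )


def static_ecm(
    series: MaskedSeries, tol: float = 1e-9, max_iter: int = 1000
) -> CentralityMap:
    """Whole-series ("static") ECM of a raw series: z-score then fast_ecm."""
    return fast_ecm(zscore_rows(series), tol=tol, max_iter=max_iter)


def dense_ecm_oracle(series: MaskedSeries) -> CentralityMap:
    """Direct eigendecomposition of the materialised A = (C + 1)/2.

    Independent cross-check of :func:`fast_ecm`: builds the full correlation
    matrix, solves the symmetric eigenproblem, sign-fixes the leading
    eigenvector to the nonnegative orthant.  Guarded to small problems.
    """
    _check_zscored(series)
    M = series.data
    n, T = M.shape
    if n < 2:
        raise ValueError("need at least 2 voxels")
    if n > DENSE_ORACLE_MAX_VOXELS:
        raise MemoryError(
            f"dense oracle limited to {DENSE_ORACLE_MAX_VOXELS} voxels (got {n})"
        )
    C = (M @ M.T) / (T - 1)
    A = (C + 1.0) / 2.0
    eigvals, eigvecs = np.linalg.eigh(A)
    v = eigvecs[:, -1]
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    v /= np.linalg.norm(v)
    return CentralityMap(mask=series.mask, values=v, iterations=0, residual=0.0)
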