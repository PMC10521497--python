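"""Population-structure PCA on the genotype (co)variance matrix.

Missing calls are mean-imputed per marker, markers are mean-centred
(optionally scaled to unit variance), and the individuals x individuals
covariance matrix is eigen-decomposed.  Scores for component k are the
eigenvector scaled by sqrt(eigenvalue); the explained-variance fraction is
lambda_k over the sum of all eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MISSING, GenotypeDataset


@dataclass
class PCAResult:
    scores: np.ndarray  # (n_individuals, n_components)
    variance_fraction: np.ndarray  # (n_components,)
    n_components: int
    warnings: list[str]


def run_pca(
    ds: GenotypeDataset, n_components: int, scale: bool = False
) -> PCAResult:
    """Eigen-decomposition PCA over individuals.

    Parameters
    ----------
    ds : GenotypeDataset
        QC-filtered dataset.
    n_components : int
        Number of leading components to return; at most
        ``min(n_individuals, n_markers)``.
    scale : bool
        If True, standardise each marker to unit variance after centring
        (correlation-matrix PCA); default is covariance-matrix PCA.
    """
    n, m = ds.n_individuals, ds.n_markers
    if not (1 <= n_components <= min(n, m)):
        raise ValueError(
            f"n_components must be in [1, {min(n, m)}], got {n_components}"
        )

    x = ds.calls.astype(float)
    miss = x == MISSING
    x[miss] = np.nan
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    x = np.where(np.isnan(x), col_mean[None, :], x)
    x -= col_mean[None, :]
    if scale:
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x /= sd[None, :]

    cov = x @ x.T / max(m, 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)

    warnings: list[str] = []
    total = eigval.sum()
    if total <= 0:
        warnings.append(
            "all eigenvalues are zero (monomorphic dataset); scores are zero"
        )
        scores = np.zeros((n, n_components))
        var_frac = np.zeros(n_components)
        return PCAResult(scores, var_frac, n_components, warnings)

    var_frac = eigval[:n_components] / total
    scores = eigvec[:, :n_components] * np.sqrt(eigval[:n_components])[None, :]
    # deterministic sign: largest-magnitude entry of each component positive
    for k in range(n_components):
        col = scores[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            scores[:, k] = -col
    return PCAResult(scores, var_frac, n_components, warnings)
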