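"""Principal component analysis by explicit covariance eigendecomposition.

The model is fitted the classical way: mean vector m, population
covariance S = (1/N) * sum_n (x_n - m)(x_n - m)^T, and the eigenpairs of
S sorted by descending eigenvalue. Projection of x onto the first d
components is u_j^T (x - m), j = 1..d.

The population divisor N (not N-1) is deliberate: it matches the
covariance definition this pipeline standardizes on. Eigenvector signs
are pinned by flipping each vector so its largest-magnitude entry is
positive, making fitted models bit-reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PCAModel:
    mean: np.ndarray          # (K,)
    covariance: np.ndarray    # (K, K)
    eigenvalues: np.ndarray   # (K,), descending
    eigenvectors: np.ndarray  # (K, K), column j is u_j
    n_fit: int

    @property
    def K(self) -> int:
        return self.mean.shape[0]


def fit_pca(X: np.ndarray) -> PCAModel:
    """Fit a PCA model on the rows of X (n_fit x K).

    Raises ``ValueError`` on an empty matrix. A single row is allowed and
    yields a zero covariance with all-zero eigenvalues.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0 or X.shape[1] == 0:
        raise ValueError(f"need a nonempty 2-D matrix, got shape {X.shape}")
    n, k = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / n  # population divisor
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals, kind="stable")[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    # sign convention: largest-magnitude entry of each eigenvector positive
    idx = np.argmax(np.abs(evecs), axis=0)
    signs = np.sign(evecs[idx, np.arange(k)])
    signs[signs == 0] = 1.0
    evecs = evecs * signs
    return PCAModel(mean=mean, covariance=cov, eigenvalues=evals,
                    eigenvectors=evecs, n_fit=n)


def project(model: PCAModel, x: np.ndarray, d: int) -> np.ndarray:
    """Project x (a K-vector or an n x K matrix) onto the first d components."""
    if not 1 <= d <= model.K:
        raise ValueError(f"d must be in [1, {model.K}], got {d}")
    x = np.asarray(x, dtype=float)
    return (x - model.mean) @ model.eigenvectors[:, :d]


def save_model(model: PCAModel, path) -> None:
    """Dump mean, eigenvalues and eigenvectors as flat CSV blocks for audit."""
    with open(path, "w") as fh:
        fh.write("# mean\n")
        fh.write(",".join(f"{v:.17g}" for v in model.mean) + "\n")
        fh.write("# eigenvalues\n")
        fh.write(",".join(f"{v:.17g}" for v in model.eigenvalues) + "\n")
        fh.write("# eigenvectors (column j = component j, one row per line)\n")
        for row in model.eigenvectors:
            fh.write(",".join(f"{v:.17g}" for v in row) + "\n")
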