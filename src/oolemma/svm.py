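"""Soft-margin kernel SVM with the four classical kernels.

The discriminant is f(x) = sgn( sum_i w_i K(x, x_i) + b ) over the M
support vectors x_i, with signed dual weights w_i = alpha_i y_i and
threshold b. Kernels:

    linear      K(x1, x2) = x1 . x2
    rbf         K(x1, x2) = exp(-gamma ||x1 - x2||^2)
    polynomial  K(x1, x2) = (x1 . x2 + c)^d
    sigmoid     K(x1, x2) = tanh(b_slope * x1 . x2 + c)

Kernel evaluation and prediction are implemented here; the dual
quadratic program is solved by libsvm (scikit-learn's SVC with a
precomputed Gram matrix), a replaceable component behind this module's
train/predict contract. Tests cross-check predictions against an
independent from-scratch dual solver.

Defaults where the method leaves hyperparameters open: C = 1;
gamma and the sigmoid slope default to 1 / (n_features * var(X))
(the conventional "scale" heuristic); polynomial degree 3, coef 1;
sigmoid coef 0.

Label convention: ruptured is the positive class (+1); sgn(0) = +1, so
borderline cases err toward the clinically cautious call.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.svm import SVC

KERNEL_KINDS = ("linear", "rbf", "polynomial", "sigmoid")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and hyperparameters.

    ``gamma`` (rbf) and ``slope`` (sigmoid) may be left as ``None`` to be
    resolved from the training data as 1/(n_features * var). ``degree``
    is the polynomial exponent and ``coef`` the additive constant of the
    polynomial and sigmoid kernels.
    """

    kind: str = "linear"
    gamma: float | None = None
    degree: int = 3
    coef: float = 1.0
    slope: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind: {self.kind!r}")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.degree < 1:
            raise ValueError("polynomial degree must be >= 1")

    def resolved(self, X: np.ndarray) -> "KernelSpec":
        """Fill data-dependent defaults (gamma, slope) from training data."""
        scale = None
        if (self.kind == "rbf" and self.gamma is None) or (
            self.kind == "sigmoid" and self.slope is None
        ):
            var = float(np.asarray(X, dtype=float).var())
            scale = 1.0 / (X.shape[1] * var) if var > 0 else 1.0
        out = self
        if self.kind == "rbf" and self.gamma is None:
            out = replace(out, gamma=scale)
        if self.kind == "sigmoid" and self.slope is None:
            out = replace(out, slope=scale)
        return out


@dataclass(frozen=True)
class SVMModel:
    support_vectors: np.ndarray  # (M, d)
    weights: np.ndarray          # (M,), alpha_i * y_i
    threshold: float             # b
    kernel: KernelSpec

    @property
    def M(self) -> int:
        return self.support_vectors.shape[0]


def kernel_eval(spec: KernelSpec, x1: np.ndarray, x2: np.ndarray) -> float:
    """Evaluate the kernel on a single pair of vectors."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError(f"shape mismatch: {x1.shape} vs {x2.shape}")
    return float(gram(spec, x1[None, :], x2[None, :])[0, 0])


def gram(spec: KernelSpec, X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    """Kernel Gram matrix K[i, j] = K(X1[i], X2[j])."""
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError(f"feature-dimension mismatch: {X1.shape[1]} vs {X2.shape[1]}")
    dots = X1 @ X2.T
    if spec.kind == "linear":
        return dots
    if spec.kind == "rbf":
        if spec.gamma is None:
            raise ValueError("rbf gamma unresolved; call spec.resolved(X) first")
        sq = (
            np.sum(X1 * X1, axis=1)[:, None]
            - 2.0 * dots
            + np.sum(X2 * X2, axis=1)[None, :]
        )
        return np.exp(-spec.gamma * np.maximum(sq, 0.0))
    if spec.kind == "polynomial":
        return (dots + spec.coef) ** spec.degree
    if spec.kind == "sigmoid":
        if spec.slope is None:
            raise ValueError("sigmoid slope unresolved; call spec.resolved(X) first")
        return np.tanh(spec.slope * dots + spec.coef)
    raise AssertionError(spec.kind)


def train_svm(X: np.ndarray, y: np.ndarray, kernel: KernelSpec = KernelSpec(),
              C: float = 1.0) -> SVMModel:
    """Train a soft-margin SVM on labels in {-1, +1}.

    Raises ``ValueError`` for single-class input, non-finite features or
    fewer than two samples.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an n x d matrix with n >= 2")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    if set(np.unique(y)) != {-1, 1}:
        raise ValueError("labels must contain both classes, encoded as -1/+1")
    if C <= 0:
        raise ValueError("C must be positive")
    spec = kernel.resolved(X)
    K = gram(spec, X, X)
    clf = SVC(kernel="precomputed", C=C)
    clf.fit(K, y.astype(int))
    sv_idx = clf.support_
    # dual_coef_ holds alpha_i * y_i ordered like support_; classes_ is
    # [-1, 1] so the sign convention matches the +1-positive discriminant.
    weights = clf.dual_coef_.ravel().astype(float)
    return SVMModel(
        support_vectors=X[sv_idx].copy(),
        weights=weights,
        threshold=float(clf.intercept_[0]),
        kernel=spec,
    )


def decision_value(model: SVMModel, x: np.ndarray) -> np.ndarray:
    """sum_i w_i K(x, x_i) + b for one vector or a batch of rows."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.support_vectors.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} != model dimension "
            f"{model.support_vectors.shape[1]}"
        )
    vals = gram(model.kernel, X, model.support_vectors) @ model.weights + model.threshold
    return vals[0] if single else vals


def predict(model: SVMModel, x: np.ndarray) -> np.ndarray | int:
    """Sign of the discriminant; exactly zero maps to +1 (ruptured)."""
    vals = decision_value(model, x)
    labels = np.where(np.atleast_1d(vals) >= 0, 1, -1)
    return int(labels[0]) if np.ndim(vals) == 0 else labels


def save_model(model: SVMModel, path) -> None:
    """Audit dump: kernel parameters, threshold, and per-SV dual weights."""
    with open(path, "w") as fh:
        k = model.kernel
        fh.write(f"# kernel={k.kind} gamma={k.gamma} degree={k.degree} "
                 f"coef={k.coef} slope={k.slope} threshold={model.threshold:.17g}\n")
        fh.write("sv_index,weight," +
                 ",".join(f"x{j}" for j in range(model.support_vectors.shape[1])) + "\n")
        for i, (w, sv) in enumerate(zip(model.weights, model.support_vectors)):
            fh.write(f"{i},{w:.17g}," + ",".join(f"{v:.17g}" for v in sv) + "\n")
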