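"""Independent reference implementations used as test oracles.

These are deliberately naive and share no code with the package: a
per-pixel, per-bit LBP coder and a projected-gradient solver for the
soft-margin SVM dual. They exist so the vectorized/production paths can
be checked against something written from the definitions alone.
"""

from __future__ import annotations

import numpy as np

# same frozen neighbor enumeration as the package documents: clockwise
# from the top-left offset, bit i weighted 2**i
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]


def naive_lbp_code_map(frame: np.ndarray) -> np.ndarray:
    """Per-pixel, per-bit LBP (bit=1 iff neighbor - center >= 0)."""
    frame = np.asarray(frame).astype(int)
    h, w = frame.shape
    out = np.zeros((h - 2, w - 2), dtype=int)
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            code = 0
            for i, (dr, dc) in enumerate(_OFFSETS):
                if frame[r + dr, c + dc] - frame[r, c] >= 0:
                    code += 2 ** i
            out[r - 1, c - 1] = code
    return out


def reference_dual_svm(K: np.ndarray, y: np.ndarray, C: float,
                       n_iter: int = 20000, lr: float | None = None):
    """Solve the soft-margin dual by projected gradient ascent.

    maximize  sum(a) - 0.5 a^T (y y^T * K) a
    s.t.      0 <= a <= C,  a . y = 0

    Equality is maintained by projecting the gradient onto the
    constraint plane and clipping to the box, with a final exact
    projection step. Returns (alpha, b).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    Q = (y[:, None] * y[None, :]) * K
    if lr is None:
        lr = 1.0 / (np.linalg.norm(Q, 2) + 1.0)
    a = np.full(n, min(C, 1.0) * 0.5)
    a -= y * (a @ y) / n  # start on the equality plane
    a = np.clip(a, 0, C)
    for _ in range(n_iter):
        grad = 1.0 - Q @ a
        grad -= y * (grad @ y) / n  # stay on the plane
        a_new = np.clip(a + lr * grad, 0, C)
        # clipping can leave the plane; pull back along y among free coords
        drift = a_new @ y
        free = (a_new > 1e-12) & (a_new < C - 1e-12)
        if free.any():
            a_new[free] -= y[free] * drift / free.sum()
            a_new = np.clip(a_new, 0, C)
        if np.max(np.abs(a_new - a)) < 1e-12:
            a = a_new
            break
        a = a_new
    # threshold from margin support vectors (0 < alpha < C)
    f_no_b = (a * y) @ K
    margin = (a > 1e-6 * C) & (a < C * (1 - 1e-6))
    if margin.any():
        b = float(np.mean(y[margin] - f_no_b[margin]))
    else:
        sv = a > 1e-8
        b = float(np.mean(y[sv] - f_no_b[sv])) if sv.any() else 0.0
    return a, b


def reference_predict(Xtr: np.ndarray, ytr: np.ndarray, alpha: np.ndarray,
                      b: float, kernel_fn, Xte: np.ndarray) -> np.ndarray:
    K = kernel_fn(Xte, Xtr)
    vals = K @ (alpha * ytr) + b
    return np.where(vals >= 0, 1, -1)
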