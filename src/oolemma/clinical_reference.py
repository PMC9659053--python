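"""Published per-cell results of the original 93-oocyte clinical evaluation.

The clinical movie dataset behind the original study of this pipeline is
not publicly deposited, so its per-cell results cannot be recomputed
here. What *can* be recomputed is the aggregation bookkeeping built on
top of them: the published report lists, for the polynomial kernel at
two and three sampling frames, the classification accuracy at every
dimensionality from 1 to 11, together with per-row means, sample
standard deviations and the "amount of change" between consecutive
rows. The per-cell accuracies below are transcribed input data for that
arithmetic; they are not outputs of this package.
"""

from __future__ import annotations

from .evaluation import GridCell

#: Accuracy (%) of the polynomial kernel, dimensionality 1..11, as published.
POLYNOMIAL_ACCURACY = {
    2: [65.05, 73.12, 76.88, 77.96, 82.26, 85.48, 90.32, 86.56, 89.78, 89.25, 90.32],
    3: [63.80, 75.99, 77.06, 78.49, 84.23, 85.66, 85.66, 89.25, 91.40, 89.25, 87.10],
}

#: Published headline: best accuracy 91.4% at 3 sampling frames, dimensionality 9.
BEST_ACCURACY = 91.40
BEST_N_SAMPLES = 3
BEST_DIMENSIONALITY = 9


def reference_cells(n_samples: int) -> list[GridCell]:
    """The published polynomial column as GridCell inputs for aggregation."""
    accs = POLYNOMIAL_ACCURACY[n_samples]
    return [
        GridCell(kernel="polynomial", n_samples=n_samples, dimensionality=d,
                 confusion=None, accuracy=a, sensitivity=float("nan"),
                 specificity=float("nan"))
        for d, a in zip(range(1, 12), accs)
    ]
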