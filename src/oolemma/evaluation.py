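"""Leave-one-oocyte-out evaluation of the LBP -> PCA -> SVM pipeline.

One evaluation cell fixes a kernel, a number of sampling frames
(1-5 frames taken strictly before the reference frame at a stride of 6)
and a PCA dimensionality (1-11). For each fold, every frame of one
oocyte is held out; the LBP histograms of all remaining oocytes' sampled
frames fit the PCA basis and train the SVM, and each held-out frame is
predicted individually. Frame-level outcomes accumulate into a single
confusion matrix per cell, from which accuracy, sensitivity and
specificity are derived as percentages. With one sampling frame this
reduces to ordinary leave-one-out cross-validation.

Fitting the PCA basis on the training folds only (the default) keeps the
held-out oocyte out of the transform; a ``pca_scope="all"`` flag exists
for comparison runs.

The grid sweep (4 kernels x 5 sampling-frame counts x 11
dimensionalities = 220 cells) shares feature extraction and per-fold PCA
fits across cells, which changes nothing numerically: features depend
only on the frame set, and the eigenbasis of the training covariance
does not depend on how many leading components are later retained.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from . import frame_io, lbp, pca, svm
from .frame_io import FrameSequence, RoiSpec

KERNELS = ("linear", "rbf", "polynomial", "sigmoid")
DEFAULT_N_SAMPLES_RANGE = tuple(range(1, 6))
DEFAULT_DIMS_RANGE = tuple(range(1, 12))

#: Called once per fold with (training oocyte ids, held-out oocyte ids);
#: used to audit the leakage guarantee.
FoldHook = Callable[[set, set], None]


class AggregationError(ValueError):
    """Grid incomplete for the requested grouping."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """Frame-level 2x2 outcome tally; ruptured is the positive class."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)

    def as_table(self) -> np.ndarray:
        """Rows = true class (ruptured, nonruptured); columns = predicted."""
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


@dataclass(frozen=True)
class GridCell:
    kernel: str
    n_samples: int
    dimensionality: int
    confusion: ConfusionMatrix | None
    accuracy: float      # unrounded percentage
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class AggregateRow:
    group_key: int
    mean: dict            # kernel -> unrounded mean accuracy (%)
    sd: dict              # kernel -> sample SD (divisor n-1)
    change: dict          # kernel -> mean - previous group's mean, or None


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline holds fixed across a run."""

    roi: RoiSpec | None = None          # None -> centered default-size crop
    interval: int = frame_io.DEFAULT_INTERVAL
    lbp: lbp.LBPConfig = field(default_factory=lbp.LBPConfig)
    C: float = 1.0
    degree: int = 3
    coef: float = 1.0
    gamma: float | None = None          # None -> 1/(n_features * var)
    slope: float | None = None
    pca_scope: str = "train"            # or "all" (leaks the test oocyte)
    feature_scaling: str = "norm"       # or "none"

    def kernel_spec(self, kind: str) -> svm.KernelSpec:
        return svm.KernelSpec(kind=kind, gamma=self.gamma, degree=self.degree,
                              coef=self.coef, slope=self.slope)

    def resolve_roi(self, frame_shape: tuple[int, int]) -> RoiSpec:
        if self.roi is not None:
            return self.roi
        h, w = frame_shape
        return RoiSpec.centered(h, w,
                                width=min(frame_io.DEFAULT_ROI_WIDTH, w),
                                height=min(frame_io.DEFAULT_ROI_HEIGHT, h))


def _norm_scale(Xtr: np.ndarray) -> float:
    """Root-mean-square row norm of the training block.

    Density LBP histograms (and their PCA projections) have norms of
    order 1e-2, which makes the additive constant of the polynomial and
    sigmoid kernels dominate the data term and makes C=1 act as extreme
    regularization. Dividing train and test features by this single
    scalar — fitted on the training fold only — fixes the units without
    altering the geometry the PCA established.
    """
    s = float(np.sqrt((Xtr ** 2).sum(axis=1).mean()))
    return s if s > 0 else 1.0


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding used for all displayed percentages."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return math.nan
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(accuracy %, sensitivity %, specificity %) to two decimals.

    A zero denominator yields NaN for the affected ratio rather than an
    exception, so degenerate cells surface in reports as blanks.
    """
    acc, sens, spec = raw_metrics(cm)
    return round_half_up(acc), round_half_up(sens), round_half_up(spec)


def raw_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """Unrounded percentage metrics (NaN on a zero denominator)."""
    acc = 100.0 * (cm.tp + cm.tn) / cm.total if cm.total else math.nan
    sens = 100.0 * cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else math.nan
    spec = 100.0 * cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) else math.nan
    return acc, sens, spec


def chi_square_test(cm: ConfusionMatrix) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2 table.

    Returns (statistic, p); (nan, nan) when a margin is zero and the test
    is undefined.
    """
    table = cm.as_table()
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return math.nan, math.nan
    stat, p, _, _ = chi2_contingency(table, correction=False)
    return float(stat), float(p)


def count_feature_instances(
    n_oocytes: int,
    n_samples_range: Sequence[int] = DEFAULT_N_SAMPLES_RANGE,
    dims_range: Sequence[int] = DEFAULT_DIMS_RANGE,
) -> int:
    """Dry-run enumerator of the maximal feature-instance count of a sweep.

    The sweep's maximal data set is |oocytes| x max(sampling frames) x
    max(dimensionality): with the 93-oocyte cohort and full ranges,
    93 x 5 x 11 = 5115.
    """
    return n_oocytes * max(n_samples_range) * max(dims_range)


# ---------------------------------------------------------------------------
# feature extraction


def extract_features(
    dataset: Sequence[FrameSequence],
    n_samples: int,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """LBP feature matrix for the sampled frames of every oocyte.

    Returns ``(X, y, groups)``: X is (n_oocytes * n_samples, 256), y holds
    +/-1 frame labels, groups the oocyte index of each row. Rows of one
    oocyte are contiguous and in chronological frame order.
    """
    rows, ys, groups = [], [], []
    for g, seq in enumerate(dataset):
        roi = config.resolve_roi(seq.frames[0].shape)
        for frame in frame_io.sample_frames(seq, n_samples, config.interval):
            hist = lbp.frame_features(frame_io.crop_roi(frame, roi), config.lbp)
            rows.append(hist.bins)
            ys.append(seq.y)
            groups.append(g)
    return np.asarray(rows), np.asarray(ys), np.asarray(groups)


def features_frame(
    dataset: Sequence[FrameSequence],
    n_samples: int,
    config: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Feature matrix as a DataFrame (oocyte_id, label, frame_index, f0..f255)."""
    records = []
    for seq in dataset:
        roi = config.resolve_roi(seq.frames[0].shape)
        idxs = frame_io.sample_indices(seq.reference_frame, n_samples, config.interval)
        for i in idxs:
            if i < 0:
                raise frame_io.SamplingError(
                    f"oocyte {seq.oocyte_id}: sequence too short for "
                    f"{n_samples} samples at stride {config.interval}"
                )
            hist = lbp.frame_features(frame_io.crop_roi(seq.frames[i], roi),
                                      config.lbp, (seq.oocyte_id, i))
            rec = {"oocyte_id": seq.oocyte_id, "label": seq.label, "frame_index": i}
            rec.update({f"f{j}": v for j, v in enumerate(hist.bins)})
            records.append(rec)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# cross-validation


def _confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == -1) & (y_pred == -1))),
        fp=int(np.sum((y_true == -1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == -1))),
    )


def _fit_predict(Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray,
                 spec: svm.KernelSpec, C: float) -> np.ndarray:
    """Train on a fold and predict; a single-class training fold (possible
    only in degenerate cohorts with one oocyte of a class) yields a constant
    classifier predicting that class."""
    classes = np.unique(ytr)
    if len(classes) == 1:
        return np.full(len(Xte), int(classes[0]))
    model = svm.train_svm(Xtr, ytr, spec, C=C)
    return np.atleast_1d(svm.predict(model, Xte))


def leave_one_oocyte_out(
    dataset: Sequence[FrameSequence],
    n_samples: int,
    dimensionality: int,
    kernel: str | svm.KernelSpec,
    config: PipelineConfig = PipelineConfig(),
    fold_hook: FoldHook | None = None,
) -> ConfusionMatrix:
    """Grouped cross-validation of a single (kernel, frames, dims) cell.

    Every fold excludes all sampled frames of one oocyte from LBP->PCA
    fitting and SVM training, then predicts each of that oocyte's frames
    individually.
    """
    labels = {seq.label for seq in dataset}
    if labels != set(frame_io.LABELS):
        raise ValueError("need at least one oocyte of each class")
    X, y, groups = extract_features(dataset, n_samples, config)
    spec = kernel if isinstance(kernel, svm.KernelSpec) else config.kernel_spec(kernel)
    ids = [seq.oocyte_id for seq in dataset]
    cm = ConfusionMatrix()
    model_all = pca.fit_pca(X) if config.pca_scope == "all" else None
    for g in range(len(dataset)):
        test = groups == g
        train = ~test
        if fold_hook is not None:
            fold_hook({ids[i] for i in set(groups[train])},
                      {ids[i] for i in set(groups[test])})
        pmodel = model_all if model_all is not None else pca.fit_pca(X[train])
        Xtr = pca.project(pmodel, X[train], dimensionality)
        Xte = pca.project(pmodel, X[test], dimensionality)
        if config.feature_scaling == "norm":
            s = _norm_scale(Xtr)
            Xtr, Xte = Xtr / s, Xte / s
        y_pred = _fit_predict(Xtr, y[train], Xte, spec, config.C)
        cm = cm + _confusion_from_predictions(y[test], y_pred)
    return cm


def _cell(kernel: str, n_samples: int, d: int, cm: ConfusionMatrix) -> GridCell:
    acc, sens, spec = raw_metrics(cm)
    return GridCell(kernel=kernel, n_samples=n_samples, dimensionality=d,
                    confusion=cm, accuracy=acc, sensitivity=sens, specificity=spec)


def grid_search(
    dataset: Sequence[FrameSequence],
    n_samples_range: Sequence[int] = DEFAULT_N_SAMPLES_RANGE,
    dims_range: Sequence[int] = DEFAULT_DIMS_RANGE,
    kernels: Sequence[str] = KERNELS,
    config: PipelineConfig = PipelineConfig(),
    fold_hook: FoldHook | None = None,
) -> list[GridCell]:
    """Sweep every (kernel, sampling frames, dimensionality) combination.

    Numerically identical to calling :func:`leave_one_oocyte_out` per
    cell; feature extraction and per-fold PCA fits are shared across
    cells for speed (the smaller frame sets are suffixes of the largest
    one, and the eigenbasis does not depend on the retained dimension).
    """
    labels = {seq.label for seq in dataset}
    if labels != set(frame_io.LABELS):
        raise ValueError("need at least one oocyte of each class")
    max_n = max(n_samples_range)
    max_d = max(dims_range)
    X_full, y_full, groups = extract_features(dataset, max_n, config)
    ids = [seq.oocyte_id for seq in dataset]
    n_oocytes = len(dataset)
    cells: dict[tuple[str, int, int], ConfusionMatrix] = {
        (k, n, d): ConfusionMatrix()
        for k in kernels for n in n_samples_range for d in dims_range
    }
    for n_samples in sorted(n_samples_range):
        # frames for n samples are the last n of the max_n sampled frames
        keep = np.zeros(len(X_full), dtype=bool)
        for g in range(n_oocytes):
            rows = np.flatnonzero(groups == g)
            keep[rows[max_n - n_samples :]] = True
        X, y, grp = X_full[keep], y_full[keep], groups[keep]
        model_all = pca.fit_pca(X) if config.pca_scope == "all" else None
        for g in range(n_oocytes):
            test = grp == g
            train = ~test
            if fold_hook is not None:
                fold_hook({ids[i] for i in set(grp[train])},
                          {ids[i] for i in set(grp[test])})
            pmodel = model_all if model_all is not None else pca.fit_pca(X[train])
            Ptr = pca.project(pmodel, X[train], max_d)
            Pte = pca.project(pmodel, X[test], max_d)
            scales = {d: (_norm_scale(Ptr[:, :d])
                          if config.feature_scaling == "norm" else 1.0)
                      for d in dims_range}
            for kind in kernels:
                spec = config.kernel_spec(kind)
                for d in dims_range:
                    s = scales[d]
                    y_pred = _fit_predict(Ptr[:, :d] / s, y[train],
                                          Pte[:, :d] / s, spec, config.C)
                    key = (kind, n_samples, d)
                    cells[key] = cells[key] + _confusion_from_predictions(y[test], y_pred)
    return [_cell(k, n, d, cm) for (k, n, d), cm in cells.items()]


def best_cell(cells: Iterable[GridCell]) -> GridCell:
    """Cell with the highest accuracy (first encountered wins ties)."""
    return max(cells, key=lambda c: (c.accuracy if not math.isnan(c.accuracy) else -1.0))


# ---------------------------------------------------------------------------
# aggregation (mean / sample SD / amount of change)


def _aggregate(cells: Sequence[GridCell], group_attr: str,
               other_attr: str) -> list[AggregateRow]:
    kernels = sorted({c.kernel for c in cells}, key=KERNELS.index)
    groups = sorted({getattr(c, group_attr) for c in cells})
    others = sorted({getattr(c, other_attr) for c in cells})
    table: dict[tuple[str, int], list[GridCell]] = {}
    for c in cells:
        table.setdefault((c.kernel, getattr(c, group_attr)), []).append(c)
    missing = []
    for k in kernels:
        for g in groups:
            got = {getattr(c, other_attr) for c in table.get((k, g), [])}
            missing += [f"{k}/{group_attr}={g}/{other_attr}={o}"
                        for o in others if o not in got]
    if missing:
        raise AggregationError("incomplete grid, missing cells: " + ", ".join(missing))
    rows: list[AggregateRow] = []
    prev_mean: dict[str, float] = {}
    for g in groups:
        mean, sd, change = {}, {}, {}
        for k in kernels:
            vals = np.array([c.accuracy for c in
                             sorted(table[(k, g)], key=lambda c: getattr(c, other_attr))])
            mean[k] = float(vals.mean())
            sd[k] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            change[k] = mean[k] - prev_mean[k] if k in prev_mean else None
            prev_mean[k] = mean[k]
        rows.append(AggregateRow(group_key=g, mean=mean, sd=sd, change=change))
    return rows


def aggregate_by_frames(cells: Sequence[GridCell]) -> list[AggregateRow]:
    """Per sampling-frame count and kernel: mean accuracy over the
    dimensionality axis, sample SD (divisor n-1), and the change from the
    previous row's unrounded mean."""
    return _aggregate(cells, "n_samples", "dimensionality")


def aggregate_by_dimensionality(cells: Sequence[GridCell]) -> list[AggregateRow]:
    """Per dimensionality and kernel: mean accuracy over the sampling-frame
    axis, sample SD, and the change from the previous row."""
    return _aggregate(cells, "dimensionality", "n_samples")


# ---------------------------------------------------------------------------
# reports


def cells_frame(cells: Sequence[GridCell]) -> pd.DataFrame:
    """Per-cell report with displayed metrics rounded half-up to 2 decimals."""
    recs = []
    for c in sorted(cells, key=lambda c: (KERNELS.index(c.kernel),
                                          c.n_samples, c.dimensionality)):
        cm = c.confusion or ConfusionMatrix()
        recs.append({
            "kernel": c.kernel, "sampling_frames": c.n_samples,
            "dimensionality": c.dimensionality,
            "TP": cm.tp, "TN": cm.tn, "FP": cm.fp, "FN": cm.fn,
            "accuracy": round_half_up(c.accuracy),
            "sensitivity": round_half_up(c.sensitivity),
            "specificity": round_half_up(c.specificity),
        })
    return pd.DataFrame.from_records(recs)


def aggregate_frame(rows: Sequence[AggregateRow], group_name: str) -> pd.DataFrame:
    recs = []
    for row in rows:
        rec = {group_name: row.group_key}
        for k in row.mean:
            rec[f"{k}_mean"] = round_half_up(row.mean[k])
            rec[f"{k}_sd"] = round_half_up(row.sd[k])
            rec[f"{k}_change"] = (round_half_up(row.change[k])
                                  if row.change[k] is not None else "")
        recs.append(rec)
    return pd.DataFrame.from_records(recs)


def write_reports(cells: Sequence[GridCell], outdir: str | Path,
                  config: PipelineConfig = PipelineConfig(),
                  seed: int | None = None) -> dict[str, Path]:
    """Emit table1/table2/table3 CSVs, per-cell confusion matrices and a run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["table1"] = outdir / "table1.csv"
    cells_frame(cells).to_csv(paths["table1"], index=False)
    paths["table2"] = outdir / "table2.csv"
    aggregate_frame(aggregate_by_frames(cells), "sampling_frames").to_csv(
        paths["table2"], index=False)
    paths["table3"] = outdir / "table3.csv"
    aggregate_frame(aggregate_by_dimensionality(cells), "dimensionality").to_csv(
        paths["table3"], index=False)
    confdir = outdir / "confusion"
    confdir.mkdir(exist_ok=True)
    for c in cells:
        if c.confusion is None:
            continue
        cm = c.confusion
        p = confdir / f"{c.kernel}_f{c.n_samples}_d{c.dimensionality}.csv"
        pd.DataFrame([[cm.tp, cm.fn], [cm.fp, cm.tn]],
                     index=["true_ruptured", "true_nonruptured"],
                     columns=["pred_ruptured", "pred_nonruptured"]).to_csv(p)
    cfg_text = repr(config)
    log = {
        "config": cfg_text,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": seed,
        "n_cells": len(cells),
    }
    paths["log"] = outdir / "run_log.json"
    paths["log"].write_text(json.dumps(log, indent=2))
    return paths
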