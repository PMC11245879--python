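"""Confusion counting, classification metrics, grid search and learning curve.

Metrics follow the standard screening definitions: sensitivity TP/(TP+FN),
specificity TN/(TN+FP), PPV TP/(TP+FP), NPV TN/(TN+FN), accuracy
(TP+TN)/(TP+TN+FP+FN), F1 = 2*PPV*Sen/(PPV+Sen), and AUC as the probability
that a random positive outscores a random negative (ties counted half),
computed by the rank method.  Multi-class masks are scored one-vs-rest per
class and macro-averaged; a metric whose denominator is zero is flagged
undefined (NaN) and excluded from the macro average rather than silently
substituted.

The hyperparameter grid couples the spatial window size WS (1, 3, 5, 7, 9,
11, 13) with the spatial-spectral-neighbor count (2, 4, ..., 16); every cell
retrains the classifier from the same master seed so the whole table is
reproducible.  The learning curve retrains over growing labeled-image
budgets and reports mean +/- SD test accuracy over seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import HSCube, LabelMask, PipelineConfig
from .scnn import (
    ClassifierSpec,
    SCNNClassifier,
    build_classifier,
    train_classifier,
)
from .sscd import augment_training_set, extract_window, make_pixel_samples
from .synthgen import SynthParams, generate_cube, sample_labeled_pixels

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "GridResult",
    "DEFAULT_WS_GRID",
    "DEFAULT_SSN_GRID",
    "DEFAULT_SAMPLE_SIZES",
    "confusion",
    "compute_metrics",
    "roc_auc",
    "evaluate_masks",
    "overall_accuracy",
    "split_stratified",
    "grid_search",
    "SCNNAdapter",
    "learning_curve",
]

DEFAULT_WS_GRID = (1, 3, 5, 7, 9, 11, 13)
DEFAULT_SSN_GRID = (2, 4, 6, 8, 10, 12, 14, 16)
DEFAULT_SAMPLE_SIZES = (20, 30, 40, 50, 60, 70, 80, 90, 100)

METRIC_NAMES = ("acc", "sen", "spe", "ppv", "npv", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest tally for a single positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _labels(mask) -> np.ndarray:
    return mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)


def confusion(pred, truth, positive_class: int) -> ConfusionCounts:
    """Exhaustive one-vs-rest tally of a predicted vs. true label array."""
    p, t = _labels(pred), _labels(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    pp = p == positive_class
    tp_ = t == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pp & tp_)),
        tn=int(np.sum(~pp & ~tp_)),
        fp=int(np.sum(pp & ~tp_)),
        fn=int(np.sum(~pp & tp_)),
    )


def compute_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Scalar metric suite from one confusion tally.

    Returns a dict with keys acc, sen, spe, ppv, npv, f1; a metric whose
    denominator vanishes is NaN (undefined), never zero-filled.
    """

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    acc = ratio(counts.tp + counts.tn, counts.total)
    sen = ratio(counts.tp, counts.tp + counts.fn)
    spe = ratio(counts.tn, counts.tn + counts.fp)
    ppv = ratio(counts.tp, counts.tp + counts.fp)
    npv = ratio(counts.tn, counts.tn + counts.fn)
    if np.isnan(ppv) or np.isnan(sen) or (ppv + sen) == 0:
        f1 = float("nan")
    else:
        f1 = 2.0 * ppv * sen / (ppv + sen)
    return {"acc": acc, "sen": sen, "spe": spe, "ppv": ppv, "npv": npv, "f1": f1}


def roc_auc(scores, truth) -> float:
    """AUC by the rank (Mann-Whitney) method.

    Equals the probability that a uniformly random positive sample receives a
    strictly higher score than a uniformly random negative one, with ties
    counted one half — and hence is invariant under strictly monotone
    transforms of the scores.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    truth = np.asarray(truth).ravel().astype(bool)
    if scores.shape != truth.shape:
        raise ValueError("scores/labels length mismatch")
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative sample")
    ranks = rankdata(scores)
    return float((ranks[truth].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def overall_accuracy(pred, truth) -> float:
    """Fraction of positions whose predicted class equals the true class."""
    p, t = _labels(pred), _labels(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    return float(np.mean(p == t))


@dataclass
class MetricsReport:
    """Per-class and macro-averaged metrics with full provenance echo.

    ``per_class`` maps class index to its metric dict (NaN = undefined);
    ``macro`` averages each metric over the classes where it is defined.
    ``overall_acc`` is the plain multi-class fraction-correct.
    """

    per_class: dict[int, dict[str, float]]
    macro: dict[str, float]
    overall_acc: float
    counts: dict[int, ConfusionCounts]
    config_echo: dict = field(default_factory=dict)

    def to_rows(self):
        yield ("overall_acc", self.overall_acc)
        for name, val in self.macro.items():
            yield (f"macro.{name}", val)
        for klass in sorted(self.per_class):
            for name, val in self.per_class[klass].items():
                yield (f"class{klass}.{name}", val)
            c = self.counts[klass]
            for cname in ("tp", "tn", "fp", "fn"):
                yield (f"class{klass}.{cname}", getattr(c, cname))


def evaluate_masks(
    pred,
    truth,
    scores: np.ndarray | None = None,
    classes: tuple[int, ...] = (0, 1, 2),
    config_echo: dict | None = None,
) -> MetricsReport:
    """Score a predicted mask against ground truth, one-vs-rest per class.

    ``scores``, if given, is an H x W x n_classes probability array from
    which per-class AUC is computed (skipped for classes absent from the
    truth or covering it entirely).
    """
    per_class: dict[int, dict[str, float]] = {}
    counts: dict[int, ConfusionCounts] = {}
    t = _labels(truth)
    for klass in classes:
        c = confusion(pred, truth, klass)
        m = compute_metrics(c)
        if scores is not None:
            binary = (t == klass).ravel()
            if 0 < binary.sum() < binary.size:
                m["auc"] = roc_auc(scores[..., klass].ravel(), binary)
            else:
                m["auc"] = float("nan")
        per_class[klass] = m
        counts[klass] = c
    names = list(next(iter(per_class.values())).keys())
    macro = {}
    for name in names:
        vals = [per_class[k][name] for k in classes if not np.isnan(per_class[k][name])]
        macro[name] = float(np.mean(vals)) if vals else float("nan")
    return MetricsReport(
        per_class=per_class,
        macro=macro,
        overall_acc=overall_accuracy(pred, truth),
        counts=counts,
        config_echo=config_echo or {},
    )


# --------------------------------------------------------------------------
# protocols: stratified split, grid search, learning curve
# --------------------------------------------------------------------------

def split_stratified(
    labeled: list[tuple[int, int, int]], seed: int, train_frac: float = 0.5
) -> tuple[list[tuple[int, int, int]], list[tuple[int, int, int]]]:
    """Per-class random split of sparse labels into train/test halves."""
    rng = np.random.default_rng(seed)
    train: list[tuple[int, int, int]] = []
    test: list[tuple[int, int, int]] = []
    by_class: dict[int, list[tuple[int, int, int]]] = {}
    for item in labeled:
        by_class.setdefault(item[2], []).append(item)
    for klass in sorted(by_class):
        items = by_class[klass]
        perm = rng.permutation(len(items))
        n_train = max(1, int(round(train_frac * len(items)))) if len(items) > 1 else 1
        for j, i in enumerate(perm):
            (train if j < n_train else test).append(items[i])
    return train, test


def _predict_positions(
    model: SCNNClassifier,
    cube: HSCube,
    positions: list[tuple[int, int]],
    ws: int,
) -> np.ndarray:
    patches = np.stack(
        [extract_window(cube, pos, ws).data.transpose(2, 0, 1) for pos in positions]
    )
    return model.predict(patches)


@dataclass
class GridResult:
    """Accuracy table over the WS x SSN grid plus its best cell."""

    table: pd.DataFrame  # index ws, columns k_ssn
    best_ws: int
    best_k: int
    best_acc: float
    seed: int

    def __post_init__(self) -> None:
        best = self.table.loc[self.best_ws, self.best_k]
        if not np.isclose(best, np.nanmax(self.table.to_numpy())):
            raise ValueError("best cell does not attain the table maximum")


def _train_eval_cell(
    cube: HSCube,
    train_labels: list[tuple[int, int, int]],
    test_labels: list[tuple[int, int, int]],
    ws: int,
    k: int,
    config: PipelineConfig,
) -> float:
    """Augment -> train -> held-out pixel accuracy, for one grid cell."""
    samples = make_pixel_samples(cube, train_labels, ws)
    augmented = augment_training_set(cube, samples, ws, k)
    test_positions = {(r, c) for r, c, _ in test_labels}
    augmented = [
        s
        for s in augmented
        if s.provenance == "original" or s.position not in test_positions
    ]
    spec = ClassifierSpec.for_patch(
        ws, cube.band_count, config.block_channels, config.kernel
    )
    model = build_classifier(spec, seed=config.seed)
    train_classifier(model, augmented, config.replace(ws=ws, k_ssn=k))
    preds = _predict_positions(model, cube, [(r, c) for r, c, _ in test_labels], ws)
    return float(np.mean(preds == np.array([lab for _, _, lab in test_labels])))


def grid_search(
    cube: HSCube,
    labeled: list[tuple[int, int, int]],
    ws_list: tuple[int, ...] = DEFAULT_WS_GRID,
    ssn_list: tuple[int, ...] = DEFAULT_SSN_GRID,
    config: PipelineConfig | None = None,
) -> GridResult:
    """Retrain and score the classifier for every (WS, SSN-count) pair.

    Labeled pixels are split stratified 50/50 by the master seed once; every
    cell trains on the same half (after its own SSN augmentation) and is
    scored on the other half.  A cell whose training fails is recorded as
    NaN.  Ties for the best cell break toward the smallest WS, then the
    smallest SSN count.
    """
    if not ws_list or not ssn_list:
        raise ValueError("grids must be non-empty")
    config = config or PipelineConfig()
    train_labels, test_labels = split_stratified(labeled, config.seed)
    if not test_labels:
        raise ValueError("too few labeled pixels to hold out a test half")
    table = pd.DataFrame(
        np.full((len(ws_list), len(ssn_list)), np.nan),
        index=pd.Index(ws_list, name="ws"),
        columns=pd.Index(ssn_list, name="k_ssn"),
    )
    for ws in ws_list:
        for k in ssn_list:
            try:
                table.loc[ws, k] = _train_eval_cell(
                    cube, train_labels, test_labels, ws, k, config
                )
            except Exception as exc:  # a failed cell must not kill the sweep
                import logging

                logging.getLogger("hypercell").warning(
                    "grid cell ws=%d k=%d failed: %s", ws, k, exc
                )
    arr = table.to_numpy()
    if np.all(np.isnan(arr)):
        raise RuntimeError("every grid cell failed")
    best_acc = np.nanmax(arr)
    for ws in ws_list:  # row-major scan gives smallest-ws, smallest-k tie-break
        for k in ssn_list:
            if np.isclose(table.loc[ws, k], best_acc, equal_nan=False):
                return GridResult(table, ws, k, float(best_acc), config.seed)
    raise AssertionError("unreachable: max not found in table")


class SCNNAdapter:
    """Default classifier adapter wrapping the separable CNN.

    Any object with the same ``fit(x, y, seed)`` / ``predict(x)`` surface —
    e.g. a wrapper around an off-the-shelf deep model — can be passed to
    ``learning_curve`` in its place.
    """

    def __init__(self, config: PipelineConfig, bands: int):
        self.config = config
        self.bands = bands
        self.model: SCNNClassifier | None = None

    def fit(self, x: np.ndarray, y: np.ndarray, seed: int) -> None:
        spec = ClassifierSpec.for_patch(
            self.config.ws, self.bands, self.config.block_channels, self.config.kernel
        )
        self.model = build_classifier(spec, seed=seed)
        self.model.fit(x, y, self.config.replace(seed=seed))

    def predict(self, x: np.ndarray) -> np.ndarray:
        assert self.model is not None, "fit before predict"
        return self.model.predict(x)


def learning_curve(
    sample_sizes: tuple[int, ...] = DEFAULT_SAMPLE_SIZES,
    task: SynthParams | None = None,
    n_seeds: int = 5,
    adapter_factory=None,
    config: PipelineConfig | None = None,
    pixels_per_image: int = 1,
    n_test_images: int = 8,
    test_pixels_per_image: int = 15,
) -> pd.DataFrame:
    """Test accuracy versus labeled-image budget, averaged over seeds.

    A "sample" is one labeled image contributing ``pixels_per_image`` labeled
    pixels per class; for each replicate seed, ``max(sample_sizes)`` training
    images and ``n_test_images`` held-out images are generated from ``task``
    (fresh noise and cell layout per image), the classifier is retrained at
    every budget on the first ``size`` images, and accuracy is measured on
    the held-out images' pixels.  Returns a frame indexed by size with
    columns mean_acc, sd_acc and one acc_seed<i> column per replicate.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    if not sample_sizes:
        raise ValueError("sample_sizes must be non-empty")
    sizes = sorted(int(s) for s in sample_sizes)
    task = task or SynthParams()
    config = config or PipelineConfig(ws=5, k_ssn=0)
    n_train = max(sizes)
    accs = np.zeros((len(sizes), n_seeds))
    base = np.random.SeedSequence(config.seed)
    child_seeds = [int(s) for s in base.generate_state(n_seeds * (n_train + n_test_images + 1)) >> 1]
    ptr = 0
    for rep in range(n_seeds):
        train_sets = []
        for i in range(n_train):
            cube, mask = generate_cube(task.replace(seed=child_seeds[ptr]))
            labels = sample_labeled_pixels(
                mask, pixels_per_image, seed=child_seeds[ptr]
            )
            ptr += 1
            train_sets.append((cube, labels))
        test_x, test_y = [], []
        for i in range(n_test_images):
            cube, mask = generate_cube(task.replace(seed=child_seeds[ptr]))
            labels = sample_labeled_pixels(
                mask, test_pixels_per_image, seed=child_seeds[ptr]
            )
            ptr += 1
            for r, c, lab in labels:
                test_x.append(extract_window(cube, (r, c), config.ws).data.transpose(2, 0, 1))
                test_y.append(lab)
        test_x = np.stack(test_x)
        test_y = np.array(test_y, dtype=np.int64)
        fit_seed = child_seeds[ptr]
        ptr += 1
        for si, size in enumerate(sizes):
            if size > n_train:
                raise ValueError(f"sample size {size} exceeds generated pool {n_train}")
            x_parts, y_parts = [], []
            for cube, labels in train_sets[:size]:
                samples = make_pixel_samples(cube, labels, config.ws)
                if config.k_ssn > 0:
                    samples = augment_training_set(cube, samples, config.ws, config.k_ssn)
                for s in samples:
                    x_parts.append(s.patch.data.transpose(2, 0, 1))
                    y_parts.append(s.label)
            adapter = (
                adapter_factory(config, task.bands)
                if adapter_factory is not None
                else SCNNAdapter(config, task.bands)
            )
            adapter.fit(np.stack(x_parts), np.array(y_parts, dtype=np.int64), fit_seed)
            accs[si, rep] = float(np.mean(adapter.predict(test_x) == test_y))
    out = pd.DataFrame(
        {
            "mean_acc": accs.mean(axis=1),
            "sd_acc": accs.std(axis=1, ddof=1) if n_seeds > 1 else np.zeros(len(sizes)),
        },
        index=pd.Index(sizes, name="sample_size"),
    )
    for rep in range(n_seeds):
        out[f"acc_seed{rep}"] = accs[:, rep]
    return out
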