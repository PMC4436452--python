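"""Multilabel metrics and the repeated cross-validation protocol.

Evaluation follows the weak-label experimental design: within each fold of
a repeated 10-fold cross-validation, the *training* labels are masked to
the target weak-label ratio while the held-out bags are scored against
their full, unmasked annotation — recovering positives the training matrix
never showed is precisely what is being measured.

Metrics: Hamming loss (fraction of bag–label cells predicted incorrectly),
macro-F1 (per-label F1 averaged over all labels, zero-division → 0) and
micro-F1 (F1 of the pooled confusion counts). Paired two-sided t-tests
compare methods across the fold × repetition cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .baseline import MIMLkNN
from .bagdist import pairwise_bag_distances
from .datamodel import LabelMatrix, MIMLDataset
from .mimlwel import MIMLwel
from .weak_label import MaskingConfig, mask_labels


# ---------------------------------------------------------------------------
# metrics


def _check_shapes(pred, truth):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return pred, truth


def hamming_loss(pred, truth) -> float:
    pred, truth = _check_shapes(pred, truth)
    return float((pred != truth).mean())


def per_label_f1(pred, truth) -> np.ndarray:
    """F1 per label column, 0 where the label has no TP, FP or FN."""
    pred, truth = _check_shapes(pred, truth)
    tp = ((pred == 1) & (truth == 1)).sum(axis=0).astype(float)
    fp = ((pred == 1) & (truth == 0)).sum(axis=0).astype(float)
    fn = ((pred == 0) & (truth == 1)).sum(axis=0).astype(float)
    denom = 2 * tp + fp + fn
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = np.where(denom > 0, 2 * tp / denom, 0.0)
    return f1


def macro_f1(pred, truth) -> float:
    return float(per_label_f1(pred, truth).mean())


def micro_f1(pred, truth) -> float:
    pred, truth = _check_shapes(pred, truth)
    tp = float(((pred == 1) & (truth == 1)).sum())
    fp = float(((pred == 1) & (truth == 0)).sum())
    fn = float(((pred == 0) & (truth == 1)).sum())
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom > 0 else 0.0


def paired_t_test(a, b, level: float = 0.95):
    """Two-sided paired t-test; returns (t, p, significant).

    Zero variance of the differences is resolved by convention: p = 1 when
    the mean difference is 0 (identical samples), p = 0 for a constant
    nonzero shift. Significant iff p < 1 − level.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("samples must be 1-D of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 paired observations")
    diff = a - b
    if np.std(diff, ddof=1) == 0:
        if np.mean(diff) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = float(np.sign(np.mean(diff)) * np.inf), 0.0
    else:
        t, p = stats.ttest_rel(a, b)
        t, p = float(t), float(p)
    return t, p, p < (1.0 - level)


# ---------------------------------------------------------------------------
# cross-validation harness


@dataclass
class MetricReport:
    hamming_loss: float
    macro_f1: float
    micro_f1: float
    per_label_f1: np.ndarray = field(repr=False, default=None)

    @classmethod
    def from_predictions(cls, pred, truth) -> "MetricReport":
        return cls(
            hamming_loss=hamming_loss(pred, truth),
            macro_f1=macro_f1(pred, truth),
            micro_f1=micro_f1(pred, truth),
            per_label_f1=per_label_f1(pred, truth),
        )


METRIC_NAMES = ("hamming_loss", "macro_f1", "micro_f1")


@dataclass
class CVResult:
    """Per-repetition × per-fold metric reports plus summary and config."""

    reports: list  # reps × folds nested list of MetricReport
    fold_assignments: list  # per rep: array of fold id per bag
    config: dict

    def cells(self, metric: str) -> np.ndarray:
        return np.array(
            [getattr(r, metric) for rep in self.reports for r in rep]
        )

    @property
    def mean(self) -> dict:
        return {m: float(self.cells(m).mean()) for m in METRIC_NAMES}

    @property
    def std(self) -> dict:
        return {m: float(self.cells(m).std(ddof=1)) for m in METRIC_NAMES}

    def summary(self) -> dict:
        return {
            "config": self.config,
            "mean": self.mean,
            "std": self.std,
        }


def make_method(spec: dict, seed: int = 0):
    """Instantiate a method from a spec dict like {'method': 'mimlwel', ...}."""
    spec = dict(spec)
    kind = spec.pop("method", "mimlwel")
    if kind == "mimlwel":
        return MIMLwel(seed=seed, **spec)
    if kind == "mimlknn":
        return MIMLkNN(**spec)
    raise ValueError(f"unknown method {kind!r}")


def _fold_split(m: int, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random fold id per bag; sizes differ by at most one."""
    ids = np.arange(m) % folds
    return ids[rng.permutation(m)]


def _derive_seed(*parts) -> int:
    ss = np.random.SeedSequence(list(parts))
    return int(ss.generate_state(1)[0] % (2**31))


def run_repeated_cv(
    dataset: MIMLDataset,
    method_spec: dict,
    folds: int = 10,
    reps: int = 10,
    wlr: float = 0.8,
    seed: int = 0,
    D: np.ndarray | None = None,
) -> CVResult:
    """Repeated k-fold CV with per-training-fold weak-label masking.

    The fold structure depends only on (seed, repetition), so sweeps over
    the weak-label ratio at the same seed are paired. Test folds are scored
    against the full label matrix.
    """
    m = dataset.n_bags
    if folds > m:
        raise ValueError(f"folds={folds} exceeds {m} bags")
    if not (0.0 < wlr <= 1.0):
        raise ValueError(f"wlr must be in (0, 1], got {wlr}")
    metric = method_spec.get("distance", "avg")
    if D is None:
        D = pairwise_bag_distances(dataset.bags, metric=metric)
    Y_full = dataset.labels
    if Y_full.role != "full":
        raise ValueError("repeated CV requires a full label matrix for scoring")

    reports, assignments = [], []
    for rep in range(reps):
        rng = np.random.default_rng(_derive_seed(seed, rep, 0))
        fold_ids = _fold_split(m, folds, rng)
        assignments.append(fold_ids)
        rep_reports = []
        for fold in range(folds):
            test_idx = np.flatnonzero(fold_ids == fold)
            train_idx = np.flatnonzero(fold_ids != fold)
            train_bags = [dataset.bags[i] for i in train_idx]
            test_bags = [dataset.bags[i] for i in test_idx]
            Y_train = LabelMatrix(Y_full.values[train_idx], "full")
            # a masked column needs >=1 positive; drop train-empty columns
            keep = Y_train.values.sum(axis=0) > 0
            Y_train_kept = LabelMatrix(Y_train.values[:, keep], "full")
            if wlr < 1.0:
                Y_obs = mask_labels(
                    Y_train_kept,
                    MaskingConfig(ratio=wlr, seed=_derive_seed(seed, rep, fold, 1)),
                )
            else:
                Y_obs = LabelMatrix(Y_train_kept.values, "observed")
            est = make_method(method_spec, seed=_derive_seed(seed, rep, fold, 2))
            est.fit(train_bags, Y_obs, D=D[np.ix_(train_idx, train_idx)])
            _, binary_kept = est.predict(
                test_bags, D_to_train=D[np.ix_(test_idx, train_idx)]
            )
            # labels unseen in this training fold are predicted all-negative
            binary = np.zeros((len(test_idx), dataset.n_labels), dtype=np.int8)
            binary[:, keep] = binary_kept
            truth = Y_full.values[test_idx]
            rep_reports.append(MetricReport.from_predictions(binary, truth))
        reports.append(rep_reports)

    config = {
        "method": dict(method_spec),
        "folds": folds,
        "reps": reps,
        "wlr": wlr,
        "seed": seed,
        "m": m,
        "L": dataset.n_labels,
    }
    return CVResult(reports, assignments, config)


def wlr_sweep(
    dataset: MIMLDataset,
    method_spec: dict,
    ratios=(0.2, 0.4, 0.6, 0.8),
    folds: int = 10,
    reps: int = 10,
    seed: int = 0,
    D: np.ndarray | None = None,
) -> list:
    """One CVResult per weak-label ratio with a shared fold structure."""
    ratios = list(ratios)
    if not ratios:
        raise ValueError("empty ratio list")
    if any(not (0.0 < r <= 1.0) for r in ratios):
        raise ValueError("ratios must lie in (0, 1]")
    if D is None:
        D = pairwise_bag_distances(
            dataset.bags, metric=method_spec.get("distance", "avg")
        )
    return [
        run_repeated_cv(
            dataset, method_spec, folds=folds, reps=reps, wlr=r, seed=seed, D=D
        )
        for r in ratios
    ]


def param_grid(
    dataset: MIMLDataset,
    mu_values=(0.2, 0.4, 0.6, 0.8, 1.0),
    alpha_values=(0.02, 0.04, 0.06, 0.08, 0.1),
    wlr: float = 0.8,
    folds: int = 10,
    reps: int = 10,
    seed: int = 0,
    method_spec: dict | None = None,
    D: np.ndarray | None = None,
) -> dict:
    """Evaluate MIMLwel over the μ × α grid at a fixed weak-label ratio.

    Returns {'grid': {(mu, alpha): CVResult}, 'argmax': {metric: (mu, alpha)}}
    where argmax minimizes Hamming loss and maximizes the F1 metrics.
    """
    if any(v <= 0 for v in list(mu_values) + list(alpha_values)):
        raise ValueError("grid values must be positive")
    base = dict(method_spec or {})
    base.setdefault("method", "mimlwel")
    if D is None:
        D = pairwise_bag_distances(dataset.bags)
    grid = {}
    for mu in mu_values:
        for alpha in alpha_values:
            spec = dict(base, mu=mu, alpha=alpha)
            grid[(mu, alpha)] = run_repeated_cv(
                dataset, spec, folds=folds, reps=reps, wlr=wlr, seed=seed, D=D
            )
    argbest = {}
    for metric in METRIC_NAMES:
        items = [(point, res.mean[metric]) for point, res in grid.items()]
        if metric == "hamming_loss":
            argbest[metric] = min(items, key=lambda kv: kv[1])[0]
        else:
            argbest[metric] = max(items, key=lambda kv: kv[1])[0]
    return {"grid": grid, "argmax": argbest}


def compare_methods(
    dataset: MIMLDataset,
    specs: dict,
    ratios=(0.2, 0.4, 0.6, 0.8),
    folds: int = 10,
    reps: int = 10,
    seed: int = 0,
    reference: str = "mimlwel",
) -> dict:
    """Sweep several methods over the ratios and attach paired t-tests.

    For each ratio and metric, the reference method is compared against each
    other method across the fold × repetition cells; a '●' marker records a
    significantly better reference (p < 0.05 and better mean).
    """
    D = pairwise_bag_distances(dataset.bags)
    results = {
        name: wlr_sweep(
            dataset, spec, ratios=ratios, folds=folds, reps=reps, seed=seed, D=D
        )
        for name, spec in specs.items()
    }
    tests = {}
    for ri, ratio in enumerate(ratios):
        ref_res = results[reference][ri]
        for name in specs:
            if name == reference:
                continue
            for metric in METRIC_NAMES:
                a = ref_res.cells(metric)
                b = results[name][ri].cells(metric)
                t, p, sig = paired_t_test(a, b)
                better = (
                    ref_res.mean[metric] < results[name][ri].mean[metric]
                    if metric == "hamming_loss"
                    else ref_res.mean[metric] > results[name][ri].mean[metric]
                )
                tests[(ratio, name, metric)] = {
                    "t": t,
                    "p": p,
                    "marker": "●" if (sig and better) else "",
                }
    return {"results": results, "tests": tests, "ratios": list(ratios)}
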