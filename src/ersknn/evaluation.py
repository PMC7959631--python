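"""Stratified cross-validation protocol and the classification metric suite.

Conventions follow the BCI-evaluation literature: accuracy, sensitivity,
specificity, false-positive rate and error rate on the percent scale;
precision, recall, F1, Cohen's kappa, the Matthews correlation coefficient
and AUC on the unit scale.  Binary problems report the positive-class
(class 0 by default) values; multiclass problems compute per-class
one-vs-all values and aggregate them macro (unweighted class mean) or
micro (pooled counts — micro recall equals overall accuracy).

``run_cv_pipeline`` executes the full workflow — band-pass, CSP,
random-forest feature selection, random-subspace k-NN — fitting every
supervised stage inside each training fold only, so no information from a
test split reaches any fitted parameter.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field, replace

import numpy as np

from .csp import FeatureMatrix, extract_features, fit_csp_multiclass
from .preprocess import FilterSpec, bandpass
from .rf_select import fit_forest, oob_permutation_importance, select_features
from .rs_knn import fit_rs_knn, predict_ensemble, tune_k
from .trials_io import TrialSet, select_window

# ---------------------------------------------------------------- folds


def stratified_folds(labels, n_folds: int, seed: int = 0) -> np.ndarray:
    """Assign each trial to one of ``n_folds`` folds, stratified by class.

    Within each class the (shuffled) trials are dealt round-robin, with a
    per-class starting offset that balances fold sizes, so per-fold class
    proportions differ from the global proportions by at most one trial.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if n_folds < 2:
        raise ValueError(f"n_folds must be >= 2; got {n_folds}")
    counts = np.bincount(labels)
    present = np.flatnonzero(counts)
    small = [int(c) for c in present if counts[c] < n_folds]
    if small:
        raise ValueError(
            f"classes {small} have fewer trials than n_folds={n_folds}"
        )
    rng = np.random.default_rng(seed)
    assign = np.empty(labels.shape[0], dtype=np.int64)
    offset = 0
    for c in present:
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        assign[idx] = (np.arange(idx.size) + offset) % n_folds
        offset += idx.size
    return assign


# ---------------------------------------------------------------- metrics


def confusion_matrix(y_true, y_pred, n_classes: int | None = None) -> np.ndarray:
    """k x k count matrix; rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


@dataclass
class MetricsReport:
    """Full metric suite for one confusion matrix.

    Percent-scale: ``accuracy``, ``sensitivity``, ``specificity``, ``fpr``,
    ``error_rate``.  Unit-scale: ``precision``, ``recall``, ``f1``,
    ``kappa``, ``mcc``, ``auc`` (the last only when scores were supplied).
    Scalars are positive-class values for binary problems and
    macro/micro-averaged (per ``averaging``) for multiclass; ``per_class``
    holds the one-vs-all values behind them.  Undefined (zero-denominator)
    class metrics are NaN and named in ``flags`` rather than silently 0.
    """

    cm: np.ndarray
    accuracy: float
    error_rate: float
    sensitivity: float
    specificity: float
    fpr: float
    precision: float
    recall: float
    f1: float
    kappa: float
    mcc: float
    averaging: str
    per_class: dict = field(default_factory=dict)
    micro: dict = field(default_factory=dict)
    auc: float | None = None
    auc_per_class: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)


def _safe_div(num, den):
    num = np.asarray(num, dtype=np.float64)
    den = np.asarray(den, dtype=np.float64)
    out = np.full(np.broadcast(num, den).shape, np.nan)
    ok = den > 0
    np.divide(num, den, out=out, where=ok)
    return out


def compute_metrics(
    cm: np.ndarray,
    averaging: str = "macro",
    positive: int = 0,
) -> MetricsReport:
    """Compute the metric suite from a confusion matrix.

    For binary matrices the scalar sensitivity/specificity/... are those of
    the ``positive`` class; for k > 2 they are macro or micro averages of
    the per-class one-vs-all values.  Kappa is Cohen's kappa from the
    marginals; MCC uses the generalized multiclass formula.
    """
    cm = np.asarray(cm, dtype=np.float64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError(f"confusion matrix must be square; got {cm.shape}")
    if np.any(cm < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix total must be positive")
    if averaging not in ("macro", "micro"):
        raise ValueError(f"averaging must be macro or micro; got {averaging!r}")
    k = cm.shape[0]
    tp = np.diag(cm)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = total - tp - fn - fp

    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    prec = _safe_div(tp, tp + fp)
    f1 = _safe_div(2 * prec * sens, prec + sens)
    flags = []
    for name, arr in (("sensitivity", sens), ("specificity", spec),
                      ("precision", prec), ("f1", f1)):
        for c in np.flatnonzero(~np.isfinite(arr)):
            flags.append(f"{name} undefined for class {int(c)} (zero denominator)")
    per_class = {
        "sensitivity": sens * 100.0,
        "specificity": spec * 100.0,
        "fpr": (1.0 - spec) * 100.0,
        "precision": prec,
        "recall": sens,
        "f1": f1,
    }
    micro_tp, micro_fn, micro_fp, micro_tn = tp.sum(), fn.sum(), fp.sum(), tn.sum()
    micro = {
        "sensitivity": 100.0 * micro_tp / (micro_tp + micro_fn),
        "specificity": 100.0 * micro_tn / (micro_tn + micro_fp),
        "precision": micro_tp / (micro_tp + micro_fp),
        "recall": micro_tp / (micro_tp + micro_fn),
    }
    micro["fpr"] = 100.0 - micro["specificity"]
    pr_sum = micro["precision"] + micro["recall"]
    micro["f1"] = (
        2 * micro["precision"] * micro["recall"] / pr_sum if pr_sum > 0 else np.nan
    )

    accuracy = 100.0 * tp.sum() / total
    if k == 2:
        s_sens = float(per_class["sensitivity"][positive])
        s_spec = float(per_class["specificity"][positive])
        s_prec = float(prec[positive])
        s_rec = float(sens[positive])
        s_f1 = float(f1[positive])
    elif averaging == "macro":
        with np.errstate(invalid="ignore"):
            s_sens = float(np.nanmean(per_class["sensitivity"]))
            s_spec = float(np.nanmean(per_class["specificity"]))
            s_prec = float(np.nanmean(prec))
            s_rec = float(np.nanmean(sens))
            s_f1 = float(np.nanmean(f1))
    else:
        s_sens = micro["sensitivity"]
        s_spec = micro["specificity"]
        s_prec = micro["precision"]
        s_rec = micro["recall"]
        s_f1 = micro["f1"]

    # Cohen's kappa from the marginals
    p_o = tp.sum() / total
    p_e = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / total**2
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0

    # generalized (multiclass) Matthews correlation coefficient
    t_k = cm.sum(axis=1)
    p_k = cm.sum(axis=0)
    cov_yy = total * tp.sum() - float(t_k @ p_k)
    den1 = total**2 - float(p_k @ p_k)
    den2 = total**2 - float(t_k @ t_k)
    mcc = cov_yy / np.sqrt(den1 * den2) if den1 > 0 and den2 > 0 else np.nan
    if not np.isfinite(mcc):
        flags.append("mcc undefined (single-class margin)")

    return MetricsReport(
        cm=cm.astype(np.int64),
        accuracy=accuracy,
        error_rate=100.0 - accuracy,
        sensitivity=s_sens,
        specificity=s_spec,
        fpr=100.0 - s_spec,
        precision=s_prec,
        recall=s_rec,
        f1=s_f1,
        kappa=float(kappa),
        mcc=float(mcc),
        averaging=averaging,
        per_class=per_class,
        micro=micro,
        flags=flags,
    )


def roc_auc(scores, labels, positive: int) -> tuple[np.ndarray, np.ndarray, float]:
    """One-vs-all ROC for one class from per-trial scores.

    ``scores`` is the positive-class score (e.g. ensemble vote fraction).
    Thresholds sweep the distinct score values from high to low; tied
    scores move as one block, so the trapezoid-rule AUC equals the
    Mann-Whitney U statistic (with the 1/2 tie convention) divided by
    n_pos * n_neg.  Returns ``(fpr, tpr, auc)``.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    pos = labels == positive
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"need both positive and negative examples of class {positive}"
        )
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = pos[order]
    # block boundaries where the score strictly drops
    last_of_block = np.r_[s[1:] != s[:-1], True]
    tp_cum = np.cumsum(y)[last_of_block]
    fp_cum = np.cumsum(~y)[last_of_block]
    tpr = np.r_[0.0, tp_cum / n_pos]
    fpr = np.r_[0.0, fp_cum / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


@dataclass
class AggregateStat:
    """Mean +/- sample SD of a metric over folds or subjects."""

    mean: float
    sd: float
    n: int
    single_value: bool = False

    def display(self, decimals: int = 2) -> str:
        return (
            f"{round_display(self.mean, decimals):.{decimals}f} ± "
            f"{round_display(self.sd, decimals):.{decimals}f}"
        )


def round_display(x: float, decimals: int = 2) -> float:
    """Round half away from zero (the convention of printed results tables).

    Works on the shortest decimal representation of ``x`` so that e.g.
    1.005 -> 1.01 despite its binary representation sitting just below the
    halfway point.
    """
    import decimal

    quantum = decimal.Decimal(1).scaleb(-decimals)
    return float(
        decimal.Decimal(repr(float(x))).quantize(
            quantum, rounding=decimal.ROUND_HALF_UP
        )
    )


def aggregate(values) -> AggregateStat:
    """Mean and sample SD (n-1 denominator) of per-subject/per-fold values.

    A single value yields SD 0 with ``single_value`` flagged.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot aggregate an empty list")
    if values.size == 1:
        return AggregateStat(mean=float(values[0]), sd=0.0, n=1, single_value=True)
    return AggregateStat(
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        n=int(values.size),
        single_value=False,
    )


# ---------------------------------------------------------------- pipeline


@dataclass
class PipelineConfig:
    """All tunable parameters of the CV pipeline, with literature defaults.

    ``knn_k`` may be an integer or ``"auto"`` (per-fold CV tuning on the
    training split).  ``subspace_dim=None`` means ceil(p/2) after
    selection.  ``select_enabled=False`` skips the random-forest stage and
    classifies on all CSP features.
    """

    band: FilterSpec | None = field(default_factory=FilterSpec)
    window: tuple[float, float] | None = None
    n_pairs: int = 1
    shrinkage: float = 1e-8
    log_variance: bool = False
    select_enabled: bool = True
    rf_ntree: int = 100
    rf_max_splits: int | None = 359
    rf_criterion: str = "gini"
    select_tolerance: float = 0.005
    n_learners: int = 50
    knn_k: int | str = 10
    subspace_dim: int | None = None
    metric: str = "euclidean"
    standardize: bool = False
    cv_folds: int = 10
    averaging: str = "macro"
    seed: int = 0


@dataclass
class CVResult:
    """Outcome of one cross-validated pipeline run."""

    fold_assignments: np.ndarray
    per_fold: list[MetricsReport]
    pooled: MetricsReport
    aggregate: AggregateStat
    selected_features: list[np.ndarray]
    model_checksums: list[str]
    predictions: np.ndarray
    scores: np.ndarray
    stage_seconds: dict[str, float]


def _subset(tset: TrialSet, mask: np.ndarray) -> TrialSet:
    return replace(
        tset,
        data=tset.data[mask],
        labels=tset.labels[mask],
        class_names=list(tset.class_names),
        channel_names=list(tset.channel_names),
    )


def _child_seed(seed: int, *key: int) -> int:
    return int(
        np.random.SeedSequence(seed, spawn_key=tuple(key)).generate_state(1)[0]
        % (2**31)
    )


def _cv_knn_accuracy(values, labels, k, metric, folds=3, seed=0):
    """Cheap stratified-CV plain-kNN accuracy, the feature-sweep evaluator."""
    from scipy.spatial.distance import cdist

    from .rs_knn import _check_metric, _vote

    labels = np.asarray(labels, dtype=np.int64)
    counts = np.bincount(labels)
    folds = int(min(folds, counts[counts > 0].min()))
    if folds < 2:
        raise ValueError("a class has too few trials for the selection evaluator")
    assign = stratified_folds(labels, folds, seed=seed)
    nc = int(labels.max()) + 1
    correct = 0
    for f in range(folds):
        test = assign == f
        kk = min(k, int((~test).sum()))
        d = cdist(values[test], values[~test], metric=_check_metric(metric))
        nn = np.argsort(d, axis=1, kind="stable")[:, :kk]
        y_tr = labels[~test]
        for i in range(d.shape[0]):
            winner, _, _ = _vote(d[i, nn[i]], y_tr[nn[i]], nc)
            correct += winner == labels[test][i]
    return correct / labels.size


def _model_checksum(bank, selected, model) -> str:
    h = hashlib.sha256()
    for W in bank.filters:
        h.update(np.ascontiguousarray(W).tobytes())
    h.update(np.ascontiguousarray(np.asarray(selected, dtype=np.int64)).tobytes())
    for sub in model.subspaces:
        h.update(np.ascontiguousarray(sub).tobytes())
    h.update(np.ascontiguousarray(model.train_X).tobytes())
    h.update(np.ascontiguousarray(model.train_labels).tobytes())
    h.update(str(model.k).encode())
    return h.hexdigest()


def run_cv_pipeline(
    tset: TrialSet,
    config: PipelineConfig | None = None,
    fold_assignments: np.ndarray | None = None,
) -> CVResult:
    """Run the full stratified-CV pipeline on a labelled trial set.

    Per fold: band-pass (stateless, applied up front), then CSP, optional
    random-forest feature selection, and the random-subspace k-NN ensemble
    are fitted on the training split only; the held-out split is projected
    and scored.  Returns per-fold and pooled metrics, the fold-accuracy
    mean +/- SD, per-fold selected features and fitted-model checksums, and
    pooled one-vs-all AUCs from the ensemble vote fractions.
    """
    if config is None:
        config = PipelineConfig()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    work = tset
    if config.window is not None:
        work = select_window(work, *config.window)
    if config.band is not None:
        work = bandpass(work, config.band)
    timings["preprocess"] = time.perf_counter() - t0

    if fold_assignments is None:
        fold_assignments = stratified_folds(
            work.labels, config.cv_folds, seed=config.seed
        )
    else:
        fold_assignments = np.asarray(fold_assignments, dtype=np.int64)
    n_folds = int(fold_assignments.max()) + 1
    n_classes = len(work.class_names)

    per_fold: list[MetricsReport] = []
    selected_all: list[np.ndarray] = []
    checksums: list[str] = []
    predictions = np.empty(work.n_trials, dtype=np.int64)
    scores = np.zeros((work.n_trials, n_classes))
    pooled_cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    timings["csp"] = timings["select"] = timings["classify"] = 0.0

    for f in range(n_folds):
        test_mask = fold_assignments == f
        train = _subset(work, ~test_mask)
        test = _subset(work, test_mask)

        t0 = time.perf_counter()
        bank = fit_csp_multiclass(
            train, n_pairs=config.n_pairs, shrinkage=config.shrinkage
        )
        feats_train = extract_features(train, bank, log_variance=config.log_variance)
        feats_test = extract_features(test, bank, log_variance=config.log_variance)
        timings["csp"] += time.perf_counter() - t0

        t0 = time.perf_counter()
        if config.select_enabled and feats_train.n_features > 1:
            forest = fit_forest(
                feats_train.values,
                feats_train.labels,
                ntree=config.rf_ntree,
                criterion=config.rf_criterion,
                max_splits=config.rf_max_splits,
                seed=_child_seed(config.seed, 2, f),
            )
            ranking = oob_permutation_importance(
                forest, feats_train.values, feats_train.labels
            )
            eval_k = config.knn_k if isinstance(config.knn_k, int) else 10
            evaluator = lambda v, y: _cv_knn_accuracy(  # noqa: E731
                v, y, k=eval_k, metric=config.metric,
                seed=_child_seed(config.seed, 3, f),
            )
            selected, _curve = select_features(
                feats_train, ranking, evaluator, tolerance=config.select_tolerance
            )
        else:
            selected = np.arange(feats_train.n_features)
        timings["select"] += time.perf_counter() - t0

        t0 = time.perf_counter()
        sub_train = feats_train.subset(selected)
        sub_test = feats_test.subset(selected)
        if config.knn_k == "auto":
            k_use, _ = tune_k(
                sub_train,
                cv_folds=min(5, config.cv_folds),
                metric=config.metric,
                seed=_child_seed(config.seed, 4, f),
            )
        else:
            k_use = min(int(config.knn_k), sub_train.values.shape[0])
        model = fit_rs_knn(
            sub_train,
            n_learners=config.n_learners,
            k=k_use,
            subspace_dim=(
                None
                if config.subspace_dim is None
                else min(config.subspace_dim, sub_train.n_features)
            ),
            metric=config.metric,
            seed=_child_seed(config.seed, 5, f),
            standardize=config.standardize,
        )
        pred, frac = predict_ensemble(model, sub_test)
        timings["classify"] += time.perf_counter() - t0

        predictions[test_mask] = pred
        scores[test_mask] = frac
        cm = confusion_matrix(test.labels, pred, n_classes)
        pooled_cm += cm
        per_fold.append(compute_metrics(cm, averaging=config.averaging))
        selected_all.append(np.sort(selected))
        checksums.append(_model_checksum(bank, np.sort(selected), model))

    pooled = compute_metrics(pooled_cm, averaging=config.averaging)
    aucs = np.full(n_classes, np.nan)
    for c in range(n_classes):
        if (work.labels == c).any() and (work.labels != c).any():
            _, _, aucs[c] = roc_auc(scores[:, c], work.labels, positive=c)
    pooled.auc_per_class = aucs
    with np.errstate(invalid="ignore"):
        pooled.auc = float(np.nanmean(aucs))
    agg = aggregate([m.accuracy for m in per_fold])
    return CVResult(
        fold_assignments=fold_assignments,
        per_fold=per_fold,
        pooled=pooled,
        aggregate=agg,
        selected_features=selected_all,
        model_checksums=checksums,
        predictions=predictions,
        scores=scores,
        stage_seconds=timings,
    )
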