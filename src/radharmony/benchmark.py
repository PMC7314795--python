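"""Downstream model-performance benchmark over harmonization variants.

The harness mirrors a multicenter modelling workflow: the whole cohort is
harmonized (harmonization is unsupervised in the outcome), one batch — the
reference — serves as the training set and the remaining batches as the
held-out test set, class imbalance is corrected by SMOTE on the training
fold only, and three classification pipelines are compared:

* ``mr``  — logistic regression on LASSO-selected features (penalty chosen by
            10-fold cross-validation, selected features refit unpenalized);
* ``rf``  — random forest with embedded feature selection: importance
            averaged over bootstrap refits, then stepwise forward selection
            minimizing out-of-bootstrap validation error;
* ``svm`` — support-vector machine with cost tuned first, features ranked by
            single-feature leave-one-out error, then the same forward
            selection.

Test metrics (BAcc, MCC, AUC, sensitivity, specificity) are computed on
samples never seen in training or SMOTE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC

from .combat import apply_model, harmonize
from .evaluate import ConfusionCounts, balanced_accuracy, matthews_cc
from .types import BatchDesign, FeatureTable, RunConfig

VARIANT_ORDER = ("untransformed", "combat", "b-combat", "m-combat", "bm-combat")
PIPELINES = ("mr", "rf", "svm")


@dataclass
class BenchmarkConfig:
    smote_k: int = 5
    lasso_cv_folds: int = 10
    rf_trees: int = 500
    inner_bootstrap: int = 100  # importance-averaging refits
    val_bootstrap: int = 25  # out-of-bootstrap error estimates per subset
    max_forward: int = 15  # longest ranking prefix examined
    svm_c_grid: Sequence[float] = (0.01, 0.1, 1.0, 10.0)
    svm_kernel: str = "linear"
    n_bootstrap: int = 100  # B for the bootstrap harmonization variants
    prior: str = "nonparametric"
    harmonize_train_only: bool = False
    seed: int = 0


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------


def smote_oversample(
    features: np.ndarray,
    outcome: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by synthetic minority oversampling.

    Each synthetic sample is x + lambda (x_nn - x) with lambda ~ U[0, 1],
    x a random minority sample and x_nn one of its k nearest minority
    neighbours (Euclidean).  Returns the augmented (features, outcome);
    already balanced input is returned unchanged.
    """
    features = np.asarray(features, dtype=float)
    outcome = np.asarray(outcome).astype(int)
    classes, counts = np.unique(outcome, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE needs a binary outcome")
    if counts[0] == counts[1]:
        return features, outcome
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    x_min = features[outcome == minority]
    if len(x_min) < k_neighbors + 1:
        raise ValueError(
            f"minority class has {len(x_min)} samples; needs >= {k_neighbors + 1} "
            f"for k_neighbors={k_neighbors}"
        )
    rng = np.random.default_rng(seed)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(x_min)
    _, nbr = nn.kneighbors(x_min)
    nbr = nbr[:, 1:]  # drop self
    base = rng.integers(0, len(x_min), size=n_needed)
    pick = rng.integers(0, k_neighbors, size=n_needed)
    lam = rng.uniform(size=n_needed)[:, None]
    x_new = x_min[base] + lam * (x_min[nbr[base, pick]] - x_min[base])
    return (
        np.vstack([features, x_new]),
        np.concatenate([outcome, np.full(n_needed, minority, dtype=int)]),
    )


# ---------------------------------------------------------------------------
# metrics helper
# ---------------------------------------------------------------------------


def _metrics(y_true: np.ndarray, y_pred: np.ndarray, score: np.ndarray) -> dict:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    c = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    try:
        auc = float(roc_auc_score(y_true, score))
    except ValueError:
        auc = float("nan")
    return {
        "bacc": balanced_accuracy(c),
        "mcc": matthews_cc(c),
        "auc": auc,
        "sensitivity": sens,
        "specificity": spec,
    }


def _decision_scores(model, x: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(x)[:, 1]
    return model.decision_function(x)


# ---------------------------------------------------------------------------
# pipelines
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    selected: list[str]
    model: object
    scaler: Optional[StandardScaler]
    train_metrics: dict
    test_metrics: dict
    flags: list[str] = field(default_factory=list)


class _MajorityModel:
    """Intercept-only fallback when LASSO selects nothing."""

    def __init__(self, rate: float) -> None:
        self.rate = rate

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.full(len(x), int(self.rate >= 0.5))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return np.tile([1 - self.rate, self.rate], (len(x), 1))


def mr_lasso_pipeline(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    y_test: np.ndarray,
    feature_names: Sequence[str],
    config: BenchmarkConfig,
    seed: int = 0,
) -> PipelineResult:
    """LASSO-penalized logistic selection + unpenalized logistic refit."""
    if len(y_train) < 10:
        raise ValueError("need at least 10 training samples")
    scaler = StandardScaler().fit(x_train)
    xs = scaler.transform(x_train)
    folds = min(config.lasso_cv_folds, int(np.min(np.bincount(y_train))))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        # large-C path members on separable folds stop at max_iter; harmless
        warnings.simplefilter("ignore", ConvergenceWarning)
        # the C grid stays within [1e-2, 1e1]: beyond that the l1 path on
        # near-separable oversampled folds barely changes the selected set
        # but the solver's cost explodes
        lasso = LogisticRegressionCV(
            penalty="l1",
            solver="liblinear",
            Cs=np.logspace(-2, 1, 10),
            cv=StratifiedKFold(folds, shuffle=True, random_state=seed),
            scoring="accuracy",
            max_iter=2000,
            random_state=seed,
        ).fit(xs, y_train)
    sel = np.flatnonzero(np.abs(lasso.coef_[0]) > 1e-10)
    flags = []
    if len(sel) == 0:
        flags.append("empty-selection:intercept-only")
        model: object = _MajorityModel(float(np.mean(y_train)))
        pred_tr = model.predict(xs)
        sco_tr = model.predict_proba(xs)[:, 1]
        xt = scaler.transform(x_test)
        pred_te = model.predict(xt)
        sco_te = model.predict_proba(xt)[:, 1]
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model = LogisticRegression(C=np.inf, max_iter=5000).fit(
                xs[:, sel], y_train
            )
        pred_tr = model.predict(xs[:, sel])
        sco_tr = _decision_scores(model, xs[:, sel])
        xt = scaler.transform(x_test)
        pred_te = model.predict(xt[:, sel])
        sco_te = _decision_scores(model, xt[:, sel])
    return PipelineResult(
        selected=[feature_names[j] for j in sel],
        model=model,
        scaler=scaler,
        train_metrics=_metrics(y_train, pred_tr, sco_tr),
        test_metrics=_metrics(y_test, pred_te, sco_te),
        flags=flags,
    )


def _bootstrap_indices(
    rng: np.random.Generator, y: np.ndarray, max_tries: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap train indices + out-of-bag indices, redrawn until both
    partitions contain both classes."""
    n = len(y)
    for _ in range(max_tries):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        if len(oob) and len(np.unique(y[idx])) == 2 and len(np.unique(y[oob])) == 2:
            return idx, oob
    raise RuntimeError("could not draw a non-degenerate bootstrap split")


def _oob_error(
    make_model,
    x: np.ndarray,
    y: np.ndarray,
    cols: np.ndarray,
    rng: np.random.Generator,
    n_rounds: int,
) -> float:
    """Mean out-of-bootstrap balanced error for a feature subset."""
    errs = []
    for _ in range(n_rounds):
        idx, oob = _bootstrap_indices(rng, y)
        m = make_model(rng)
        m.fit(x[idx][:, cols], y[idx])
        pred = m.predict(x[oob][:, cols])
        tp = np.sum((y[oob] == 1) & (pred == 1))
        fn = np.sum((y[oob] == 1) & (pred == 0))
        tn = np.sum((y[oob] == 0) & (pred == 0))
        fp = np.sum((y[oob] == 0) & (pred == 1))
        bacc = 0.5 * (tp / (tp + fn) + tn / (tn + fp))
        errs.append(1.0 - bacc)
    return float(np.mean(errs))


def _forward_select(
    ranking: np.ndarray,
    make_model,
    x: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    config: BenchmarkConfig,
) -> tuple[np.ndarray, list[float]]:
    """Examine ranking prefixes of growing length; keep the global error
    minimum (ties toward fewer features)."""
    errors = []
    upto = min(config.max_forward, len(ranking))
    for p in range(1, upto + 1):
        errors.append(
            _oob_error(make_model, x, y, ranking[:p], rng, config.val_bootstrap)
        )
    best = int(np.argmin(errors)) + 1
    return ranking[:best], errors


def embedded_fs_rf(
    x_train: np.ndarray,
    y_train: np.ndarray,
    feature_names: Sequence[str],
    config: BenchmarkConfig,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, RandomForestClassifier]:
    """Bootstrap-averaged RF importances + forward selection + final refit.

    Returns (full importance ranking, chosen feature indices, fitted model).
    """
    if x_train.shape[1] < 1:
        raise ValueError("need at least one feature")
    rng = np.random.default_rng(seed)
    imp = np.zeros(x_train.shape[1])
    for _ in range(config.inner_bootstrap):
        idx, _ = _bootstrap_indices(rng, y_train)
        rf = RandomForestClassifier(
            n_estimators=config.rf_trees,
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        ).fit(x_train[idx], y_train[idx])
        imp += rf.feature_importances_
    ranking = np.argsort(-imp / config.inner_bootstrap, kind="stable")

    def make_model(r):
        return RandomForestClassifier(
            n_estimators=config.rf_trees, random_state=int(r.integers(2**31)), n_jobs=1
        )

    if x_train.shape[1] == 1:
        chosen = ranking[:1]
    else:
        chosen, _ = _forward_select(ranking, make_model, x_train, y_train, rng, config)
    final = RandomForestClassifier(
        n_estimators=config.rf_trees, random_state=seed, n_jobs=1
    ).fit(x_train[:, chosen], y_train)
    return ranking, chosen, final


def embedded_fs_svm(
    x_train: np.ndarray,
    y_train: np.ndarray,
    feature_names: Sequence[str],
    config: BenchmarkConfig,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, SVC, float]:
    """Cost tuning, single-feature leave-one-out ranking, forward selection.

    Features whose single-feature model classifies best under leave-one-out
    are ranked first.  Returns (ranking, chosen indices, fitted model, C).
    """
    if x_train.shape[1] < 1:
        raise ValueError("need at least one feature")
    rng = np.random.default_rng(seed)
    folds = min(5, int(np.min(np.bincount(y_train))))
    best_c, best_score = None, -np.inf
    for c in config.svm_c_grid:
        s = cross_val_score(
            SVC(C=c, kernel=config.svm_kernel),
            x_train,
            y_train,
            cv=StratifiedKFold(folds, shuffle=True, random_state=seed),
            scoring="balanced_accuracy",
        ).mean()
        if s > best_score:
            best_c, best_score = c, s

    n = len(y_train)
    loo_acc = np.zeros(x_train.shape[1])
    # single-feature leave-one-out ranking; the fast liblinear solver is an
    # exact stand-in for a linear-kernel SVM on 1-D data
    fast = config.svm_kernel == "linear"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for j in range(x_train.shape[1]):
            xj = x_train[:, [j]]
            correct = 0
            for i in range(n):
                mask = np.ones(n, dtype=bool)
                mask[i] = False
                if len(np.unique(y_train[mask])) < 2:
                    continue
                if fast:
                    m = LinearSVC(C=best_c).fit(xj[mask], y_train[mask])
                else:
                    m = SVC(C=best_c, kernel=config.svm_kernel).fit(
                        xj[mask], y_train[mask]
                    )
                correct += int(m.predict(xj[[i]])[0] == y_train[i])
            loo_acc[j] = correct / n
    ranking = np.argsort(-loo_acc, kind="stable")

    def make_model(r):
        return SVC(C=best_c, kernel=config.svm_kernel)

    if x_train.shape[1] == 1:
        chosen = ranking[:1]
    else:
        chosen, _ = _forward_select(ranking, make_model, x_train, y_train, rng, config)
    final = SVC(C=best_c, kernel=config.svm_kernel).fit(x_train[:, chosen], y_train)
    return ranking, chosen, final, float(best_c)


# ---------------------------------------------------------------------------
# full grid
# ---------------------------------------------------------------------------


def _harmonized_versions(
    table: FeatureTable,
    design: BatchDesign,
    variants: Sequence[str],
    config: BenchmarkConfig,
    train_mask: Optional[np.ndarray] = None,
) -> dict[str, FeatureTable]:
    out = {}
    for v in variants:
        if v == "untransformed":
            out[v] = table
            continue
        rc = RunConfig(
            variant=v,
            prior=config.prior,
            n_bootstrap=config.n_bootstrap,
            seed=config.seed,
        )
        if config.harmonize_train_only and train_mask is not None:
            idx = np.flatnonzero(train_mask)
            sub = FeatureTable(
                [table.sample_ids[i] for i in idx],
                list(table.feature_names),
                table.values[idx],
            )
            _, model = harmonize(sub, design.subset(idx), rc)
            out[v] = apply_model(table, design, model)
        else:
            out[v], _ = harmonize(table, design, rc)
    return out


def run_benchmark(
    table: FeatureTable,
    design: BatchDesign,
    outcome: np.ndarray,
    train_batches: Sequence[str],
    config: Optional[BenchmarkConfig] = None,
    variants: Sequence[str] = VARIANT_ORDER,
    pipelines: Sequence[str] = PIPELINES,
) -> pd.DataFrame:
    """Run the variant x pipeline grid; returns a tidy DataFrame.

    ``train_batches`` names the batch(es) forming the training set (in an
    external-validation design this is the reference batch); all other
    batches form the held-out test set.  Harmonization is fit on the whole cohort by default
    (it is unsupervised in the outcome, matching the multicenter workflow of
    harmonizing the pooled database before modelling).  The strict
    ``config.harmonize_train_only`` mode fits the harmonization on training
    rows only and re-applies the frozen model — it requires every batch to
    appear in the training set, since the model cannot extrapolate to
    unseen batches, and is offered for methodological comparison.
    """
    config = config or BenchmarkConfig()
    outcome = np.asarray(outcome).astype(int)
    train_mask = np.isin(design.labels, list(train_batches))
    if not train_mask.any() or train_mask.all():
        raise ValueError("train/test split by batch leaves one side empty")
    for side, mask in (("train", train_mask), ("test", ~train_mask)):
        if len(np.unique(outcome[mask])) < 2:
            raise ValueError(f"{side} set contains a single outcome class")

    versions = _harmonized_versions(table, design, variants, config, train_mask)
    rows = []
    for vname, vtable in versions.items():
        x = vtable.values
        x_tr, y_tr = x[train_mask], outcome[train_mask]
        x_te, y_te = x[~train_mask], outcome[~train_mask]
        x_bal, y_bal = smote_oversample(x_tr, y_tr, config.smote_k, config.seed)
        for pname in pipelines:
            if pname == "mr":
                res = mr_lasso_pipeline(
                    x_bal, y_bal, x_te, y_te, vtable.feature_names, config, config.seed
                )
                tr_m, te_m = res.train_metrics, res.test_metrics
                selected = res.selected
            elif pname == "rf":
                _, chosen, model = embedded_fs_rf(
                    x_bal, y_bal, vtable.feature_names, config, config.seed
                )
                tr_m = _metrics(
                    y_bal,
                    model.predict(x_bal[:, chosen]),
                    _decision_scores(model, x_bal[:, chosen]),
                )
                te_m = _metrics(
                    y_te,
                    model.predict(x_te[:, chosen]),
                    _decision_scores(model, x_te[:, chosen]),
                )
                selected = [vtable.feature_names[j] for j in chosen]
            elif pname == "svm":
                scaler = StandardScaler().fit(x_bal)
                xb, xt = scaler.transform(x_bal), scaler.transform(x_te)
                _, chosen, model, _ = embedded_fs_svm(
                    xb, y_bal, vtable.feature_names, config, config.seed
                )
                tr_m = _metrics(
                    y_bal, model.predict(xb[:, chosen]), model.decision_function(xb[:, chosen])
                )
                te_m = _metrics(
                    y_te, model.predict(xt[:, chosen]), model.decision_function(xt[:, chosen])
                )
                selected = [vtable.feature_names[j] for j in chosen]
            else:
                raise ValueError(f"unknown pipeline {pname!r}")
            for split, m in (("train", tr_m), ("test", te_m)):
                for metric, value in m.items():
                    rows.append(
                        {
                            "variant": vname,
                            "pipeline": pname,
                            "split": split,
                            "metric": metric,
                            "value": value,
                            "n_selected": len(selected),
                        }
                    )
    return pd.DataFrame(rows)
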