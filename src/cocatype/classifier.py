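"""Binary expression classifier: focal subtype versus merged rest.

The study design is: an 80/20 stratified split, lasso
(L1-penalized logistic) feature selection on standardized training
expression at a fixed penalty (default alpha = 0.0015) or by repeated
cross-validation, per-gene within-cohort standardization to harmonize
external cohorts onto the training scale, and a bake-off of seven
classification algorithms — a fully connected neural network
(input -> 500 -> 1500 -> 1700 -> 2 softmax, Adam, batch 200, 50 epochs,
learning rate 0.001), SVM, logistic regression, KNN, LDA, naive Bayes, and
CART — ranked by validation accuracy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, log_loss
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

DEFAULT_LASSO_ALPHA = 0.0015
NN_HIDDEN = (500, 1500, 1700)
NN_BATCH_SIZE = 200
NN_EPOCHS = 50
NN_LEARNING_RATE = 0.001

METHODS = ("neural_net", "svm", "logistic", "knn", "lda", "naive_bayes", "cart")


@dataclass
class ClassifierModel:
    method: str
    selected_genes: list[str]
    estimator: object
    scaler_mean: pd.Series
    scaler_std: pd.Series
    training_accuracy: float
    validation_accuracy: float | None = None
    split_seed: int = 0
    hyperparams: dict = field(default_factory=dict)


def split_cohort(
    samples: list[str], labels: pd.Series, train_fraction: float = 0.8, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Stratified train/validation split preserving class proportions."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    y = labels.loc[samples]
    counts = y.value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("both classes need at least 2 samples for a stratified split")
    train, val = train_test_split(
        list(samples), train_size=train_fraction, stratify=y, random_state=seed
    )
    return list(train), list(val)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std_safe = np.where(std == 0, 1.0, std)
    return (X - mean) / std_safe, mean, std_safe


def lasso_select_features(
    expression: pd.DataFrame,
    labels: pd.Series,
    penalty: float | str = DEFAULT_LASSO_ALPHA,
    cv_folds: int = 5,
    cv_repeats: int = 100,
    seed: int = 0,
    *,
    alpha_grid: tuple[float, ...] = (0.0005, 0.0015, 0.005, 0.015, 0.05),
) -> list[str]:
    """Genes with nonzero coefficients in an L1-penalized logistic fit.

    ``expression`` is gene x sample; genes are standardized before fitting
    (constant genes are excluded with a log line).  The penalty ``alpha`` is
    the per-observation L1 weight (sklearn C = 1 / (n * alpha)).
    ``penalty="auto"`` picks alpha from ``alpha_grid`` by ``cv_repeats``
    repetitions of stratified ``cv_folds``-fold cross-validated deviance.
    """
    X_full = expression.T  # samples x genes
    y = labels.loc[X_full.index].to_numpy()
    value_range = X_full.max(axis=0) - X_full.min(axis=0)
    constant = value_range[value_range == 0].index
    if len(constant):
        logger.info("lasso_select_features: excluding %d constant genes", len(constant))
        X_full = X_full.drop(columns=constant)
    genes = list(X_full.columns)
    X, _, _ = _standardize(X_full.to_numpy())
    n = X.shape[0]

    def fit_at(alpha: float, Xf: np.ndarray, yf: np.ndarray) -> LogisticRegression:
        clf = LogisticRegression(
            l1_ratio=1.0,  # pure lasso penalty
            C=1.0 / (alpha * len(yf)),
            solver="liblinear",
            max_iter=2000,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(Xf, yf)
        return clf

    if penalty == "auto":
        rng = np.random.default_rng(seed)
        fold_dev: dict[float, list[float]] = {a: [] for a in alpha_grid}
        for rep in range(cv_repeats):
            skf = StratifiedKFold(
                n_splits=cv_folds, shuffle=True, random_state=int(rng.integers(0, 2**31 - 1))
            )
            for tr, te in skf.split(X, y):
                for a in alpha_grid:
                    clf = fit_at(a, X[tr], y[tr])
                    prob = clf.predict_proba(X[te])
                    fold_dev[a].append(log_loss(y[te], prob, labels=clf.classes_))
        means = {a: float(np.mean(v)) for a, v in fold_dev.items()}
        best = min(alpha_grid, key=lambda a: means[a])
        best_se = float(np.std(fold_dev[best], ddof=1) / np.sqrt(len(fold_dev[best])))
        # 1-SE rule: the sparsest penalty statistically indistinguishable
        # from the deviance minimum
        alpha = max(a for a in alpha_grid if means[a] <= means[best] + best_se)
        logger.info("lasso_select_features: auto-selected alpha=%g (1-SE rule)", alpha)
    else:
        alpha = float(penalty)
        if alpha <= 0:
            raise ValueError("penalty must be positive")
    clf = fit_at(alpha, X, y)
    coef = clf.coef_.ravel()
    return [g for g, c in zip(genes, coef) if c != 0.0]


def harmonize_cohorts(
    reference_expression: pd.DataFrame,
    target_expression: pd.DataFrame,
    min_genes: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-cohort harmonization: restrict to the shared gene set and
    z-score each gene within its own cohort.  Removes per-gene location and
    scale batch differences; idempotent up to floating-point error."""
    shared = reference_expression.index.intersection(target_expression.index)
    if len(shared) < min_genes:
        raise ValueError(f"gene intersection has only {len(shared)} genes (< {min_genes})")

    def zscore(df: pd.DataFrame) -> pd.DataFrame:
        X = df.loc[shared].to_numpy(dtype=float)
        mean = X.mean(axis=1, keepdims=True)
        std = X.std(axis=1, keepdims=True)
        std = np.where(std == 0, 1.0, std)
        return pd.DataFrame((X - mean) / std, index=shared, columns=df.columns)

    return zscore(reference_expression), zscore(target_expression)


def _make_estimator(method: str, seed: int, hyperparams: dict) -> tuple[object, dict]:
    if method == "neural_net":
        params = {
            "batch_size": hyperparams.get("batch_size", NN_BATCH_SIZE),
            "epochs": hyperparams.get("epochs", NN_EPOCHS),
            "learning_rate": hyperparams.get("learning_rate", NN_LEARNING_RATE),
            "hidden": hyperparams.get("hidden", NN_HIDDEN),
        }
        est = MLPClassifier(
            hidden_layer_sizes=params["hidden"],
            solver="adam",
            batch_size=params["batch_size"],
            max_iter=params["epochs"],
            learning_rate_init=params["learning_rate"],
            random_state=seed,
        )
        return est, params
    simple = {
        "svm": lambda: SVC(kernel="rbf", random_state=seed),
        "logistic": lambda: LogisticRegression(max_iter=2000, random_state=seed),
        "knn": lambda: KNeighborsClassifier(n_neighbors=hyperparams.get("n_neighbors", 5)),
        "lda": lambda: LinearDiscriminantAnalysis(),
        "naive_bayes": lambda: GaussianNB(),
        "cart": lambda: DecisionTreeClassifier(random_state=seed),
    }
    if method not in simple:
        raise ValueError(f"unknown method {method!r}; valid: {list(METHODS)}")
    return simple[method](), dict(hyperparams)


def train_classifier(
    expression: pd.DataFrame,
    labels: pd.Series,
    selected_genes: list[str],
    method: str = "neural_net",
    hyperparams: dict | None = None,
    seed: int = 0,
) -> ClassifierModel:
    """Fit one algorithm on the selected genes (gene x sample input); the
    feature scaler is learned on this training data and stored for reuse at
    prediction time."""
    missing = [g for g in selected_genes if g not in expression.index]
    if missing:
        raise ValueError(f"selected genes missing from expression: {missing[:10]}")
    hyperparams = hyperparams or {}
    X_raw = expression.loc[selected_genes].T.to_numpy(dtype=float)
    y = labels.loc[expression.columns].to_numpy()
    X, mean, std = _standardize(X_raw)
    est, params = _make_estimator(method, seed, hyperparams)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    acc = float(accuracy_score(y, est.predict(X)))
    return ClassifierModel(
        method=method,
        selected_genes=list(selected_genes),
        estimator=est,
        scaler_mean=pd.Series(mean, index=selected_genes),
        scaler_std=pd.Series(std, index=selected_genes),
        training_accuracy=acc,
        split_seed=seed,
        hyperparams=params,
    )


def predict_subtype(model: ClassifierModel, expression: pd.DataFrame) -> pd.DataFrame:
    """Predict class labels (and decision scores where available) for new
    samples; the input must contain every selected gene."""
    missing = [g for g in model.selected_genes if g not in expression.index]
    if missing:
        raise ValueError(f"missing selected genes: {missing[:10]}")
    X_raw = expression.loc[model.selected_genes].T.to_numpy(dtype=float)
    X = (X_raw - model.scaler_mean.to_numpy()) / model.scaler_std.to_numpy()
    pred = model.estimator.predict(X)
    out = pd.DataFrame({"label": pred}, index=expression.columns)
    if hasattr(model.estimator, "predict_proba"):
        out["score"] = model.estimator.predict_proba(X)[:, -1]
    elif hasattr(model.estimator, "decision_function"):
        out["score"] = model.estimator.decision_function(X)
    return out


def compare_methods(
    expression: pd.DataFrame,
    labels: pd.Series,
    selected_genes: list[str],
    train_samples: list[str],
    validation_samples: list[str],
    methods: tuple[str, ...] = METHODS,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, ClassifierModel]]:
    """Train every method on the training partition, evaluate on the
    validation partition, and rank by validation accuracy (the pipeline's
    model-selection rule picks the argmax)."""
    models: dict[str, ClassifierModel] = {}
    rows = []
    for method in methods:
        model = train_classifier(
            expression[train_samples], labels, selected_genes, method=method, seed=seed
        )
        pred = predict_subtype(model, expression[validation_samples])
        val_acc = float(
            accuracy_score(labels.loc[validation_samples].to_numpy(), pred["label"].to_numpy())
        )
        model.validation_accuracy = val_acc
        models[method] = model
        rows.append({"method": method, "train_accuracy": model.training_accuracy,
                     "validation_accuracy": val_acc})
    report = (
        pd.DataFrame(rows)
        .sort_values(["validation_accuracy", "train_accuracy"], ascending=False)
        .reset_index(drop=True)
    )
    return report, models
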