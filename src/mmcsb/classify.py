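"""Segment-level CSB classification from the binary (LPM, SPM) features.

Two deliberately interpretable classifiers are fitted on the two binary
predictors:

* a **logistic model** ``logit P(CSB) = b0 + b1*LPM + b2*SPM`` fitted by
  maximum likelihood (IRLS, via statsmodels on the aggregated 2x2x2 count
  table), reported with Wald intervals, odds ratios and AIC.  With two
  binary predictors complete/quasi-separation is common in clean data; it
  is detected and flagged, and the reported coefficients are capped rather
  than left divergent.
* a **CART decision tree** grown by greedy binary partitioning on Gini
  impurity with a zero-gain guard, ties broken in feature order (LPM
  first).  Leaves carry the majority class and its training error rate,
  reproducing the bedside rule "LPM present -> CSB; else SPM present ->
  CSB; else no CSB" whenever the data support it.

The validation harness mirrors the published protocol: a seeded 50/50
train/test split and repeated k-fold (10 x 10) cross-validation whose 100
fold-wise metric sets are averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import FitError
from .metrics import ConfusionMatrix, MetricSet, cohens_kappa, confusion_metrics, roc_auc

__all__ = [
    "LogisticFit",
    "TreeNode",
    "TreeModel",
    "CVResult",
    "fit_logistic",
    "fit_cart",
    "predict",
    "predict_proba",
    "split_train_test",
    "cross_validate",
]

FEATURE_ORDER = ("lpm", "spm")
_COEF_CAP = 15.0  # |log-odds| beyond this is treated as separation
_MAX_IRLS_ITER = 50


def _as_feature_matrix(features) -> np.ndarray:
    """Coerce features to an (n, 2) boolean array in (lpm, spm) order."""
    if isinstance(features, pd.DataFrame):
        cols = None
        for pair in (("lpm", "spm"), ("lpm_present", "spm_present")):
            if all(c in features.columns for c in pair):
                cols = pair
                break
        if cols is None:
            raise ValueError(
                "feature frame must contain lpm/spm or lpm_present/spm_present columns"
            )
        X = features[list(cols)].to_numpy()
    else:
        X = np.asarray(features)
    X = X.astype(bool)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("features must be n x 2 (lpm, spm)")
    return X


# ---------------------------------------------------------------------------
# Logistic model


@dataclass(frozen=True)
class LogisticFit:
    """Fitted logistic model on (intercept, lpm, spm).

    ``odds_ratios = exp(coefficients)`` elementwise and
    ``aic = -2*loglik + 2*3`` by construction.  Under separation,
    ``converged`` is False, ``separation_flag`` True and the coefficients
    are capped at +/-15 on the log-odds scale.
    """

    coefficients: np.ndarray  # (intercept, beta_lpm, beta_spm)
    standard_errors: np.ndarray
    ci_level: float
    coef_cis: np.ndarray  # (3, 2)
    odds_ratios: np.ndarray
    or_cis: np.ndarray
    p_values: np.ndarray
    loglik: float
    aic: float
    converged: bool
    separation_flag: bool
    names: tuple[str, ...] = ("intercept", "lpm", "spm")

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.coefficients,
                "std_err": self.standard_errors,
                "ci_low": self.coef_cis[:, 0],
                "ci_high": self.coef_cis[:, 1],
                "odds_ratio": self.odds_ratios,
                "or_ci_low": self.or_cis[:, 0],
                "or_ci_high": self.or_cis[:, 1],
                "p_value": self.p_values,
            },
            index=list(self.names),
        )


def _aggregate_cells(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse observations onto the 4 (lpm, spm) cells.

    Returns (design, counts): design rows [1, lpm, spm] for each occupied
    cell and counts rows [n_pos, n_neg].
    """
    design, counts = [], []
    for l in (0, 1):
        for s in (0, 1):
            in_cell = (X[:, 0] == l) & (X[:, 1] == s)
            n = int(in_cell.sum())
            if n == 0:
                continue
            n_pos = int(y[in_cell].sum())
            design.append([1.0, float(l), float(s)])
            counts.append([n_pos, n - n_pos])
    return np.asarray(design), np.asarray(counts, dtype=float)


def fit_logistic(features, labels, ci_level: float = 0.95) -> LogisticFit:
    """Maximum-likelihood logistic fit of CSB on the two binary markers.

    The fit runs IRLS on the aggregated 2x2x2 count table (identical
    likelihood to the per-observation fit, orders of magnitude faster).
    The log-likelihood and AIC are computed on the Bernoulli scale so they
    match a per-observation glm fit.

    Raises
    ------
    FitError
        If labels contain a single class.
    """
    X = _as_feature_matrix(features)
    y = np.asarray(labels).astype(bool)
    if y.all() or (~y).all():
        raise FitError("labels contain a single class; logistic fit undefined")

    design, counts = _aggregate_cells(X, y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(counts, design, family=sm.families.Binomial())
        res = model.fit(maxiter=_MAX_IRLS_ITER, tol=1e-10)
    params = np.asarray(res.params, dtype=float)
    converged = bool(getattr(res, "converged", True))
    separation = (not converged) or bool(np.any(np.abs(params) > _COEF_CAP))
    coefficients = params
    if separation:
        # rescale the whole coefficient vector so the largest log-odds is
        # capped: the separating decision boundary is preserved while the
        # reported magnitudes stay finite and clearly flagged
        coefficients = params * (_COEF_CAP / np.max(np.abs(params)))

    se = np.asarray(res.bse, dtype=float)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    coef_cis = np.column_stack([coefficients - z * se, coefficients + z * se])
    if separation:
        # Wald intervals are meaningless under separation; report them on
        # the same capped log-odds scale as the coefficients
        coef_cis = np.clip(coef_cis, -_COEF_CAP, _COEF_CAP)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_values = np.where(
            se > 0, 2.0 * stats.norm.sf(np.abs(coefficients) / np.where(se > 0, se, 1.0)), np.nan
        )

    # Bernoulli log-likelihood at the reported (possibly capped) coefficients
    eta = design @ coefficients
    p = 1.0 / (1.0 + np.exp(-eta))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    loglik = float(np.sum(counts[:, 0] * np.log(p) + counts[:, 1] * np.log(1.0 - p)))
    aic = -2.0 * loglik + 2.0 * coefficients.size

    return LogisticFit(
        coefficients=coefficients,
        standard_errors=se,
        ci_level=ci_level,
        coef_cis=coef_cis,
        odds_ratios=np.exp(coefficients),
        or_cis=np.exp(coef_cis),
        p_values=p_values,
        loglik=loglik,
        aic=aic,
        converged=converged and not separation,
        separation_flag=separation,
    )


# ---------------------------------------------------------------------------
# CART


@dataclass(frozen=True)
class TreeNode:
    """Internal node (``feature`` set) or leaf (``feature`` is None)."""

    feature: str | None = None
    absent: "TreeNode | None" = None  # feature == False branch
    present: "TreeNode | None" = None  # feature == True branch
    label: bool | None = None
    error_rate: float | None = None
    n: int | None = None
    p_pos: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass(frozen=True)
class TreeModel:
    """A fitted CART classifier over the two binary features."""

    root: TreeNode
    feature_names: tuple[str, ...] = FEATURE_ORDER

    def leaves(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend([node.present, node.absent])
        return out

    def rules(self) -> list[str]:
        """Human-readable branch rules, depth-first."""
        lines: list[str] = []

        def walk(node: TreeNode, conds: list[str]):
            if node.is_leaf:
                cond = " and ".join(conds) if conds else "always"
                lines.append(
                    f"if {cond} -> {'CSB' if node.label else 'no CSB'} "
                    f"(training error {node.error_rate:.3f}, n={node.n})"
                )
                return
            walk(node.absent, conds + [f"{node.feature} absent"])
            walk(node.present, conds + [f"{node.feature} present"])

        walk(self.root, [])
        return lines


def _gini(n_pos: float, n_neg: float) -> float:
    n = n_pos + n_neg
    if n == 0:
        return 0.0
    p = n_pos / n
    return 2.0 * p * (1.0 - p)


def _leaf(y: np.ndarray) -> TreeNode:
    n = y.size
    n_pos = int(y.sum())
    label = n_pos > n - n_pos  # ties default to the negative (no-CSB) class
    err = min(n_pos, n - n_pos) / n if n else 0.0
    return TreeNode(label=bool(label), error_rate=err, n=n, p_pos=n_pos / n if n else 0.0)


def _grow(X: np.ndarray, y: np.ndarray, available: tuple[int, ...]) -> TreeNode:
    if y.size == 0 or not available or len(np.unique(y)) == 1:
        return _leaf(y)
    parent_imp = _gini(y.sum(), y.size - y.sum())
    best = None
    for j in available:  # feature order breaks ties (lpm first)
        mask = X[:, j]
        n1, n0 = int(mask.sum()), int((~mask).sum())
        if n1 == 0 or n0 == 0:
            continue
        child_imp = (
            n0 * _gini(y[~mask].sum(), n0 - y[~mask].sum())
            + n1 * _gini(y[mask].sum(), n1 - y[mask].sum())
        ) / y.size
        gain = parent_imp - child_imp
        if best is None or gain > best[0] + 1e-12:
            best = (gain, j, mask)
    if best is None or best[0] <= 1e-12:  # zero-gain guard
        return _leaf(y)
    _, j, mask = best
    remaining = tuple(k for k in available if k != j)
    return TreeNode(
        feature=FEATURE_ORDER[j],
        absent=_grow(X[~mask], y[~mask], remaining),
        present=_grow(X[mask], y[mask], remaining),
    )


def _prune_same_label(node: TreeNode) -> TreeNode:
    """Collapse subtrees whose leaves all predict the same class.

    Such splits cannot change any prediction; removing them yields the
    minimal, clinically readable rule.
    """
    if node.is_leaf:
        return node
    absent = _prune_same_label(node.absent)
    present = _prune_same_label(node.present)
    if absent.is_leaf and present.is_leaf and absent.label == present.label:
        n = absent.n + present.n
        n_pos = absent.p_pos * absent.n + present.p_pos * present.n
        return TreeNode(
            label=absent.label,
            error_rate=min(n_pos, n - n_pos) / n if n else 0.0,
            n=n,
            p_pos=n_pos / n if n else 0.0,
        )
    return TreeNode(feature=node.feature, absent=absent, present=present)


def fit_cart(features, labels) -> TreeModel:
    """Grow the CART classifier (Gini impurity, zero-gain guard, depth <= 2).

    Splits whose leaves agree on the predicted class are pruned away; the
    result is the minimal rule with identical predictions.  Single-class
    labels yield a single-leaf tree.
    """
    X = _as_feature_matrix(features)
    y = np.asarray(labels).astype(bool)
    if y.size == 0:
        raise FitError("cannot fit a tree on an empty dataset")
    return TreeModel(root=_prune_same_label(_grow(X, y, (0, 1))))


# ---------------------------------------------------------------------------
# Prediction


def predict_proba(model: LogisticFit | TreeModel, features) -> np.ndarray:
    """P(CSB) per segment: inverse-logit for the logistic model, leaf
    training positive fraction for the tree."""
    X = _as_feature_matrix(features)
    if isinstance(model, LogisticFit):
        eta = model.coefficients[0] + X[:, 0] * model.coefficients[1] + X[:, 1] * model.coefficients[2]
        return 1.0 / (1.0 + np.exp(-eta))
    if isinstance(model, TreeModel):
        out = np.empty(X.shape[0])
        for i, row in enumerate(X):
            node = model.root
            while not node.is_leaf:
                j = FEATURE_ORDER.index(node.feature)
                node = node.present if row[j] else node.absent
            out[i] = node.p_pos
        return out
    raise TypeError(f"unsupported model type: {type(model)!r}")


def predict(model: LogisticFit | TreeModel, features) -> np.ndarray:
    """Predicted labels: logistic at the 0.5 probability threshold, tree by
    leaf majority class."""
    X = _as_feature_matrix(features)
    if isinstance(model, LogisticFit):
        return predict_proba(model, X) >= 0.5
    if isinstance(model, TreeModel):
        out = np.empty(X.shape[0], dtype=bool)
        for i, row in enumerate(X):
            node = model.root
            while not node.is_leaf:
                j = FEATURE_ORDER.index(node.feature)
                node = node.present if row[j] else node.absent
            out[i] = node.label
        return out
    raise TypeError(f"unsupported model type: {type(model)!r}")


# ---------------------------------------------------------------------------
# Validation harness


def split_train_test(
    dataset: pd.DataFrame, fraction: float = 0.5, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded uniform split without replacement.

    ``floor(fraction * n)`` rows go to training; an odd row goes to the
    test set.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(dataset)
    perm = rng.permutation(n)
    n_train = int(np.floor(fraction * n))
    return (
        dataset.iloc[perm[:n_train]].reset_index(drop=True),
        dataset.iloc[perm[n_train:]].reset_index(drop=True),
    )


@dataclass
class CVResult:
    """Repeated k-fold cross-validation output.

    ``fold_metrics`` has ``repeats * folds`` entries; ``fold_test_indices``
    records the test block of each fold, so each observation appears in
    test exactly ``repeats`` times.  ``mean``/``std`` aggregate each metric
    over the folds where it was defined.
    """

    fold_metrics: list[MetricSet]
    fold_test_indices: list[np.ndarray]
    repeats: int
    folds: int
    seed: int | None
    model_kind: str

    @property
    def n_fold_records(self) -> int:
        return len(self.fold_metrics)

    def _collect(self, name: str) -> np.ndarray:
        vals = [getattr(m, name) for m in self.fold_metrics]
        return np.array([v for v in vals if v is not None], dtype=float)

    @property
    def mean(self) -> dict:
        return {
            name: (float(v.mean()) if v.size else None)
            for name in _CV_METRICS
            for v in [self._collect(name)]
        }

    @property
    def std(self) -> dict:
        return {
            name: (float(v.std(ddof=1)) if v.size > 1 else None)
            for name in _CV_METRICS
            for v in [self._collect(name)]
        }


_CV_METRICS = ("tpr", "tnr", "ppv", "npv", "bac", "auc", "fnr", "fpr", "mmce", "ber", "kappa")


def _fit_model(kind: str, X: np.ndarray, y: np.ndarray):
    if kind == "logistic":
        return fit_logistic(X, y)
    if kind == "cart":
        return fit_cart(X, y)
    raise ValueError(f"unknown model kind {kind!r}; use 'logistic' or 'cart'")


def evaluate(model, features, labels, ci_level: float = 0.95) -> tuple[ConfusionMatrix, MetricSet]:
    """Confusion matrix and full metric suite of a fitted model on data."""
    X = _as_feature_matrix(features)
    y = np.asarray(labels).astype(bool)
    pred = predict(model, X)
    cm = ConfusionMatrix.from_labels(y, pred)
    auc = roc_auc(predict_proba(model, X), y)
    kappa, kappa_ci = cohens_kappa(cm, ci_level)
    ms = confusion_metrics(cm, auc=auc)
    from dataclasses import replace

    return cm, replace(ms, kappa=kappa, kappa_ci=kappa_ci)


def cross_validate(
    features,
    labels,
    model_kind: str = "logistic",
    repeats: int = 10,
    folds: int = 10,
    seed: int | None = None,
) -> CVResult:
    """Repeated k-fold cross-validation (default 10 x 10).

    For each repeat the observations are re-partitioned (seeded) into
    ``folds`` near-equal blocks; each block serves once as the test set.
    Fold-wise metric sets are kept and averaged; metrics undefined on a
    fold (missing class) are simply absent from that fold's record.
    """
    X = _as_feature_matrix(features)
    y = np.asarray(labels).astype(bool)
    n = y.size
    if n < folds:
        raise ValueError(f"need at least {folds} observations for {folds}-fold CV")
    rng = np.random.default_rng(seed)

    fold_metrics: list[MetricSet] = []
    fold_test_indices: list[np.ndarray] = []
    for _ in range(repeats):
        perm = rng.permutation(n)
        for block in np.array_split(perm, folds):
            test_mask = np.zeros(n, dtype=bool)
            test_mask[block] = True
            try:
                model = _fit_model(model_kind, X[~test_mask], y[~test_mask])
            except FitError:
                fold_metrics.append(MetricSet(*([None] * 9)))
                fold_test_indices.append(block)
                continue
            _, ms = evaluate(model, X[test_mask], y[test_mask])
            fold_metrics.append(ms)
            fold_test_indices.append(block)
    return CVResult(
        fold_metrics=fold_metrics,
        fold_test_indices=fold_test_indices,
        repeats=repeats,
        folds=folds,
        seed=seed,
        model_kind=model_kind,
    )
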