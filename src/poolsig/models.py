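"""Classifier suite: single models (DT, LR, ANN80, ANN100) and composites.

The pooled cohort is split into train/test partitions many times; the
best-balanced splits (fewest variables differing between train and test)
form the cross-validation sets.  Decision trees use Gini impurity with
cost-complexity pruning chosen by internal 10-fold cross-validation;
logistic regression carries a small ridge penalty against separation; the
neural networks are single-hidden-layer perceptrons where "over-training
prevention" holds out a fraction 1-f of the training rows for
accuracy-based early stopping (f = 1 disables it).  Composites use the
tree's positively important variables as input to an LR or ANN head.

Evaluation reports accuracy at threshold 0.5 and the rank (Mann-Whitney)
formulation of the ROC AUC, both in percent, together with the
train-minus-test extrapolation differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .ranking import mannwhitney_p, mannwhitney_p_rows

SINGLE_KINDS = ("dt", "lr", "ann80", "ann100")
COMPOSITE_KINDS = ("dl", "da80", "da100")


def auc_rank(scores, labels) -> float | None:
    """ROC AUC via the rank (Mann-Whitney) formulation with midranks.

    Returns None when only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = labels.sum()
    n0 = (~labels).sum()
    if n1 == 0 or n0 == 0:
        return None
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class Split:
    """One train/test partition with its variable-balance report."""

    train_ids: list
    test_ids: list
    balance: pd.DataFrame | None = None  # variable, p, flagged

    def imbalance_count(self, alpha: float = 0.05) -> int:
        if self.balance is None:
            raise ValueError("balance_check has not been run for this split")
        return int((self.balance["p"] < alpha).sum())


def make_splits(
    sample_ids,
    sizes: tuple[int, int] = (370, 387),
    rounds: int = 400,
    rng: np.random.Generator | int | None = None,
) -> list[Split]:
    """Independent uniform train/test partitions, ``rounds`` of them."""
    sample_ids = np.asarray(sample_ids)
    n_train, n_test = sizes
    if n_train + n_test != len(sample_ids):
        raise ValueError(
            f"split sizes {sizes} do not sum to the population size {len(sample_ids)}"
        )
    if n_train < 1 or n_test < 1:
        raise ValueError("both partitions must be non-empty")
    rng = np.random.default_rng(rng)
    out = []
    for _ in range(rounds):
        perm = rng.permutation(len(sample_ids))
        out.append(
            Split(list(sample_ids[perm[:n_train]]), list(sample_ids[perm[n_train:]]))
        )
    return out


def balance_check(
    split: Split, data: pd.DataFrame, categorical: tuple[str, ...] = ()
) -> pd.DataFrame:
    """Train-vs-test balance p-values for every variable.

    Continuous variables use the Mann-Whitney test, categorical ones a
    chi-square on the contingency table.  Constant variables record p = 1
    and are flagged.  The report is stored on the split.
    """
    tr = data.loc[split.train_ids]
    te = data.loc[split.test_ids]
    results: dict[str, tuple[float, bool]] = {}

    # continuous, complete columns take a vectorized path (one rank pass)
    cont = [c for c in data.columns if c not in categorical]
    bulk = [c for c in cont if not data[c].isna().any() and data[c].nunique() > 1]
    if bulk:
        mat = np.vstack([
            np.r_[tr[c].to_numpy(dtype=float), te[c].to_numpy(dtype=float)] for c in bulk
        ])
        labels = np.r_[np.ones(len(tr), bool), np.zeros(len(te), bool)]
        for c, p in zip(bulk, mannwhitney_p_rows(mat, labels)):
            results[c] = (float(p), False)

    for col in data.columns:
        if col in results:
            continue
        a, b = tr[col].dropna(), te[col].dropna()
        pooled = pd.concat([a, b])
        if pooled.nunique() <= 1:
            results[col] = (1.0, True)
            continue
        if col in categorical:
            tab = pd.crosstab(
                np.r_[np.zeros(len(a), int), np.ones(len(b), int)],
                pooled.to_numpy(),
            )
            p = float(stats.chi2_contingency(tab.to_numpy())[1])
        else:
            p = mannwhitney_p(a.to_numpy(), b.to_numpy())
        results[col] = (p, False)

    report = pd.DataFrame(
        [(c, *results[c]) for c in data.columns], columns=["variable", "p", "flagged"]
    )
    split.balance = report
    return report


def select_cv_sets(splits: list[Split], m: int = 20, alpha: float = 0.05) -> list[Split]:
    """Keep the m best-balanced splits (fewest p < alpha variables).

    Ties resolve by split index, so selection is deterministic.
    """
    if len(splits) < m:
        raise ValueError(f"need at least {m} candidate splits, have {len(splits)}")
    order = sorted(range(len(splits)), key=lambda i: (splits[i].imbalance_count(alpha), i))
    return [splits[i] for i in order[:m]]


@dataclass
class TrainedModel:
    """A fitted classifier plus per-variable importances."""

    kind: str
    estimator: object
    scaler: StandardScaler | None
    variables: list[str]
    importance: pd.Series
    f: float = 1.0
    selected_variables: list[str] | None = None  # composite: DT-chosen subset

    def predict_proba(self, data: pd.DataFrame) -> np.ndarray:
        x = data[self.variables].to_numpy(dtype=float)
        if self.scaler is not None:
            x = self.scaler.transform(x)
        return self.estimator.predict_proba(x)[:, 1]


def _check_labels(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("training labels are single-class")


def fit_dt(
    data: pd.DataFrame, labels, seed: int = 0, min_leaf: int = 5, cv: int = 10
) -> TrainedModel:
    """CART-style tree: Gini impurity, minimum leaf size, cost-complexity
    pruning selected by internal 10-fold cross-validation on the training set.

    Importance is the (normalized) total impurity decrease per variable;
    unused variables score exactly 0.
    """
    x = data.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_labels(y)
    base = DecisionTreeClassifier(
        criterion="gini", min_samples_leaf=min_leaf, random_state=seed
    )
    path = base.cost_complexity_pruning_path(x, y)
    alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
    if len(alphas) > 1:
        kf = KFold(n_splits=min(cv, len(y)), shuffle=True, random_state=seed)
        folds = list(kf.split(x))
        mean_acc = []
        for a in alphas:
            accs = []
            for tr, va in folds:
                clf = DecisionTreeClassifier(
                    criterion="gini",
                    min_samples_leaf=min_leaf,
                    random_state=seed,
                    ccp_alpha=a,
                )
                if len(np.unique(y[tr])) < 2:
                    continue
                clf.fit(x[tr], y[tr])
                accs.append((clf.predict(x[va]) == y[va]).mean())
            mean_acc.append(np.mean(accs) if accs else -np.inf)
        mean_acc = np.asarray(mean_acc)
        # ties resolve to the largest alpha (simplest tree)
        best = len(mean_acc) - 1 - np.argmax(mean_acc[::-1])
        alpha = alphas[best]
    else:
        alpha = alphas[0]
    clf = DecisionTreeClassifier(
        criterion="gini", min_samples_leaf=min_leaf, random_state=seed, ccp_alpha=alpha
    )
    clf.fit(x, y)
    imp = pd.Series(clf.feature_importances_, index=data.columns, name="importance")
    return TrainedModel("dt", clf, None, list(data.columns), imp)


def fit_lr(data: pd.DataFrame, labels, ridge: float = 1e-4, max_iter: int = 2000) -> TrainedModel:
    """Ridge-guarded maximum-likelihood logistic regression on standardized
    inputs; importance is |coefficient| on the standardized scale."""
    x = data.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_labels(y)
    scaler = StandardScaler().fit(x)
    xs = scaler.transform(x)
    clf = LogisticRegression(C=1.0 / ridge, max_iter=max_iter, solver="lbfgs")
    clf.fit(xs, y)
    if clf.n_iter_[0] >= max_iter:
        raise RuntimeError(
            f"logistic regression did not converge in {max_iter} iterations "
            f"(|coef| max {np.abs(clf.coef_).max():.3g})"
        )
    imp = pd.Series(np.abs(clf.coef_[0]), index=data.columns, name="importance")
    return TrainedModel("lr", clf, scaler, list(data.columns), imp)


def _permutation_importance(
    est, x: np.ndarray, y: np.ndarray, columns, rng: np.random.Generator, repeats: int = 10
) -> pd.Series:
    """Mean decrease in training accuracy under within-column permutation."""
    base = (est.predict(x) == y).mean()
    imp = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        drops = []
        for _ in range(repeats):
            xp = x.copy()
            xp[:, j] = xp[rng.permutation(len(y)), j]
            drops.append(base - (est.predict(xp) == y).mean())
        imp[j] = np.mean(drops)
    return pd.Series(imp, index=columns, name="importance")


def fit_ann(
    data: pd.DataFrame,
    labels,
    f: float = 0.8,
    hidden: int = 10,
    seed: int = 0,
    max_iter: int = 400,
    patience: int = 20,
) -> TrainedModel:
    """Single-hidden-layer perceptron with logistic activations.

    With f < 1 a fraction 1-f of training rows is an internal validation
    holdout; training stops at the best internal-validation score with the
    given patience (over-training prevention).  f = 1 trains for the fixed
    epoch budget.  Importance is the mean decrease in training accuracy
    under within-column permutation (10 permutations, seeded).
    """
    if not 0 < f <= 1:
        raise ValueError("prevention fraction f must be in (0, 1]")
    x = data.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_labels(y)
    scaler = StandardScaler().fit(x)
    xs = scaler.transform(x)
    clf = MLPClassifier(
        hidden_layer_sizes=(hidden,),
        activation="logistic",
        solver="adam",
        learning_rate_init=0.01,
        max_iter=max_iter,
        random_state=seed,
        early_stopping=f < 1,
        validation_fraction=1 - f if f < 1 else 0.1,
        n_iter_no_change=patience if f < 1 else max_iter,
    )
    with warnings.catch_warnings():
        # f = 1 trains a fixed epoch budget; hitting it is by design
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        clf.fit(xs, y)
    kind = "ann80" if abs(f - 0.8) < 1e-12 else ("ann100" if f == 1 else f"ann{int(round(f * 100))}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    imp = _permutation_importance(clf, xs, y, data.columns, rng)
    return TrainedModel(kind, clf, scaler, list(data.columns), imp, f=f)


def fit_composite(
    data: pd.DataFrame,
    labels,
    head: str = "lr",
    f: float = 0.8,
    seed: int = 0,
    fallback_genes: list[str] | None = None,
) -> TrainedModel:
    """DT-selected variables feed an LR or ANN head (DL, DA80, DA100).

    If the pruned tree selects no variables, falls back to the first ten
    entries of ``fallback_genes`` (the ranking order).
    """
    dt = fit_dt(data, labels, seed=seed)
    chosen = list(dt.importance.index[dt.importance > 0])
    if not chosen:
        if fallback_genes is None:
            raise ValueError("tree selected no variables and no fallback was given")
        chosen = list(fallback_genes[:10])
    sub = data[chosen]
    if head == "lr":
        model = fit_lr(sub, labels)
        kind = "dl"
    elif head == "ann":
        model = fit_ann(sub, labels, f=f, seed=seed)
        kind = "da80" if f < 1 else "da100"
    else:
        raise ValueError(f"unknown head {head!r}")
    model.kind = kind
    model.selected_variables = chosen
    return model


def fit_model(
    kind: str, data: pd.DataFrame, labels, seed: int = 0, fallback_genes=None
) -> TrainedModel:
    """Dispatch on the model kind names used throughout the pipeline."""
    kind = kind.lower()
    if kind == "dt":
        return fit_dt(data, labels, seed=seed)
    if kind == "lr":
        return fit_lr(data, labels)
    if kind == "ann80":
        return fit_ann(data, labels, f=0.8, seed=seed)
    if kind == "ann100":
        return fit_ann(data, labels, f=1.0, seed=seed)
    if kind == "dl":
        return fit_composite(data, labels, head="lr", seed=seed, fallback_genes=fallback_genes)
    if kind == "da80":
        return fit_composite(data, labels, head="ann", f=0.8, seed=seed, fallback_genes=fallback_genes)
    if kind == "da100":
        return fit_composite(data, labels, head="ann", f=1.0, seed=seed, fallback_genes=fallback_genes)
    raise ValueError(f"unknown model kind {kind!r}")


@dataclass
class EvalReport:
    """Train/test accuracy and AUC (percent) with extrapolation deltas."""

    kind: str
    acc_train: float
    acc_test: float
    auc_train: float | None
    auc_test: float | None
    auc_missing: bool = False

    @property
    def d_acc(self) -> float:
        return self.acc_train - self.acc_test

    @property
    def d_auc(self) -> float | None:
        if self.auc_train is None or self.auc_test is None:
            return None
        return self.auc_train - self.auc_test

    def as_row(self) -> dict:
        return {
            "model": self.kind,
            "acc_train": self.acc_train,
            "acc_test": self.acc_test,
            "d_acc": self.d_acc,
            "auc_train": self.auc_train,
            "auc_test": self.auc_test,
            "d_auc": self.d_auc,
        }


def evaluate(
    model: TrainedModel,
    train: pd.DataFrame,
    y_train,
    test: pd.DataFrame,
    y_test,
    threshold: float = 0.5,
) -> EvalReport:
    """ACC at the probability threshold and rank-formulation AUC, in percent."""
    if len(train) == 0 or len(test) == 0:
        raise ValueError("empty evaluation set")
    y_tr = np.asarray(y_train, dtype=int)
    y_te = np.asarray(y_test, dtype=int)
    p_tr = model.predict_proba(train)
    p_te = model.predict_proba(test)
    acc_tr = float(((p_tr >= threshold).astype(int) == y_tr).mean() * 100)
    acc_te = float(((p_te >= threshold).astype(int) == y_te).mean() * 100)
    auc_tr = auc_rank(p_tr, y_tr)
    auc_te = auc_rank(p_te, y_te)
    return EvalReport(
        model.kind,
        acc_tr,
        acc_te,
        None if auc_tr is None else auc_tr * 100,
        None if auc_te is None else auc_te * 100,
        auc_missing=auc_tr is None or auc_te is None,
    )


def integrate_importance(
    importances: dict[str, pd.Series], tiebreak: pd.Series | None = None
) -> pd.DataFrame:
    """Borda integration: mean of per-model importance ranks (1 = top).

    Variables missing from a model get the worst rank and are flagged; ties
    in the integrated score break by the gene-ranking trimmed-mean p (when
    given), then by variable id.  The output order is the gene-addition
    order used by the signature stage.
    """
    universe = sorted(set().union(*[s.index for s in importances.values()]))
    v = len(universe)
    ranks = {}
    flagged = pd.Series(False, index=universe)
    for kind, imp in importances.items():
        aligned = imp.reindex(universe)
        missing = aligned.isna()
        flagged |= missing
        r = (-aligned).rank(method="average", na_option="bottom")
        r[missing] = v
        ranks[kind] = r
    table = pd.DataFrame(ranks, index=universe)
    table["integrated_score"] = table[list(importances)].mean(axis=1)
    tb = tiebreak.reindex(universe) if tiebreak is not None else pd.Series(0.0, index=universe)
    order = sorted(universe, key=lambda g: (table.at[g, "integrated_score"], tb[g], g))
    table = table.loc[order]
    table["integrated_rank"] = np.arange(1, v + 1)
    table["flagged"] = flagged.loc[order]
    table.index.name = "variable"
    return table
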