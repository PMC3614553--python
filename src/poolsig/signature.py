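"""Incremental standardized-Cox gene signature and survival comparison.

Genes are added one at a time in importance order to a Cox proportional
hazards fit on the training set; each fit's standardized coefficients
define a risk score applied unchanged to the test set; the gene count
maximizing test AUC against the five-year relapse label is the signature
size.  A sensitivity-constrained cutoff dichotomizes the score into high
and low recurrence-risk groups which are compared by Kaplan-Meier curves,
the log-rank test, unadjusted and clinically adjusted hazard ratios and
the net reclassification improvement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test

from .models import auc_rank


@dataclass
class CoxFit:
    """Standardized Cox coefficients with standard errors."""

    coef: pd.Series  # log hazard per covariate unit
    se: pd.Series
    converged: bool = True

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.coef)

    def ci(self, z: float = 1.959963984540054) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hr": np.exp(self.coef),
                "lo": np.exp(self.coef - z * self.se),
                "hi": np.exp(self.coef + z * self.se),
            }
        )


def cox_fit(
    covariates: pd.DataFrame,
    time,
    event,
    penalizer: float = 1e-6,
) -> CoxFit:
    """Cox proportional-hazards partial-likelihood fit (Efron ties).

    A small ridge penalty guards against monotone likelihood.  Raises on
    non-convergence or degenerate input.
    """
    ev = np.asarray(event, dtype=float)
    if ev.sum() < 1:
        raise ValueError("need at least one event")
    const = [c for c in covariates.columns if covariates[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariates: {const}")
    df = covariates.copy()
    df["_time"] = np.asarray(time, dtype=float)
    df["_event"] = ev
    cph = CoxPHFitter(penalizer=penalizer, l1_ratio=0.0)
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except Exception as exc:
        raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    return CoxFit(coef=cph.params_.copy(), se=cph.standard_errors_.copy())


def risk_score(fit: CoxFit, z: pd.DataFrame) -> pd.Series:
    """Linear predictor sum_j beta_j * z_j with training-derived betas."""
    missing = fit.coef.index.difference(z.columns)
    if len(missing):
        raise KeyError(f"missing covariates in expression data: {list(missing)}")
    return z[fit.coef.index] @ fit.coef


@dataclass
class RiskSignature:
    """Ordered gene subset with the selected size and training fit."""

    ordered_genes: list[str]
    k_star: int
    fit: CoxFit
    cutoff: float | None
    auc_curve: pd.DataFrame  # k, auc_train, auc_test (NaN where a fit failed)
    train_stats: pd.DataFrame  # per-gene train mean/sd used for z-scoring
    skipped_k: list[int] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return self.ordered_genes[: self.k_star]

    def scores(self, expr: pd.DataFrame) -> pd.Series:
        z = standardize_to_train(expr, self.train_stats)
        return risk_score(self.fit, z)


def standardize_to_train(expr: pd.DataFrame, train_stats: pd.DataFrame) -> pd.DataFrame:
    """z-score columns with the training means and SDs (no re-estimation)."""
    mu = train_stats["mean"]
    sd = train_stats["sd"]
    return (expr[train_stats.index] - mu) / sd


def incremental_signature(
    ordered_genes: list[str],
    train_expr: pd.DataFrame,
    train_time,
    train_event,
    train_label5,
    test_expr: pd.DataFrame,
    test_label5,
    k_max: int = 100,
    min_sensitivity: float | None = 0.80,
) -> RiskSignature:
    """Grow the signature gene by gene; keep the size maximizing test AUC.

    For each k the Cox fit uses the training set only; risk scores on both
    sets are evaluated by AUC against the five-year relapse label.  Ties in
    the argmax resolve to the smallest k.  A k whose fit fails is skipped
    and flagged.
    """
    ordered_genes = list(ordered_genes)[:k_max]
    if not ordered_genes:
        raise ValueError("empty gene ordering")
    stats_df = pd.DataFrame(
        {
            "mean": train_expr[ordered_genes].mean(),
            "sd": train_expr[ordered_genes].std(ddof=1),
        }
    )
    if (stats_df["sd"] == 0).any():
        bad = list(stats_df.index[stats_df["sd"] == 0])
        raise ValueError(f"zero-variance genes in the training set: {bad}")
    z_train = standardize_to_train(train_expr, stats_df)
    z_test = standardize_to_train(test_expr, stats_df)

    rows = []
    fits: dict[int, CoxFit] = {}
    skipped = []
    for k in range(1, len(ordered_genes) + 1):
        genes_k = ordered_genes[:k]
        try:
            fit_k = cox_fit(z_train[genes_k], train_time, train_event)
        except (RuntimeError, ValueError):
            skipped.append(k)
            rows.append((k, np.nan, np.nan))
            continue
        fits[k] = fit_k
        s_tr = risk_score(fit_k, z_train)
        s_te = risk_score(fit_k, z_test)
        rows.append(
            (k, auc_rank(s_tr, train_label5), auc_rank(s_te, test_label5))
        )
    curve = pd.DataFrame(rows, columns=["k", "auc_train", "auc_test"])
    if curve["auc_test"].isna().all():
        raise RuntimeError("every incremental Cox fit failed")
    k_star = int(curve.loc[curve["auc_test"].idxmax(), "k"])  # idxmax -> first max
    fit = fits[k_star]
    cutoff = None
    if min_sensitivity is not None:
        cutoff = choose_cutoff(
            risk_score(fit, z_train), np.asarray(train_label5, dtype=bool), min_sensitivity
        )
    return RiskSignature(ordered_genes, k_star, fit, cutoff, curve, stats_df, skipped)


def choose_cutoff(scores, labels, min_sensitivity: float = 0.80) -> float:
    """Highest-specificity threshold with sensitivity >= the floor.

    Candidates are midpoints of adjacent sorted unique scores plus guards
    below the minimum and above the maximum; classification is positive at
    score >= cutoff; ties in specificity resolve to the higher threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise ValueError("both classes required to choose a cutoff")
    uniq = np.unique(scores)
    span = max(uniq[-1] - uniq[0], 1.0)
    cands = np.concatenate(
        [[uniq[0] - 1e-9 * span], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1e-9 * span]]
    )
    best = None
    for c in cands:
        pred = scores >= c
        sens = pred[labels].mean()
        spec = (~pred)[~labels].mean()
        if sens >= min_sensitivity and (
            best is None or spec > best[0] or (spec == best[0] and c > best[1])
        ):
            best = (spec, c)
    if best is None:
        raise ValueError(f"no threshold attains sensitivity >= {min_sensitivity}")
    return float(best[1])


def km_curve(time, event) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate as a (time, survival) step table."""
    t = np.asarray(time, dtype=float)
    if (t < 0).any():
        raise ValueError("negative times")
    km = KaplanMeierFitter()
    km.fit(t, np.asarray(event, dtype=float))
    sf = km.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})


def log_rank(time, event, group) -> tuple[float, float]:
    """Log-rank chi-square statistic and p-value across groups."""
    ev = np.asarray(event, dtype=float)
    g = np.asarray(group)
    if len(np.unique(g)) < 2:
        raise ValueError("need at least two groups")
    if ev.sum() == 0:
        raise ValueError("no events")
    if len(np.unique(g)) == 2:
        a, b = np.unique(g)
        res = logrank_test(
            np.asarray(time)[g == a], np.asarray(time)[g == b], ev[g == a], ev[g == b]
        )
    else:
        res = multivariate_logrank_test(np.asarray(time), g, ev)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class SurvivalSummary:
    """High-vs-low risk survival comparison around the signature."""

    km_high: pd.DataFrame
    km_low: pd.DataFrame
    logrank_stat: float
    logrank_p: float
    hr_univariate: pd.DataFrame  # hr, lo, hi (single row: risk group)
    hr_multivariate: pd.DataFrame  # risk group + clinical adjustments
    nri: float | None = None


def hazard_ratios(
    group,
    clinical: pd.DataFrame,
    time,
    event,
    grade_high_cut: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Univariate and clinically adjusted Cox HRs for the risk-group flag.

    The multivariate fit adjusts for age, tumor diameter, dichotomized
    histopathologic grade (>= ``grade_high_cut``) and estrogen-receptor
    status.
    """
    g = pd.Series(np.asarray(group, dtype=float), index=clinical.index, name="risk_group")
    uni = cox_fit(g.to_frame(), time, event)
    adj = pd.DataFrame(
        {
            "risk_group": g,
            "age": clinical["age"].astype(float),
            "tumor_size": clinical["tumor_size"].astype(float),
            "grade_high": (clinical["grade"].astype(float) >= grade_high_cut).astype(float),
            "er_status": clinical["er_status"].astype(float),
        },
        index=clinical.index,
    )
    multi = cox_fit(adj, time, event)
    return uni.ci(), multi.ci()


def nri(old_categories, new_categories, events) -> float:
    """Net reclassification improvement between two risk categorizations.

    NRI = [P(up|event) - P(down|event)] + [P(down|non-event) - P(up|non-event)]
    where up/down are category moves from old to new.
    """
    old = np.asarray(old_categories, dtype=float)
    new = np.asarray(new_categories, dtype=float)
    ev = np.asarray(events, dtype=bool)
    if old.shape != new.shape or old.shape != ev.shape:
        raise ValueError("categorizations must cover the same subjects")
    if ev.all() or (~ev).all():
        raise ValueError("both event classes required")
    up = new > old
    down = new < old
    ev_term = up[ev].mean() - down[ev].mean()
    ne_term = down[~ev].mean() - up[~ev].mean()
    return float(ev_term + ne_term)
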