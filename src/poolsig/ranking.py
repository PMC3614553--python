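"""Bootstrap trimmed-mean gene ranking.

A fixed-size subject subsample is drawn from the pooled cohort; over B
bootstrap resamples of it, each gene receives a two-sided Mann-Whitney U
p-value comparing relapse vs non-relapse subjects; the top and bottom 5%
of each gene's p-values are trimmed and the remainder averaged; genes are
ranked by that trimmed mean and the smallest-p genes selected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def subsample_subjects(
    sample_ids,
    labels,
    n: int = 200,
    rng: np.random.Generator | int | None = None,
    max_attempts: int = 100,
) -> list:
    """Uniform without-replacement subject subsample containing both classes.

    Redraws (up to ``max_attempts``) if a draw is single-class.
    """
    rng = np.random.default_rng(rng)
    sample_ids = np.asarray(sample_ids)
    labels = np.asarray(labels, dtype=bool)
    if n > len(sample_ids):
        raise ValueError("subsample larger than the population")
    if labels.all() or (~labels).all():
        raise ValueError("population is single-class")
    for _ in range(max_attempts):
        idx = rng.choice(len(sample_ids), size=n, replace=False)
        sub = labels[idx]
        if sub.any() and (~sub).any():
            return list(sample_ids[idx])
    raise ValueError(f"no two-class subsample after {max_attempts} attempts")


def mannwhitney_p(x, y) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact by enumeration when both groups have <= 8 values and no ties occur;
    otherwise the normal approximation with tie and continuity correction.
    Identical pooled values give p = 1 (no signal), never an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(x) <= 8 and len(y) <= 8 and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(min(res.pvalue, 1.0))


def mannwhitney_p_rows(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Mann-Whitney p-values, one per matrix row.

    Normal approximation with midranks, tie correction and continuity
    correction, matching :func:`mannwhitney_p`'s large-sample branch.
    ``values`` is features x subjects; ``labels`` marks group A membership.
    """
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n2 = int((~labels).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    n = n1 + n2
    ranks = stats.rankdata(values, axis=1)
    r1 = ranks[:, labels].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction from the multiplicity of each distinct value per row
    tie_term = np.empty(values.shape[0])
    for i, row in enumerate(values):
        _, counts = np.unique(row, return_counts=True)
        tie_term[i] = (counts.astype(float) ** 3 - counts).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    p = np.ones(values.shape[0])
    ok = sigma2 > 0
    z = (np.abs(u1[ok] - mu) - 0.5) / np.sqrt(sigma2[ok])
    z = np.maximum(z, 0.0)
    p[ok] = np.minimum(2.0 * stats.norm.sf(z), 1.0)
    return p


def bootstrap_pvalues(
    expr: pd.DataFrame,
    labels,
    B: int = 200,
    rng: np.random.Generator | int | None = None,
    max_attempts: int = 100,
) -> pd.DataFrame:
    """Per-gene p-values over B bootstrap resamples of the subjects.

    Each round resamples the subjects with replacement (same size);
    single-class resamples are redrawn so B stays fixed.  Returns a
    genes x B frame; deterministic for a fixed generator state.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(rng)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise ValueError("labels are single-class")
    vals = expr.to_numpy(dtype=float)
    n = vals.shape[1]
    out = np.empty((vals.shape[0], B))
    for b in range(B):
        for _ in range(max_attempts):
            idx = rng.integers(0, n, size=n)
            lab = labels[idx]
            if lab.any() and (~lab).any():
                break
        else:  # pragma: no cover - pathological label balance
            raise ValueError("could not draw a two-class resample")
        out[:, b] = mannwhitney_p_rows(vals[:, idx], lab)
    return pd.DataFrame(out, index=expr.index, columns=[f"b{j + 1:03d}" for j in range(B)])


def trimmed_mean(values, trim: float = 0.05) -> float:
    """Symmetric trimmed mean: drop floor(B*trim) values from each end.

    With B = 200 and trim = 0.05 exactly 180 values remain.
    """
    v = np.sort(np.asarray(values, dtype=float))
    g = int(np.floor(len(v) * trim))
    kept = v[g : len(v) - g] if g else v
    if len(kept) == 0:
        raise ValueError("trimming removed all values")
    return float(kept.mean())


def rank_and_select(trimmed: pd.Series, k: int = 100) -> pd.DataFrame:
    """Rank genes by ascending trimmed-mean p; ties broken by gene id.

    Returns the full ranking with a ``selected`` flag on the top-k genes.
    """
    if k > len(trimmed):
        raise ValueError("k exceeds the number of genes")
    df = pd.DataFrame({"gene_id": trimmed.index, "trimmed_p": trimmed.to_numpy()})
    df = df.sort_values(["trimmed_p", "gene_id"], kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["selected"] = df["rank"] <= k
    return df


def rank_genes(
    expr: pd.DataFrame,
    labels: pd.Series,
    n_subsample: int = 200,
    B: int = 200,
    trim: float = 0.05,
    k: int = 100,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Full ranking stage: subsample, bootstrap, trim, rank, select."""
    rng = np.random.default_rng(rng)
    subset = subsample_subjects(expr.columns, labels.reindex(expr.columns), n_subsample, rng)
    sub_expr = expr[subset]
    sub_labels = labels.reindex(subset)
    pvals = bootstrap_pvalues(sub_expr, sub_labels, B, rng)
    trimmed = pvals.apply(lambda row: trimmed_mean(row, trim), axis=1)
    ranked = rank_and_select(trimmed, k)
    ranked.attrs["bootstrap_rounds"] = B
    return ranked
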