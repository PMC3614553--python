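"""Cross-cohort harmonization and the subject exclusion cascade.

Heterogeneous cohorts are brought onto a common gene-level scale in five
stages: (1) affine-log conversion of linear intensities, y = log2(a*x + b),
per cohort; (2) probe-to-gene collapse by the per-sample median;
(3) per-gene z-standardization within cohort; (4) merging; (5) quantile
normalization over the merged samples.  Input matrices are assumed
background-corrected (a precondition, not a stage here).

Subject selection removes, in order: records with missing relapse status,
lymph-node-positive or node-missing records, and event-free records with
less than five years of follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .io import CohortBundle, ExpressionMatrix


@dataclass
class TransformParams:
    """Affine parameters of the log conversion y = log2(a*x + b)."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("multiplier a must be positive")


@dataclass
class ExclusionReport:
    """Subject counts along the exclusion cascade (non-increasing)."""

    initial: int
    after_missing_relapse: int
    after_node: int
    after_followup: int

    def __post_init__(self) -> None:
        seq = (self.initial, self.after_missing_relapse, self.after_node, self.after_followup)
        if any(b > a for a, b in zip(seq, seq[1:])):
            raise ValueError("cascade counts must be non-increasing")

    @property
    def removed(self) -> tuple[int, int, int]:
        return (
            self.initial - self.after_missing_relapse,
            self.after_missing_relapse - self.after_node,
            self.after_node - self.after_followup,
        )


def apply_affine_log(m: ExpressionMatrix, p: TransformParams) -> ExpressionMatrix:
    """Convert a raw-linear matrix to log2 via y = log2(a*x + b).

    Raises on any non-positive argument, naming the offending cell; no
    silent clipping.
    """
    if m.scale != "raw-linear":
        raise ValueError(f"expected raw-linear input, got {m.scale!r}")
    arg = p.a * m.values.to_numpy() + p.b
    if (arg <= 0).any():
        r, c = np.argwhere(arg <= 0)[0]
        raise ValueError(
            f"affine-log argument non-positive ({arg[r, c]:g}) at feature "
            f"{m.values.index[r]!r}, sample {m.values.columns[c]!r}"
        )
    out = pd.DataFrame(np.log2(arg), index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(out, scale="log2", level=m.level)


def estimate_affine_params(
    cohort: ExpressionMatrix, reference: ExpressionMatrix
) -> TransformParams:
    """Fit (a, b) so log2(a*X + b) matches the reference's mean and SD.

    Derivative-free Nelder-Mead from (a, b) = (1, 0) on the squared distance
    between the (mean, SD) of the converted cohort and of the reference;
    deterministic for fixed inputs.
    """
    if cohort.scale != "raw-linear":
        raise ValueError("cohort matrix must be raw-linear")
    if reference.scale != "log2":
        raise ValueError("reference matrix must be log2")
    x = cohort.values.to_numpy().ravel()
    ref = reference.values.to_numpy().ravel()
    if x.std(ddof=1) == 0 or ref.std(ddof=1) == 0:
        raise ValueError("degenerate (zero-variance) matrix")
    m_ref, s_ref = ref.mean(), ref.std(ddof=1)
    x_min = x.min()

    def objective(theta):
        a, b = theta
        if a <= 0 or a * x_min + b <= 0:
            return 1e12
        y = np.log2(a * x + b)
        return (y.mean() - m_ref) ** 2 + (y.std(ddof=1) - s_ref) ** 2

    if objective((1.0, 0.0)) >= 1e12:
        raise ValueError("no admissible (a, b) from the starting point (1, 0)")
    res = optimize.minimize(
        objective,
        x0=[1.0, 0.0],
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 4000, "maxfev": 8000},
    )
    a, b = res.x
    if a <= 0 or a * x_min + b <= 0:
        raise ValueError("estimation converged to inadmissible (a, b)")
    return TransformParams(float(a), float(b))


def collapse_probes(m: ExpressionMatrix, probe_map: pd.DataFrame) -> ExpressionMatrix:
    """Collapse probes to genes by the per-sample median probe value.

    Even probe counts use the arithmetic mean of the two middle values.
    """
    mapping = probe_map.set_index("probe_id")["gene_id"]
    missing = m.values.index.difference(mapping.index)
    if len(missing):
        raise ValueError(f"probes absent from the map: {list(missing[:5])}")
    genes = mapping.reindex(m.values.index)
    collapsed = m.values.groupby(genes.to_numpy()).median()
    collapsed.index.name = None
    empty = set(probe_map["gene_id"]) - set(collapsed.index)
    if empty:
        raise ValueError(f"genes with zero probes in the matrix: {sorted(empty)[:5]}")
    return ExpressionMatrix(collapsed, scale=m.scale, level="gene")


def z_standardize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene row to mean 0, sample SD 1 (n-1 denominator)."""
    vals = m.values.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=1)
    zero = sd == 0
    if zero.any():
        ids = list(m.values.index[zero][:10])
        raise ValueError(f"zero-variance genes (drop or impute explicitly): {ids}")
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
    return ExpressionMatrix(
        pd.DataFrame(z, index=m.values.index, columns=m.values.columns),
        scale="z",
        level=m.level,
    )


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force all samples onto the mean order-statistic distribution.

    Rank values per sample; replace rank r everywhere by the mean of the
    r-th order statistics across samples; ties within a sample receive the
    mean of the tied ranks' reference values.  Afterwards every sample has
    an identical sorted value vector.
    """
    vals = m.values.to_numpy(dtype=float)
    n_rows, n_cols = vals.shape
    if n_cols < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    order = np.argsort(vals, axis=0, kind="stable")
    ref = np.take_along_axis(vals, order, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(n_cols):
        col = vals[:, j]
        assigned = np.empty(n_rows)
        assigned[order[:, j]] = ref
        # average reference values over ties within the sample
        s = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
        out[:, j] = s
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        scale="qnorm",
        level=m.level,
    )


def apply_exclusions(clinical: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the subject exclusion cascade, reporting counts at each stage.

    Order: missing relapse status; node-positive or node-missing; event-free
    follow-up shorter than five years (subjects relapsing within five years
    are retained).
    """
    n0 = len(clinical)
    t1 = clinical[clinical["relapse_event"].notna()]
    t2 = t1[t1["node_status"].notna() & (t1["node_status"] == 0)]
    short = (t2["relapse_event"] == 0) & (t2["time_years"] < 5.0)
    t3 = t2[~short]
    report = ExclusionReport(n0, len(t1), len(t2), len(t3))
    return t3.reset_index(drop=True), report


def harmonize_pipeline(
    cohorts: list[CohortBundle],
    probe_map: pd.DataFrame,
    reference: int = 0,
    params: str | dict = "given",
    exclude: bool = True,
) -> tuple[CohortBundle, ExclusionReport | None]:
    """Run affine-log -> probe collapse -> z -> merge -> quantile normalization.

    ``params`` selects where affine parameters come from: ``"given"`` uses
    each bundle's recorded (a, b); ``"estimate"`` fits them against the
    reference cohort (itself converted with its given parameters, or
    identity log2); a dict maps cohort_id to TransformParams.  With
    ``exclude`` the subject cascade runs per cohort before any transform.
    """
    if not cohorts:
        raise ValueError("no cohorts")
    report = None
    if exclude:
        merged_clin = pd.concat([b.clinical for b in cohorts], ignore_index=True)
        _, report = apply_exclusions(merged_clin)
        kept = set(report_kept_ids(merged_clin))
        filtered = []
        for b in cohorts:
            keep = b.clinical["sample_id"].isin(kept)
            if keep.sum() == 0:
                raise ValueError(f"cohort {b.cohort_id}: no subjects survive exclusions")
            filtered.append(
                CohortBundle(
                    b.cohort_id,
                    b.expression.subset_samples(b.clinical.loc[keep, "sample_id"]),
                    b.clinical[keep].reset_index(drop=True),
                    list(b.transforms),
                    b.affine_params,
                )
            )
        cohorts = filtered

    gene_mats = []
    provenance = []
    for i, b in enumerate(cohorts):
        m = b.expression
        if m.scale == "raw-linear":
            if isinstance(params, dict):
                p = params[b.cohort_id]
            elif params == "given":
                if b.affine_params is None:
                    raise ValueError(f"cohort {b.cohort_id}: no given affine parameters")
                p = TransformParams(*b.affine_params)
            elif params == "estimate":
                refb = cohorts[reference]
                ref_p = TransformParams(*(refb.affine_params or (1.0, 0.0)))
                ref_log2 = apply_affine_log(refb.expression, ref_p)
                if i == reference:
                    p = ref_p
                else:
                    p = estimate_affine_params(m, ref_log2)
            else:
                raise ValueError(f"unknown params mode {params!r}")
            m = apply_affine_log(m, p)
            provenance.append(f"{b.cohort_id}: affine-log a={p.a:.6g}, b={p.b:.6g}")
        if m.level == "probe":
            m = collapse_probes(m, probe_map)
            provenance.append(f"{b.cohort_id}: median probe collapse")
        m = z_standardize(m)
        provenance.append(f"{b.cohort_id}: per-gene z within cohort")
        gene_mats.append(m)

    idx = gene_mats[0].values.index
    for m in gene_mats[1:]:
        if not m.values.index.equals(idx):
            raise ValueError("cohorts do not share a gene universe")
    merged = pd.concat([m.values for m in gene_mats], axis=1)
    out = quantile_normalize(ExpressionMatrix(merged, scale="z", level="gene"))
    provenance.append("merged; quantile normalization across samples")
    clinical = pd.concat([b.clinical for b in cohorts], ignore_index=True)
    bundle = CohortBundle("merged", out, clinical, provenance)
    return bundle, report


def report_kept_ids(clinical: pd.DataFrame) -> pd.Series:
    """Sample ids surviving the exclusion cascade (helper for subsetting)."""
    filtered, _ = apply_exclusions(clinical)
    return filtered["sample_id"]
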