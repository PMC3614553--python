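"""Synthetic multi-cohort probe-level expression data with survival outcomes.

Emulates a pooled microarray study: several cohorts share one latent
log2 expression scale but each stores its matrix under a distinct affine
distortion of the linear intensities; genes are covered by a variable
number of probes; a minority of genes carries a recurrence signal; and
follow-up is right-censored with lymph-node-positive and missing-value
records present to exercise the downstream exclusion cascade.

Generative model
----------------
Per subject, signal-gene core values are standard normal; survival times
are exponential with hazard ``h0 * exp(sum_s w_s * c_s)`` over the cores
(plus an optional grade term), censoring uniform on ``(0, censor_window)``.
The five-year relapse indicator is derived from the latent event time.
When ``effect_size > 0`` an additive outcome-linked shift is calibrated so
the realized mean difference of each signal gene between relapse classes
equals ``effect_size`` log2 units in expectation; ``effect_size = 0``
leaves the pure proportional-hazards model intact so Cox coefficients are
recoverable at their true values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CLINICAL_COLUMNS, CohortBundle, ExpressionMatrix, write_clinical, write_expression, write_probe_map

DEFAULT_TRANSFORMS = ((1.0, 0.0), (2.2, -8.0), (2.65, -0.1), (1.0, 0.0))


@dataclass
class SimConfig:
    """Parameters of the synthetic pooled-cohort study.

    Defaults mirror the pooled four-cohort design: 922 subjects split
    198/189/249/286, 1-14 probes per gene, a small set of signal genes with
    a 1 log2-unit relapse-class shift, ~6%/yr baseline hazard giving about
    30% five-year relapse, censoring uniform on (0, 25) years (these pooled
    node-negative cohorts carry follow-up out to two decades, so short
    event-free follow-up is the exception rather than the rule).
    """

    n_cohorts: int = 4
    subjects_per_cohort: tuple = (198, 189, 249, 286)
    n_genes: int = 2000
    probes_per_gene_range: tuple = (1, 14)
    n_signal_genes: int = 20
    effect_size: float = 1.0
    hazard_weights: tuple | None = None  # None -> 0.3 per signal gene
    baseline_hazard: float = 0.06
    censor_window: float = 25.0
    node_positive_fraction: float = 0.13
    missing_fraction: float = 0.01
    cohort_transforms: tuple = DEFAULT_TRANSFORMS
    grade_hazard: float = 0.0
    noise_sd: float = 0.3
    probe_offset_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.probes_per_gene_range
        if not (1 <= lo <= hi <= 14):
            raise ValueError("probes_per_gene_range must lie within [1, 14]")
        if self.n_signal_genes > self.n_genes:
            raise ValueError("n_signal_genes exceeds n_genes")
        for name in ("node_positive_fraction", "missing_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if len(self.subjects_per_cohort) != self.n_cohorts:
            raise ValueError("subjects_per_cohort length must equal n_cohorts")
        if any(n < 2 for n in self.subjects_per_cohort):
            raise ValueError("each cohort needs at least 2 subjects")
        if len(self.cohort_transforms) < self.n_cohorts:
            raise ValueError("need one (a, b) transform per cohort")
        if any(a <= 0 for a, _ in self.cohort_transforms[: self.n_cohorts]):
            raise ValueError("affine multiplier a must be positive")
        if self.hazard_weights is not None and len(self.hazard_weights) != self.n_signal_genes:
            raise ValueError("hazard_weights length must equal n_signal_genes")
        if self.n_signal_genes > 0 and self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")

    def resolved_weights(self) -> np.ndarray:
        if self.hazard_weights is not None:
            return np.asarray(self.hazard_weights, dtype=float)
        return np.full(self.n_signal_genes, 0.3)


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery checks."""

    signal_gene_ids: list[str]
    hazard_coefficients: pd.Series  # per gene, exactly 0 off the signal set
    linear_predictor: pd.Series  # per subject
    relapse_prob_5y: pd.Series  # per subject, 1 - exp(-5 h0 e^eta)
    true_relapse_5y: pd.Series  # latent indicator (uncensored)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "linear_predictor": self.linear_predictor,
                "relapse_prob_5y": self.relapse_prob_5y,
                "true_relapse_5y": self.true_relapse_5y.astype(int),
            }
        )


def generate_probe_map(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Assign each gene a uniform number of probes within the configured range.

    Returns a two-column frame (probe_id, gene_id); the map is total and
    surjective onto the genes.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    lo, hi = config.probes_per_gene_range
    gene_ids = [f"g{i:05d}" for i in range(1, config.n_genes + 1)]
    counts = rng.integers(lo, hi + 1, size=config.n_genes)
    probe_ids = [f"{g}_p{j + 1:02d}" for g, c in zip(gene_ids, counts) for j in range(c)]
    genes_rep = np.repeat(gene_ids, counts)
    return pd.DataFrame({"probe_id": probe_ids, "gene_id": genes_rep})


def generate_cohorts(config: SimConfig) -> tuple[list[CohortBundle], GroundTruth, pd.DataFrame]:
    """Generate the cohort bundles, the planted ground truth and the probe map.

    Identical configs (including seed) give byte-identical output.
    """
    config.validate()
    ss = np.random.SeedSequence([config.seed, 0])
    rng = np.random.default_rng(ss)
    probe_map = generate_probe_map(config, np.random.default_rng(np.random.SeedSequence([config.seed, 1])))

    n_total = int(sum(config.subjects_per_cohort))
    gene_ids = [f"g{i:05d}" for i in range(1, config.n_genes + 1)]
    cohort_ids = [f"c{i + 1}" for i in range(config.n_cohorts)]
    cohort_of = np.repeat(np.arange(config.n_cohorts), config.subjects_per_cohort)
    sample_ids = [
        f"{cohort_ids[c]}s{i + 1:03d}"
        for c in range(config.n_cohorts)
        for i in range(config.subjects_per_cohort[c])
    ]

    # latent gene-level log2 values: per-gene baseline + unit-variance cores
    gene_means = rng.normal(7.0, 1.5, size=config.n_genes)
    cores = rng.standard_normal((config.n_genes, n_total))
    signal_idx = np.sort(rng.choice(config.n_genes, size=config.n_signal_genes, replace=False))
    signal_ids = [gene_ids[i] for i in signal_idx]
    weights = config.resolved_weights()

    # clinical covariates, independent of genes except the optional grade link
    age = np.clip(np.round(rng.normal(55, 10, n_total)), 25, 90)
    tumor_size = np.clip(np.round(rng.lognormal(np.log(2.0), 0.4, n_total), 1), 0.3, 10.0)
    grade = rng.choice([1, 2, 3], size=n_total, p=[0.2, 0.45, 0.35])
    er_status = (rng.random(n_total) < 0.75).astype(int)
    node_status = (rng.random(n_total) < config.node_positive_fraction).astype(float)

    # exponential survival over the signal-gene cores
    eta = weights @ cores[signal_idx] if config.n_signal_genes else np.zeros(n_total)
    eta = eta + config.grade_hazard * (grade - 2)
    hazard = config.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.uniform(0.0, config.censor_window, n_total)
    time_obs = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(float)
    relapse5 = t_event <= 5.0

    # calibrated outcome-linked shift: realized class gap == effect_size
    if config.effect_size > 0 and config.n_signal_genes and 0 < relapse5.sum() < n_total:
        gap_natural = cores[signal_idx][:, relapse5].mean(axis=1) - cores[signal_idx][:, ~relapse5].mean(axis=1)
        lam = config.effect_size - gap_natural
        cores[signal_idx] += lam[:, None] * (relapse5 - relapse5.mean())[None, :]

    latent_log2 = gene_means[:, None] + cores

    # probe-level matrix: gene value + fixed probe offset + iid noise
    gene_row = pd.Index(gene_ids).get_indexer(probe_map["gene_id"])
    probe_offsets = rng.normal(0.0, config.probe_offset_sd, size=len(probe_map))
    noise = rng.normal(0.0, config.noise_sd, size=(len(probe_map), n_total))
    probe_log2 = latent_log2[gene_row] + probe_offsets[:, None] + noise

    # missing-value injection limited to node and relapse status
    node_missing = rng.random(n_total) < config.missing_fraction
    relapse_missing = rng.random(n_total) < config.missing_fraction
    node_col = node_status.copy()
    node_col[node_missing] = np.nan
    event_col = event.copy()
    event_col[relapse_missing] = np.nan

    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cohort": [cohort_ids[c] for c in cohort_of],
            "age": age,
            "tumor_size": tumor_size,
            "grade": grade,
            "er_status": er_status,
            "node_status": node_col,
            "relapse_event": event_col,
            "time_years": time_obs,
        },
        columns=CLINICAL_COLUMNS,
    )

    bundles: list[CohortBundle] = []
    for c in range(config.n_cohorts):
        a, b = config.cohort_transforms[c]
        mask = cohort_of == c
        y = probe_log2[:, mask]
        x = (np.exp2(y) - b) / a
        if (x <= 0).any() or ((a * x + b) <= 0).any():
            raise ValueError(
                f"cohort {cohort_ids[c]}: affine parameters (a={a}, b={b}) are "
                "incompatible with the generated expression range "
                "(non-positive linear-scale value)"
            )
        expr = ExpressionMatrix(
            pd.DataFrame(x, index=probe_map["probe_id"].tolist(), columns=[s for s, m in zip(sample_ids, mask) if m]),
            scale="raw-linear",
            level="probe",
        )
        bundle = CohortBundle(
            cohort_id=cohort_ids[c],
            expression=expr,
            clinical=clinical[clinical["cohort"] == cohort_ids[c]].reset_index(drop=True),
            transforms=[f"simulated raw-linear with a={a}, b={b}"],
            affine_params=(a, b),
        )
        bundles.append(bundle)

    truth = GroundTruth(
        signal_gene_ids=signal_ids,
        hazard_coefficients=pd.Series(
            np.zeros(config.n_genes), index=gene_ids, name="hazard_coefficient"
        ).add(pd.Series(weights, index=signal_ids), fill_value=0.0),
        linear_predictor=pd.Series(eta, index=sample_ids, name="linear_predictor"),
        relapse_prob_5y=pd.Series(
            1.0 - np.exp(-5.0 * hazard), index=sample_ids, name="relapse_prob_5y"
        ),
        true_relapse_5y=pd.Series(relapse5, index=sample_ids, name="true_relapse_5y"),
    )
    return bundles, truth, probe_map


def write_cohorts(bundles, truth: GroundTruth, probe_map: pd.DataFrame, outdir) -> None:
    """Serialize cohorts as TSV/CSV plus a ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for b in bundles:
        write_expression(b.expression, outdir / f"{b.cohort_id}_expression.tsv")
        write_clinical(b.clinical, outdir / f"{b.cohort_id}_clinical.csv")
    write_probe_map(probe_map, outdir / "probe_map.tsv")
    truth.to_frame().to_csv(outdir / "ground_truth_subjects.csv", index_label="sample_id")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "signal_gene_ids": truth.signal_gene_ids,
                "hazard_coefficients": {
                    g: truth.hazard_coefficients[g] for g in truth.signal_gene_ids
                },
            },
            fh,
            indent=2,
        )
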