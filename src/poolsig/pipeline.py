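"""End-to-end driver: simulate -> harmonize -> rank -> train -> signature.

Every stage's randomness derives from the single config seed; two runs with
equal configs produce bit-identical artifacts.  Intermediate tables are
written as TSV/CSV with a provenance log of seeds and checksums.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import harmonize, models, ranking, signature as sig
from .io import PipelineConfig, file_checksum, write_clinical, write_expression
from .simulate import SimConfig, generate_cohorts, write_cohorts

log = logging.getLogger("poolsig")


def _child_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


def five_year_label(clinical: pd.DataFrame) -> pd.Series:
    """Relapse within five years: event observed at or before year five."""
    lab = (clinical["relapse_event"] == 1) & (clinical["time_years"] <= 5.0)
    return pd.Series(lab.to_numpy(dtype=bool), index=clinical["sample_id"], name="relapse5")


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Run the full pooled-cohort analysis; returns the result objects.

    Stage order and defaults follow the pooled-study design: subject
    exclusions, five-stage harmonization, 200-subject / 200-round bootstrap
    trimmed-mean ranking with the top 100 genes, 400 candidate train/test
    splits filtered to the best-balanced cross-validation sets, the seven
    classifiers, Borda importance integration, and the incremental Cox
    signature with survival comparison on the held-out test samples.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}

    # --- simulate -----------------------------------------------------
    sim_cfg = SimConfig(**{"seed": _child_seed(config.seed, 0), **config.sim})
    bundles, truth, probe_map = generate_cohorts(sim_cfg)
    log.info("simulated %d cohorts, %d genes, %d probes", len(bundles), sim_cfg.n_genes, len(probe_map))
    if out is not None:
        write_cohorts(bundles, truth, probe_map, out / "cohorts")

    # --- harmonize + exclusions ---------------------------------------
    merged, excl = harmonize.harmonize_pipeline(
        bundles, probe_map, reference=config.reference, params=config.params
    )
    clinical = merged.clinical.set_index("sample_id", drop=False)
    expr = merged.expression.values  # genes x samples
    label5 = five_year_label(merged.clinical)
    log.info("exclusion cascade: %s -> %s retained", excl.initial, excl.after_followup)
    if out is not None:
        write_expression(merged.expression, out / "harmonized_expression.tsv")
        write_clinical(merged.clinical, out / "harmonized_clinical.csv")
        checksums["harmonized_expression.tsv"] = file_checksum(out / "harmonized_expression.tsv")

    # --- gene ranking --------------------------------------------------
    ranked = ranking.rank_genes(
        expr,
        label5,
        n_subsample=min(config.subsample, expr.shape[1]),
        B=config.bootstrap_rounds,
        trim=config.trim,
        k=config.top_genes,
        rng=np.random.default_rng(_child_seed(config.seed, 1)),
    )
    top_genes = ranked.loc[ranked["selected"], "gene_id"].tolist()
    if out is not None:
        ranked.to_csv(out / "ranked_genes.tsv", sep="\t", index=False)
        checksums["ranked_genes.tsv"] = file_checksum(out / "ranked_genes.tsv")

    # --- splits, balance, cross-validation sets ------------------------
    ids = list(expr.columns)
    n = len(ids)
    if config.split_sizes is not None:
        sizes = config.split_sizes
    else:
        n_train = int(round(n * 370 / 757))
        sizes = (n_train, n - n_train)
    splits = models.make_splits(
        ids, sizes, config.split_rounds, np.random.default_rng(_child_seed(config.seed, 2))
    )
    gene_data = expr.loc[top_genes].T  # subjects x genes
    balance_data = gene_data.copy()
    clin_cols = ["age", "tumor_size", "grade", "er_status", "time_years"]
    for c in clin_cols:
        balance_data[c] = clinical.loc[balance_data.index, c].to_numpy()
    balance_data["relapse5"] = label5.reindex(balance_data.index).astype(int).to_numpy()
    for s in splits:
        models.balance_check(s, balance_data, categorical=("grade", "er_status", "relapse5"))
    cv_sets = models.select_cv_sets(splits, config.cv_sets)

    # --- model suite ----------------------------------------------------
    model_seed = _child_seed(config.seed, 3)
    reports: dict[str, list[models.EvalReport]] = {k: [] for k in config.models}
    importances: dict[str, list[pd.Series]] = {k: [] for k in models.SINGLE_KINDS if k in config.models}
    for i, split in enumerate(cv_sets):
        tr, te = gene_data.loc[split.train_ids], gene_data.loc[split.test_ids]
        y_tr = label5.reindex(split.train_ids).to_numpy()
        y_te = label5.reindex(split.test_ids).to_numpy()
        for kind in config.models:
            m = models.fit_model(kind, tr, y_tr, seed=model_seed + i, fallback_genes=top_genes)
            reports[kind].append(models.evaluate(m, tr, y_tr, te, y_te))
            if kind in importances:
                importances[kind].append(m.importance)
    eval_table = pd.DataFrame(
        [
            {
                "model": kind,
                "acc_train": np.mean([r.acc_train for r in rs]),
                "acc_test": np.mean([r.acc_test for r in rs]),
                "d_acc": np.mean([r.d_acc for r in rs]),
                "auc_train": np.mean([r.auc_train for r in rs]),
                "auc_test": np.mean([r.auc_test for r in rs]),
                "d_auc": np.mean([r.d_auc for r in rs]),
            }
            for kind, rs in reports.items()
        ]
    )
    if out is not None:
        eval_table.to_csv(out / "model_evaluation.tsv", sep="\t", index=False)

    # --- importance integration -----------------------------------------
    mean_imp = {k: pd.concat(v, axis=1).mean(axis=1) for k, v in importances.items()}
    tiebreak = ranked.set_index("gene_id")["trimmed_p"]
    integrated = models.integrate_importance(mean_imp, tiebreak=tiebreak)
    ordered_genes = list(integrated.index)
    if out is not None:
        integrated.to_csv(out / "integrated_importance.tsv", sep="\t")

    # --- incremental Cox signature on the best-balanced split ------------
    best = cv_sets[0]
    tr_ids, te_ids = best.train_ids, best.test_ids
    tr_clin = clinical.loc[tr_ids]
    te_clin = clinical.loc[te_ids]
    signature = sig.incremental_signature(
        ordered_genes,
        gene_data.loc[tr_ids],
        tr_clin["time_years"].to_numpy(),
        tr_clin["relapse_event"].to_numpy(dtype=float),
        label5.reindex(tr_ids).to_numpy(),
        gene_data.loc[te_ids],
        label5.reindex(te_ids).to_numpy(),
        k_max=min(config.k_max, len(ordered_genes)),
        min_sensitivity=config.min_sensitivity,
    )
    te_scores = signature.scores(gene_data.loc[te_ids])
    group = (te_scores >= signature.cutoff).astype(int)
    lr_stat, lr_p = sig.log_rank(
        te_clin["time_years"].to_numpy(), te_clin["relapse_event"].to_numpy(dtype=float), group.to_numpy()
    )
    km_high = sig.km_curve(
        te_clin.loc[group == 1, "time_years"], te_clin.loc[group == 1, "relapse_event"]
    )
    km_low = sig.km_curve(
        te_clin.loc[group == 0, "time_years"], te_clin.loc[group == 0, "relapse_event"]
    )
    hr_uni, hr_multi = sig.hazard_ratios(
        group.to_numpy(),
        te_clin,
        te_clin["time_years"].to_numpy(),
        te_clin["relapse_event"].to_numpy(dtype=float),
    )

    # --- reclassification: clinical-only vs clinical + gene signature ----
    def clin_covariates(frame):
        return pd.DataFrame(
            {
                "age": frame["age"].astype(float),
                "tumor_size": frame["tumor_size"].astype(float),
                "grade_high": (frame["grade"].astype(float) >= 3).astype(float),
                "er_status": frame["er_status"].astype(float),
            },
            index=frame.index,
        )

    old_fit = sig.cox_fit(
        clin_covariates(tr_clin),
        tr_clin["time_years"].to_numpy(),
        tr_clin["relapse_event"].to_numpy(dtype=float),
    )
    tr_scores = signature.scores(gene_data.loc[tr_ids])
    new_cov_tr = clin_covariates(tr_clin).assign(gene_score=tr_scores.to_numpy())
    new_fit = sig.cox_fit(
        new_cov_tr, tr_clin["time_years"].to_numpy(), tr_clin["relapse_event"].to_numpy(dtype=float)
    )
    y_tr5 = label5.reindex(tr_ids).to_numpy()
    old_cut = sig.choose_cutoff(
        sig.risk_score(old_fit, clin_covariates(tr_clin)), y_tr5, config.min_sensitivity
    )
    new_cut = sig.choose_cutoff(
        sig.risk_score(new_fit, new_cov_tr), y_tr5, config.min_sensitivity
    )
    old_cat = (sig.risk_score(old_fit, clin_covariates(te_clin)) >= old_cut).astype(int)
    new_cov_te = clin_covariates(te_clin).assign(gene_score=te_scores.to_numpy())
    new_cat = (sig.risk_score(new_fit, new_cov_te) >= new_cut).astype(int)
    nri_value = sig.nri(old_cat.to_numpy(), new_cat.to_numpy(), label5.reindex(te_ids).to_numpy())

    summary = sig.SurvivalSummary(
        km_high=km_high,
        km_low=km_low,
        logrank_stat=lr_stat,
        logrank_p=lr_p,
        hr_univariate=hr_uni,
        hr_multivariate=hr_multi,
        nri=nri_value,
    )

    if out is not None:
        sig_table = pd.DataFrame(
            {
                "gene": signature.genes,
                "order": np.arange(1, signature.k_star + 1),
                "beta": signature.fit.coef.reindex(signature.genes).to_numpy(),
            }
        )
        sig_table.to_csv(out / "signature.tsv", sep="\t", index=False)
        signature.auc_curve.to_csv(out / "signature_auc_curve.tsv", sep="\t", index=False)
        surv_rows = [
            {
                "item": "gene_signature",
                "uni_hr": hr_uni["hr"].iloc[0],
                "uni_lo": hr_uni["lo"].iloc[0],
                "uni_hi": hr_uni["hi"].iloc[0],
                "multi_hr": hr_multi.loc["risk_group", "hr"],
                "multi_lo": hr_multi.loc["risk_group", "lo"],
                "multi_hi": hr_multi.loc["risk_group", "hi"],
                "nri": nri_value,
                "logrank_p": lr_p,
            }
        ]
        pd.DataFrame(surv_rows).to_csv(out / "survival_summary.tsv", sep="\t", index=False)
        config.to_yaml(out / "config.yaml")
        with open(out / "run_log.json", "w") as fh:
            json.dump(
                {
                    "seed": config.seed,
                    "stage_seeds": {
                        "simulate": sim_cfg.seed,
                        "ranking": _child_seed(config.seed, 1),
                        "splits": _child_seed(config.seed, 2),
                        "models": model_seed,
                    },
                    "exclusions": vars(excl),
                    "k_star": signature.k_star,
                    "checksums": checksums,
                },
                fh,
                indent=2,
            )

    return {
        "sim_config": sim_cfg,
        "bundles": bundles,
        "truth": truth,
        "probe_map": probe_map,
        "merged": merged,
        "exclusions": excl,
        "label5": label5,
        "ranked": ranked,
        "top_genes": top_genes,
        "cv_sets": cv_sets,
        "eval_table": eval_table,
        "integrated": integrated,
        "signature": signature,
        "survival": summary,
        "test_ids": te_ids,
        "train_ids": tr_ids,
    }
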