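"""End-to-end orchestration: simulate/read a cohort, classify lifestyles,
compare aging outcomes across classes, decompose twin variance, and write
report tables.

All randomness flows from the config seed; re-running with the same config
reproduces every number exactly.
"""

from __future__ import annotations

import platform
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bch import BCHDistalModel, bch_from_posterior
from .biometrics import TwinBiometricModel, compare_models, pairs_from_cohort
from .cohort import CohortConfig, default_config, generate_cohort
from .indicators import default_indicator_specs
from .io import (
    descriptive_summary,
    read_cohort,
    write_cohort,
    write_json,
    write_report,
    write_truth,
)
from .lca import LatentClassModel, LatentClassResults, select_classes
from .measures import adjust_outcome, icc_by_zygosity
from .shared import decompose_shared, residual_scores


def build_covariate_matrix(
    cohort: pd.DataFrame, covariates: tuple[str, ...] = ("sex", "age", "pds")
) -> np.ndarray:
    """Covariate design columns: sex as coded (female=1), age standardized
    within sample, PDS on its raw 1-3 scale."""
    cols = []
    for name in covariates:
        v = cohort[name].to_numpy(dtype=float)
        if name == "age":
            v = (v - np.nanmean(v)) / np.nanstd(v)
        cols.append(v)
    return np.column_stack(cols) if cols else np.empty((len(cohort), 0))


def shared_variance_analysis(
    cohort: pd.DataFrame,
    outcome: str,
    lca_results: LatentClassResults,
    covariates: tuple[str, ...] = ("sex", "age", "pds"),
    weight_kind: str = "bch",
    model: str = "AE",
    seed: int | None = None,
) -> dict:
    """The full shared-variance chain for one outcome.

    1. adjust the outcome for the covariates (OLS residual);
    2. BCH weights from the class posterior over the whole cohort;
    3. no-covariate weighted distal fit -> class means;
    4. residual scores ``y - sum_k w_ik mu_k``;
    5. biometric fits (default AE) to the adjusted outcome and the residual;
    6. shared/unique decomposition.

    ``weight_kind`` selects BCH weight rows (default) or raw posterior rows
    for the residual expectation.
    """
    y_adj = adjust_outcome(
        cohort[outcome].to_numpy(dtype=float), build_covariate_matrix(cohort, covariates)
    )
    posterior = lca_results.posterior(cohort)
    bchw = bch_from_posterior(posterior)
    rows = bchw.weights if weight_kind == "bch" else posterior
    distal = BCHDistalModel(
        y_adj, bchw.weights, cluster_ids=cohort["family_id"].to_numpy()
    ).fit()
    resid = residual_scores(y_adj, rows, distal.class_means)

    work = cohort[["family_id", "member_index", "zygosity"]].copy()
    work["_total"] = y_adj
    work["_resid"] = resid
    pairs_tot = pairs_from_cohort(work, "_total")
    pairs_res = pairs_from_cohort(work, "_resid")
    fit_tot = TwinBiometricModel(pairs_tot["MZ"], pairs_tot["DZ"], model=model).fit(seed=seed)
    fit_res = TwinBiometricModel(pairs_res["MZ"], pairs_res["DZ"], model=model).fit(seed=seed)
    shares = decompose_shared(fit_tot, fit_res, warn_negative=False)
    return {
        "adjusted_outcome": y_adj,
        "distal": distal,
        "residuals": resid,
        "total_fit": fit_tot,
        "residual_fit": fit_res,
        "shares": shares,
    }


@dataclass
class PipelineConfig:
    """Settings for the one-command synthetic study reproduction."""

    output_dir: str = "twinlca_out"
    cohort_path: str | None = None          # read instead of simulating
    cohort_config: CohortConfig | None = None
    k_min: int = 1
    k_max: int = 6
    chosen_k: int = 5
    n_starts: int = 50
    tol: float = 1e-6
    max_iter: int = 1000
    outcomes: tuple[str, ...] = ("AA_Grim",)
    covariates: tuple[str, ...] = ("sex", "age", "pds")
    extra_covariates: tuple[str, ...] = ()  # e.g. adult BMI for the M2 models
    biometric_models: tuple[str, ...] = ("ACE", "ADE", "AE", "CE", "E")
    decomposition_model: str = "AE"
    weight_kind: str = "bch"
    run_selection: bool = True
    seed: int = 1

    def validate(self, cohort_columns: list[str]) -> None:
        if self.k_min > self.k_max or self.k_min < 1:
            raise ValueError("empty or invalid K range")
        if not (self.k_min <= self.chosen_k <= self.k_max) and self.run_selection:
            raise ValueError("chosen_k outside the K range")
        for col in (*self.outcomes, *self.covariates, *self.extra_covariates):
            if col not in cohort_columns:
                raise ValueError(f"column {col!r} not in the cohort schema")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis chain and write the report bundle.

    Stages: simulate (optional) -> class enumeration -> chosen-K fit ->
    BCH distal models (M1, and M2 when extra covariates are given) -> twin
    ICCs -> biometric model sequence -> shared-variance decomposition.
    Returns the in-memory results; report files are written under
    ``config.output_dir``.
    """
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    if config.cohort_path is not None:
        specs = (
            config.cohort_config.indicator_specs
            if config.cohort_config
            else default_indicator_specs()
        )
        cohort = read_cohort(config.cohort_path, specs)
    else:
        cconf = config.cohort_config or default_config(seed=config.seed)
        specs = cconf.indicator_specs
        cohort, truth = generate_cohort(cconf, return_truth=True)
        write_cohort(cohort, outdir / "cohort.tsv")
        write_truth(truth, outdir / "truth.json")
    config.validate(list(cohort.columns))

    write_report(descriptive_summary(cohort, specs), outdir / "descriptives.tsv")

    results: dict = {"cohort": cohort}
    if config.run_selection:
        selection = select_classes(
            cohort, specs, k_min=config.k_min, k_max=config.k_max,
            n_starts=config.n_starts, tol=config.tol, max_iter=config.max_iter,
            seed=int(rng.integers(2**31 - 1)),
        )
        write_report(selection.drop(columns=["converged"]), outdir / "selection.tsv")
        results["selection"] = selection
        lca_fit = selection.attrs["fits"].get(config.chosen_k)
    else:
        lca_fit = None
    if lca_fit is None:
        lca_fit = LatentClassModel(cohort, specs, config.chosen_k).fit(
            n_starts=config.n_starts, tol=config.tol, max_iter=config.max_iter,
            seed=int(rng.integers(2**31 - 1)),
        )
    results["lca"] = lca_fit
    write_json(
        {
            "K": lca_fit.n_classes,
            "loglik": lca_fit.loglik,
            "pi": lca_fit.pi,
            "avepp": lca_fit.avepp(),
            "ordinal_params": {k: v for k, v in lca_fit.ordinal_params.items()},
            "cont_means": {k: v[0] for k, v in lca_fit.cont_params.items()},
            "cont_vars": {k: v[1] for k, v in lca_fit.cont_params.items()},
            "converged": bool(lca_fit.converged),
        },
        outdir / "lca_fit.json",
    )
    posterior = lca_fit.posterior(cohort)
    post_df = pd.DataFrame(
        posterior, columns=[f"p_class{k + 1}" for k in range(lca_fit.n_classes)]
    )
    post_df.insert(0, "family_id", cohort["family_id"].to_numpy())
    post_df.insert(1, "member_index", cohort["member_index"].to_numpy())
    post_df.to_csv(outdir / "posterior.tsv", sep="\t", index=False, float_format="%.6f")

    bchw = bch_from_posterior(posterior)
    fam = cohort["family_id"].to_numpy()
    icc_rows, distal_rows, wald = [], [], {}
    biometric_tables, share_rows = {}, []
    for outcome in config.outcomes:
        for label, res in icc_by_zygosity(cohort, outcome).items():
            icc_rows.append({
                "outcome": outcome, "zygosity": label, "icc": res.icc,
                "ci_low": res.ci_low, "ci_high": res.ci_high, "n_pairs": res.n_pairs,
            })

        X1 = build_covariate_matrix(cohort, config.covariates)
        y = cohort[outcome].to_numpy(dtype=float)
        m1 = BCHDistalModel(y, bchw.weights, X1, cluster_ids=fam).fit()
        tab = m1.contrasts()
        tab.insert(0, "outcome", outcome)
        tab.insert(1, "model", "M1")
        distal_rows.append(tab)
        wald[f"{outcome}_M1"] = {
            "chi2": m1.wald_stat, "df": m1.wald_df, "p": m1.wald_p,
        }
        if config.extra_covariates:
            X2 = np.column_stack(
                [X1, build_covariate_matrix(cohort, config.extra_covariates)]
            )
            m2 = BCHDistalModel(y, bchw.weights, X2, cluster_ids=fam).fit()
            tab2 = m2.contrasts()
            tab2.insert(0, "outcome", outcome)
            tab2.insert(1, "model", "M2")
            distal_rows.append(tab2)
            wald[f"{outcome}_M2"] = {
                "chi2": m2.wald_stat, "df": m2.wald_df, "p": m2.wald_p,
            }

        y_adj = adjust_outcome(y, X1)
        work = cohort[["family_id", "member_index", "zygosity"]].copy()
        work["_adj"] = y_adj
        pairs = pairs_from_cohort(work, "_adj")
        fits = [
            TwinBiometricModel(pairs["MZ"], pairs["DZ"], model=m).fit(
                seed=int(rng.integers(2**31 - 1))
            )
            for m in config.biometric_models
        ]
        cmp_table = compare_models(fits)
        cmp_table.insert(0, "outcome", outcome)
        biometric_tables[outcome] = cmp_table

        sv = shared_variance_analysis(
            cohort, outcome, lca_fit, covariates=config.covariates,
            weight_kind=config.weight_kind, model=config.decomposition_model,
            seed=int(rng.integers(2**31 - 1)),
        )
        results[f"shared_{outcome}"] = sv
        row = {"outcome": outcome, **sv["shares"].as_dict()}
        share_rows.append(row)

    write_report(pd.DataFrame(icc_rows), outdir / "icc.tsv")
    write_report(pd.concat(distal_rows, ignore_index=True), outdir / "distal_contrasts.tsv")
    write_json(wald, outdir / "wald_tests.json")
    write_report(
        pd.concat(biometric_tables.values(), ignore_index=True), outdir / "biometric.tsv"
    )
    shares_df = pd.DataFrame(share_rows)
    write_report(shares_df, outdir / "shared_variance.tsv")
    write_json({r["outcome"]: r for r in share_rows}, outdir / "shared_variance.json")
    results["icc"] = pd.DataFrame(icc_rows)
    results["biometrics"] = biometric_tables
    results["shares_table"] = shares_df

    manifest = {
        "seed": config.seed,
        "version": __version__,
        "python": platform.python_version(),
        "wall_time_s": round(time.time() - t0, 2),
        "n_individuals": int(len(cohort)),
        "chosen_k": config.chosen_k,
        "n_starts": config.n_starts,
        "tol": config.tol,
        "covariates": list(config.covariates),
        "weight_kind": config.weight_kind,
        "decomposition_model": config.decomposition_model,
    }
    write_json(manifest, outdir / "manifest.json")
    results["manifest"] = manifest
    return results
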