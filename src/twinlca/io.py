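"""Cohort table and report IO.

Cohorts travel as TSV with a documented header, one row per individual,
missing values written as ``NA`` (empty cells also accepted on read).
Configs are YAML; hidden generating truth goes to a JSON sidecar, never into
the primary cohort file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortConfig, OutcomeParams
from .indicators import IndicatorSpec

REQUIRED_COLUMNS = ("family_id", "member_index", "zygosity", "sex", "age", "pds")
_VALID_ZYGOSITY = {"MZ", "DZ_ss", "DZ_os", "DZ"}


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_cohort(
    path: str | Path, specs: list[IndicatorSpec] | None = None
) -> pd.DataFrame:
    """Read and validate a cohort TSV/CSV.

    Checks the required column set, the two-rows-per-family structure, and —
    when indicator specs are given — that ordinal codes lie within their
    declared ranges; violations are reported with the offending row and
    column.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, na_values=["NA", ""])
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"cohort file missing required column {col!r}")
    dupes = df.duplicated(subset=["family_id", "member_index"])
    if dupes.any():
        row = int(np.flatnonzero(dupes.to_numpy())[0])
        raise ValueError(f"duplicate (family_id, member_index) at row {row + 2}")
    bad_zyg = ~df["zygosity"].astype(str).isin(_VALID_ZYGOSITY)
    if bad_zyg.any():
        row = int(np.flatnonzero(bad_zyg.to_numpy())[0])
        raise ValueError(
            f"unknown zygosity {df['zygosity'].iloc[row]!r} at row {row + 2}"
        )
    counts = df.groupby("family_id").size()
    bad_fams = counts[counts != 2]
    if len(bad_fams):
        raise ValueError(
            f"family {bad_fams.index[0]} has {bad_fams.iloc[0]} rows (expected 2)"
        )
    if specs is not None:
        for spec in specs:
            if spec.name not in df.columns:
                raise ValueError(f"cohort file missing indicator column {spec.name!r}")
            if spec.kind == "ordinal":
                col = df[spec.name]
                obs = col.notna()
                bad = obs & (~col.isin(range(spec.n_categories)))
                if bad.any():
                    row = int(np.flatnonzero(bad.to_numpy())[0])
                    raise ValueError(
                        f"ordinal code {col.iloc[row]!r} out of range 0.."
                        f"{spec.n_categories - 1} at row {row + 2}, column {spec.name!r}"
                    )
    return df


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    """Hidden generating quantities as a JSON sidecar."""
    payload = {col: truth[col].tolist() for col in truth.columns}
    Path(path).write_text(json.dumps(payload))


def specs_to_yaml(specs: list[IndicatorSpec], path: str | Path) -> None:
    data = [
        {
            "name": s.name, "kind": s.kind,
            **({"n_categories": s.n_categories} if s.kind == "ordinal" else {}),
            "timepoint": s.timepoint,
        }
        for s in specs
    ]
    Path(path).write_text(yaml.safe_dump(data))


def specs_from_yaml(path: str | Path) -> list[IndicatorSpec]:
    data = yaml.safe_load(Path(path).read_text())
    return [IndicatorSpec(**entry) for entry in data]


def config_to_yaml(config: CohortConfig, path: str | Path) -> None:
    def arr(a):
        return np.asarray(a).tolist()

    data = {
        "n_pairs": config.n_pairs,
        "seed": config.seed,
        "zygosity_probs": arr(config.zygosity_probs),
        "class_props": arr(config.class_props),
        "class_liability_h2": config.class_liability_h2,
        "mean_age": config.mean_age,
        "sd_age": config.sd_age,
        "indicators": [
            {
                "name": s.name, "kind": s.kind,
                **({"n_categories": s.n_categories} if s.kind == "ordinal" else {}),
                "timepoint": s.timepoint,
                **(
                    {"probs": arr(config.indicator_params[s.name]["probs"])}
                    if s.kind == "ordinal"
                    else {
                        "means": arr(config.indicator_params[s.name]["means"]),
                        "sds": arr(config.indicator_params[s.name]["sds"]),
                    }
                ),
            }
            for s in config.indicator_specs
        ],
        "outcomes": {
            name: {
                "class_means": arr(op.class_means),
                "a2": op.a2, "e2": op.e2, "shared_a_frac": op.shared_a_frac,
            }
            for name, op in config.outcome_params.items()
        },
        "covariate_effects": config.covariate_effects,
        "missing_rates": config.missing_rates,
        "missing_covariate_slopes": config.missing_covariate_slopes,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def config_from_yaml(path: str | Path) -> CohortConfig:
    data = yaml.safe_load(Path(path).read_text())
    specs = []
    indicator_params = {}
    for entry in data["indicators"]:
        spec = IndicatorSpec(
            name=entry["name"], kind=entry["kind"],
            n_categories=entry.get("n_categories"),
            timepoint=entry.get("timepoint", ""),
        )
        specs.append(spec)
        if spec.kind == "ordinal":
            indicator_params[spec.name] = {"probs": np.asarray(entry["probs"])}
        else:
            indicator_params[spec.name] = {
                "means": np.asarray(entry["means"]), "sds": np.asarray(entry["sds"]),
            }
    outcomes = {
        name: OutcomeParams(
            class_means=np.asarray(op["class_means"]),
            a2=op["a2"], e2=op["e2"], shared_a_frac=op["shared_a_frac"],
        )
        for name, op in data.get("outcomes", {}).items()
    }
    return CohortConfig(
        n_pairs=data["n_pairs"],
        class_props=np.asarray(data["class_props"]),
        indicator_specs=specs,
        indicator_params=indicator_params,
        outcome_params=outcomes,
        zygosity_probs=tuple(data.get("zygosity_probs", (0.34, 0.33, 0.33))),
        class_liability_h2=data.get("class_liability_h2", 0.5),
        covariate_effects=data.get("covariate_effects", {}),
        missing_rates=data.get("missing_rates", {}),
        missing_covariate_slopes=data.get(
            "missing_covariate_slopes", {"sex": 0.3, "age": 0.2}
        ),
        mean_age=data.get("mean_age", 22.4),
        sd_age=data.get("sd_age", 0.7),
        seed=data.get("seed", 0),
    )


def format_report_table(df: pd.DataFrame) -> pd.DataFrame:
    """Fixed 3-decimal formatting; p-value columns in scientific below 1e-3."""
    out = df.copy()
    for col in out.columns:
        if not pd.api.types.is_float_dtype(out[col]):
            continue
        if col.lower().endswith("_p") or col.lower() in ("p", "pvalue", "wald_p"):
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v)
                else (f"{v:.3e}" if v < 1e-3 else f"{v:.3f}")
            )
        else:
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.3f}")
    return out


def write_report(df: pd.DataFrame, path: str | Path) -> None:
    format_report_table(df).to_csv(path, sep="\t", index=False, na_rep="NA")


def write_json(obj: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))


def descriptive_summary(cohort: pd.DataFrame, specs: list[IndicatorSpec]) -> pd.DataFrame:
    """Descriptive table: n observed plus mean/SD or category percentages."""
    rows = []
    n_total = len(cohort)
    rows.append({"variable": "individuals", "n": n_total, "value": ""})
    for spec in specs:
        col = cohort[spec.name]
        n_obs = int(col.notna().sum())
        if spec.kind == "continuous":
            rows.append({
                "variable": spec.name, "n": n_obs,
                "value": f"{col.mean():.2f} ({col.std():.2f})",
            })
        else:
            counts = col.value_counts(normalize=True).sort_index()
            pct = ", ".join(
                f"{int(cat)}: {100 * frac:.1f}%" for cat, frac in counts.items()
            )
            rows.append({"variable": spec.name, "n": n_obs, "value": pct})
    return pd.DataFrame(rows)
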