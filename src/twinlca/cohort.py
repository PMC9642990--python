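"""Synthetic twin cohorts with latent lifestyle classes and heritable aging outcomes.

The generating model mirrors the structure assumed by the downstream analysis
chain:

* Each twin carries a latent *class liability* ``L = g + e`` with additive
  genetic part ``g`` (within-pair correlation 1 for MZ, 0.5 for DZ) and a
  non-shared environmental part.  Class membership is the probit-style
  discretisation of ``L`` at thresholds chosen to reproduce the target class
  proportions, so ``class_liability_h2`` is directly the heritability of the
  liability and MZ/DZ class concordance is analytic.
* Given class, the 10 lifestyle indicators are drawn independently (local
  independence): ordinal indicators from class-specific category
  probabilities, BMI from class-specific normal distributions.
* A continuous aging outcome is ``class mean + covariate effects + A + E``
  with ``Var(A) + Var(E) = 1`` (class contrasts are therefore expressed in
  residual-SD units).  A fraction ``shared_a_frac`` of the outcome's genetic
  variance is carried by the standardized class-liability genetic score,
  which is what creates genetic covariance between lifestyle patterns and
  aging; the remainder is genetic variance unique to the outcome.
* Item non-response is missing at random: per-indicator Bernoulli with a
  logit depending only on the fully observed covariates sex and age.

``true_shared_proportions`` evaluates the generating-model values of the
shared/unique variance decomposition by large-sample simulation of the
latent variables, and is the ground-truth oracle for the end-to-end
recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .indicators import IndicatorSpec, default_indicator_specs, validate_specs
from .shared import VarianceShareResult

ZYGOSITIES = ("MZ", "DZ_ss", "DZ_os")


@dataclass
class OutcomeParams:
    """Generating parameters for one continuous aging outcome.

    class_means are in residual-SD units (Var(A) + Var(E) is fixed at 1).
    """

    class_means: np.ndarray
    a2: float = 0.73
    e2: float = 0.27
    shared_a_frac: float = 0.0

    def __post_init__(self) -> None:
        self.class_means = np.asarray(self.class_means, dtype=float)
        if not np.isclose(self.a2 + self.e2, 1.0, atol=1e-8):
            raise ValueError("a2 + e2 must equal 1 (class effect is added on top)")
        if not (0.0 <= self.a2 <= 1.0 and 0.0 <= self.e2 <= 1.0):
            raise ValueError("a2 and e2 must lie in [0, 1]")
        if not 0.0 <= self.shared_a_frac <= 1.0:
            raise ValueError("shared_a_frac must lie in [0, 1]")


@dataclass
class CohortConfig:
    """Full specification of a synthetic twin cohort."""

    n_pairs: int
    class_props: np.ndarray
    indicator_specs: list[IndicatorSpec]
    indicator_params: dict[str, dict[str, Any]]
    outcome_params: dict[str, OutcomeParams] = field(default_factory=dict)
    zygosity_probs: tuple[float, float, float] = (0.34, 0.33, 0.33)
    class_liability_h2: float = 0.5
    covariate_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    missing_rates: dict[str, float] = field(default_factory=dict)
    missing_covariate_slopes: dict[str, float] = field(
        default_factory=lambda: {"sex": 0.3, "age": 0.2}
    )
    mean_age: float = 22.4
    sd_age: float = 0.7
    seed: int = 0

    @property
    def K(self) -> int:
        return len(self.class_props)

    def validate(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        props = np.asarray(self.class_props, dtype=float)
        if props.ndim != 1 or props.size < 1:
            raise ValueError("class_props must be a non-empty vector (K >= 1)")
        if np.any(props < 0) or not np.isclose(props.sum(), 1.0, atol=1e-6):
            raise ValueError("class_props must be non-negative and sum to 1")
        zyg = np.asarray(self.zygosity_probs, dtype=float)
        if zyg.size != 3 or np.any(zyg < 0) or not np.isclose(zyg.sum(), 1.0, atol=1e-6):
            raise ValueError("zygosity_probs must be a 3-vector summing to 1")
        if not 0.0 <= self.class_liability_h2 <= 1.0:
            raise ValueError("class_liability_h2 must lie in [0, 1]")
        validate_specs(self.indicator_specs)
        for spec in self.indicator_specs:
            try:
                par = self.indicator_params[spec.name]
            except KeyError as exc:
                raise ValueError(f"missing parameters for indicator {spec.name!r}") from exc
            if spec.kind == "ordinal":
                p = np.asarray(par["probs"], dtype=float)
                if p.shape != (self.K, spec.n_categories):
                    raise ValueError(f"{spec.name}: probs must be K x C")
                if np.any(p < 0) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
                    raise ValueError(f"{spec.name}: category probabilities must sum to 1")
            else:
                m = np.asarray(par["means"], dtype=float)
                s = np.asarray(par["sds"], dtype=float)
                if m.shape != (self.K,) or s.shape != (self.K,):
                    raise ValueError(f"{spec.name}: means/sds must be length-K")
                if np.any(s <= 0):
                    raise ValueError(f"{spec.name}: SDs must be > 0")
        for name, op in self.outcome_params.items():
            if op.class_means.shape != (self.K,):
                raise ValueError(f"{name}: class_means must be length-K")
        for name, rate in self.missing_rates.items():
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name}: missing rate must be in [0, 1)")


def _renorm(rows: list[list[float]]) -> np.ndarray:
    """Normalize each class-conditional probability row to sum exactly to 1."""
    a = np.asarray(rows, dtype=float)
    return a / a.sum(axis=1, keepdims=True)


def _within_class_sd(marginal_sd: float, means: np.ndarray, props: np.ndarray) -> float:
    """Common within-class SD compatible with a target marginal SD."""
    mbar = float(props @ means)
    between = float(props @ (means - mbar) ** 2)
    within = marginal_sd**2 - between
    if within <= 0:
        raise ValueError("class means alone exceed the requested marginal variance")
    return float(np.sqrt(within))


def default_config(n_pairs: int = 2557, seed: int = 0) -> CohortConfig:
    """Reference five-class generating model.

    Classes, in canonical order: C1 healthy lifestyle / physically active,
    C2 low-normal BMI, C3 healthy lifestyle with high-normal BMI, C4 high
    BMI, C5 unhealthiest lifestyle (smoking, binge drinking, low activity).
    Class-conditional indicator profiles follow the estimated five-class
    solution for a large Finnish adolescent twin cohort; common within-class
    BMI SDs are derived from the marginal BMI SDs (2.6, 2.7, 3.0 kg/m^2)
    after removing the between-class variance.  The default outcome is a
    GrimAge-style age-acceleration measure whose class contrasts (in
    residual-SD units) follow the reported between-class differences.
    """
    props = np.array([0.320, 0.199, 0.228, 0.095, 0.159])
    props = props / props.sum()  # printed proportions sum to 1.001
    bmi_means = {
        "bmi12": np.array([16.8, 15.2, 19.1, 22.7, 17.2]),
        "bmi14": np.array([18.6, 16.7, 20.9, 24.8, 18.9]),
        "bmi17": np.array([20.8, 18.8, 22.6, 27.1, 20.6]),
    }
    bmi_marginal_sd = {"bmi12": 2.6, "bmi14": 2.7, "bmi17": 3.0}
    indicator_params: dict[str, dict[str, Any]] = {}
    for name, means in bmi_means.items():
        sd = _within_class_sd(bmi_marginal_sd[name], means, props)
        indicator_params[name] = {"means": means, "sds": np.full(5, sd)}
    indicator_params["ltpa12"] = {"probs": _renorm([
        [0.29, 0.54, 0.17],
        [0.45, 0.46, 0.09],
        [0.35, 0.52, 0.14],
        [0.44, 0.47, 0.10],
        [0.44, 0.46, 0.11],
    ])}
    indicator_params["ltpa14"] = {"probs": _renorm([
        [0.08, 0.14, 0.52, 0.27],
        [0.17, 0.20, 0.45, 0.18],
        [0.14, 0.16, 0.51, 0.19],
        [0.18, 0.23, 0.43, 0.17],
        [0.27, 0.20, 0.40, 0.14],
    ])}
    indicator_params["ltpa17"] = {"probs": _renorm([
        [0.10, 0.15, 0.50, 0.26],
        [0.19, 0.18, 0.45, 0.18],
        [0.13, 0.15, 0.53, 0.20],
        [0.27, 0.18, 0.44, 0.11],
        [0.35, 0.19, 0.36, 0.10],
    ])}
    indicator_params["smoke14"] = {"probs": _renorm([
        [0.99, 0.01, 0.00, 0.00],
        [0.98, 0.02, 0.01, 0.00],
        [0.97, 0.02, 0.00, 0.00],
        [0.83, 0.09, 0.04, 0.04],
        [0.33, 0.29, 0.13, 0.25],
    ])}
    indicator_params["smoke17"] = {"probs": _renorm([
        [0.69, 0.12, 0.06, 0.13],
        [0.73, 0.09, 0.04, 0.14],
        [0.68, 0.12, 0.04, 0.17],
        [0.50, 0.11, 0.05, 0.34],
        [0.03, 0.15, 0.07, 0.74],
    ])}
    indicator_params["binge14"] = {"probs": _renorm([
        [0.88, 0.11, 0.01, 0.00],
        [0.94, 0.05, 0.02, 0.00],
        [0.84, 0.13, 0.03, 0.00],
        [0.76, 0.18, 0.05, 0.00],
        [0.23, 0.46, 0.27, 0.04],
    ])}
    indicator_params["binge17"] = {"probs": _renorm([
        [0.21, 0.48, 0.28, 0.03],
        [0.33, 0.45, 0.18, 0.04],
        [0.22, 0.46, 0.28, 0.03],
        [0.23, 0.41, 0.29, 0.08],
        [0.01, 0.26, 0.51, 0.22],
    ])}
    # Class contrasts for a GrimAge-style AA outcome, rescaled to residual-SD
    # units (reported contrasts in years divided by the residual SD implied by
    # a total SD of 3.24 and the between-class variance of the contrasts).
    grim_diffs = np.array([0.0, -0.57, 0.97, 1.83, 2.70])
    between = float(props @ (grim_diffs - props @ grim_diffs) ** 2)
    resid_sd = float(np.sqrt(3.24**2 - between))
    outcome_params = {
        "AA_Grim": OutcomeParams(
            class_means=grim_diffs / resid_sd, a2=0.73, e2=0.27, shared_a_frac=0.7
        )
    }
    # Item non-response margins implied by per-indicator observation counts
    # out of n=5114 (~2-19%, increasing with assessment age).
    missing_rates = {
        "bmi12": 0.039, "ltpa12": 0.015,
        "bmi14": 0.125, "ltpa14": 0.102, "smoke14": 0.106, "binge14": 0.107,
        "bmi17": 0.187, "ltpa17": 0.177, "smoke17": 0.181, "binge17": 0.175,
    }
    return CohortConfig(
        n_pairs=n_pairs,
        class_props=props,
        indicator_specs=default_indicator_specs(),
        indicator_params=indicator_params,
        outcome_params=outcome_params,
        zygosity_probs=(0.34, 0.33, 0.33),
        class_liability_h2=0.5,
        covariate_effects={"AA_Grim": {"sex": -0.2, "age": 0.1, "pds": 0.1}},
        missing_rates=missing_rates,
        seed=seed,
    )


def compact_two_class_config(
    n_pairs: int = 365,
    separation: float = 0.75,
    gap: float = 0.5,
    h2: float = 0.5,
    a2: float = 0.73,
    shared_a_frac: float = 0.0,
    seed: int = 0,
) -> CohortConfig:
    """Small two-class generating model for fast end-to-end experiments.

    Four 3-category ordinal indicators with mirrored class profiles; the
    ``separation`` parameter moves probability mass between the extreme
    categories and thereby sets the classification entropy (the default
    gives entropy near 0.8 at the default pair count).  One AE outcome with
    class means ``(-gap/2, +gap/2)`` in residual-SD units.
    """
    p_hi = separation
    p_lo = (1 - separation) / 2
    probs = _renorm([[p_hi, p_lo, p_lo], [p_lo, p_lo, p_hi]])
    specs = [IndicatorSpec(f"ind{j + 1}", "ordinal", 3) for j in range(4)]
    return CohortConfig(
        n_pairs=n_pairs,
        class_props=np.array([0.5, 0.5]),
        indicator_specs=specs,
        indicator_params={s.name: {"probs": probs} for s in specs},
        outcome_params={
            "y": OutcomeParams(
                class_means=np.array([-gap / 2, gap / 2]),
                a2=a2, e2=1 - a2, shared_a_frac=shared_a_frac,
            )
        },
        class_liability_h2=h2,
        seed=seed,
    )


def calibrate_shared_a_frac(
    config: CohortConfig,
    target_shared_genetic: float,
    outcome: str | None = None,
    n_draws: int = 300_000,
    oracle_seed: int = 12345,
    tol: float = 1e-3,
) -> CohortConfig:
    """Solve for the shared_a_frac that makes the oracle's shared-genetic
    proportion hit a target value (all other generator settings fixed).

    Uses common random numbers (a fixed oracle seed) so the profile of the
    oracle in shared_a_frac is smooth and bracketed root-finding applies.
    """
    if outcome is None:
        outcome = next(iter(config.outcome_params))

    def value(frac: float) -> float:
        cfg = _replace_shared_frac(config, outcome, frac)
        res = true_shared_proportions(cfg, outcome, n_draws=n_draws, seed=oracle_seed)
        return res.shared_genetic - target_shared_genetic

    lo, hi = value(0.0), value(1.0)
    if lo > 0 or hi < 0:
        raise ValueError(
            f"target {target_shared_genetic} outside the attainable range "
            f"[{lo + target_shared_genetic:.3f}, {hi + target_shared_genetic:.3f}]"
        )
    frac = float(optimize.brentq(value, 0.0, 1.0, xtol=tol))
    return _replace_shared_frac(config, outcome, frac)


def _replace_shared_frac(config: CohortConfig, outcome: str, frac: float) -> CohortConfig:
    import copy

    cfg = copy.deepcopy(config)
    op = cfg.outcome_params[outcome]
    cfg.outcome_params[outcome] = OutcomeParams(
        class_means=op.class_means, a2=op.a2, e2=op.e2, shared_a_frac=frac
    )
    return cfg


def _pair_correlated_normal(
    rng: np.random.Generator, zyg: np.ndarray, r_dz: float = 0.5
) -> np.ndarray:
    """(n_pairs, 2) standard-normal scores, correlation 1 in MZ, r_dz in DZ."""
    n = zyg.size
    common = rng.standard_normal(n)
    unique = rng.standard_normal((n, 2))
    out = np.empty((n, 2))
    mz = zyg == "MZ"
    out[mz, 0] = out[mz, 1] = common[mz]
    dz = ~mz
    out[dz] = np.sqrt(r_dz) * common[dz, None] + np.sqrt(1 - r_dz) * unique[dz]
    return out


def _draw_classes(
    rng: np.random.Generator,
    zyg: np.ndarray,
    props: np.ndarray,
    h2: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Class labels (n_pairs, 2) and the standardized genetic liability score."""
    g = _pair_correlated_normal(rng, zyg)
    e = rng.standard_normal(g.shape)
    liability = np.sqrt(h2) * g + np.sqrt(1 - h2) * e
    thresholds = stats.norm.ppf(np.cumsum(props)[:-1])
    classes = np.searchsorted(thresholds, liability)
    return classes, g


def _draw_ordinal(
    rng: np.random.Generator, classes: np.ndarray, probs: np.ndarray
) -> np.ndarray:
    cum = np.cumsum(probs, axis=1)
    u = rng.random(classes.shape)
    flat = classes.ravel()
    codes = (u.ravel()[:, None] > cum[flat][:, :-1]).sum(axis=1)
    return codes.reshape(classes.shape)


def generate_cohort(
    config: CohortConfig, return_truth: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a twin cohort; deterministic for a fixed config seed.

    Returns one row per individual.  With ``return_truth=True`` a second
    frame carries the hidden generating quantities (true class, genetic
    scores) which must never be written into the primary cohort file.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_pairs

    zyg = rng.choice(ZYGOSITIES, size=n, p=np.asarray(config.zygosity_probs, dtype=float))
    # sex: female=1; same-sex pairs share one draw, opposite-sex pairs differ
    sex = np.empty((n, 2), dtype=int)
    same = rng.integers(0, 2, size=n)
    sex[:, 0] = same
    sex[:, 1] = same
    os_mask = zyg == "DZ_os"
    first_female = rng.integers(0, 2, size=n)
    sex[os_mask, 0] = first_female[os_mask]
    sex[os_mask, 1] = 1 - first_female[os_mask]

    age = np.repeat(config.mean_age + config.sd_age * rng.standard_normal(n), 2).reshape(n, 2)
    pds = np.clip(1.6 + 0.5 * rng.standard_normal((n, 2)), 1.0, 3.0)

    classes, g_liab = _draw_classes(
        rng, zyg, np.asarray(config.class_props, dtype=float), config.class_liability_h2
    )

    columns: dict[str, np.ndarray] = {
        "family_id": np.repeat(np.arange(1, n + 1), 2),
        "member_index": np.tile([1, 2], n),
        "zygosity": np.repeat(zyg, 2),
        "sex": sex.ravel(),
        "age": age.ravel(),
        "pds": pds.ravel(),
    }

    z_age = (age - config.mean_age) / config.sd_age
    for spec in config.indicator_specs:
        par = config.indicator_params[spec.name]
        if spec.kind == "ordinal":
            vals = _draw_ordinal(rng, classes, np.asarray(par["probs"], dtype=float)).astype(float)
        else:
            means = np.asarray(par["means"], dtype=float)
            sds = np.asarray(par["sds"], dtype=float)
            vals = means[classes] + sds[classes] * rng.standard_normal(classes.shape)
        rate = config.missing_rates.get(spec.name, 0.0)
        if rate > 0:
            slopes = config.missing_covariate_slopes
            logit = np.log(rate / (1 - rate))
            logit = logit + slopes.get("sex", 0.0) * (sex - 0.5) + slopes.get("age", 0.0) * z_age
            miss = rng.random(vals.shape) < 1 / (1 + np.exp(-logit))
            vals = np.where(miss, np.nan, vals)
        columns[spec.name] = vals.ravel()

    truth_cols: dict[str, np.ndarray] = {
        "family_id": columns["family_id"],
        "member_index": columns["member_index"],
        "true_class": classes.ravel() + 1,
        "g_liability": g_liab.ravel(),
    }

    for name, op in config.outcome_params.items():
        g_unique = _pair_correlated_normal(rng, zyg)
        a = np.sqrt(op.a2) * (
            np.sqrt(op.shared_a_frac) * g_liab + np.sqrt(1 - op.shared_a_frac) * g_unique
        )
        e = np.sqrt(op.e2) * rng.standard_normal((n, 2))
        y = op.class_means[classes] + a + e
        eff = config.covariate_effects.get(name, {})
        y = y + eff.get("sex", 0.0) * sex + eff.get("age", 0.0) * z_age
        y = y + eff.get("pds", 0.0) * (pds - 1.6) / 0.5
        rate = config.missing_rates.get(name, 0.0)
        if rate > 0:
            miss = rng.random(y.shape) < rate
            y = np.where(miss, np.nan, y)
        columns[name] = y.ravel()
        truth_cols[f"A_{name}"] = a.ravel()

    cohort = pd.DataFrame(columns)
    if return_truth:
        return cohort, pd.DataFrame(truth_cols)
    return cohort


def _ae_from_pair_moments(
    var_mz: float, cov_mz: float, var_dz: float, cov_dz: float
) -> tuple[float, float]:
    """Fit the AE covariance structure to population pair moments by ML.

    Minimizes the two-group normal discrepancy
    ``sum_g [ln|Sigma(theta)| + tr(Sigma(theta)^-1 S_g) - ln|S_g| - 2]``
    with equal group weights; the start is the Falconer solution
    ``a2 = 2(cov_MZ - cov_DZ)``.
    """
    s_groups = [
        np.array([[var_mz, cov_mz], [cov_mz, var_mz]]),
        np.array([[var_dz, cov_dz], [cov_dz, var_dz]]),
    ]
    r_coef = [1.0, 0.5]

    def discrepancy(theta: np.ndarray) -> float:
        a2, e2 = theta
        total = 0.0
        for s, r in zip(s_groups, r_coef):
            sigma = np.array([[a2 + e2, r * a2], [r * a2, a2 + e2]])
            sign, logdet = np.linalg.slogdet(sigma)
            if sign <= 0:
                return 1e12
            sign_s, logdet_s = np.linalg.slogdet(s)
            total += logdet + np.trace(np.linalg.solve(sigma, s)) - logdet_s - 2.0
        return total

    a2_0 = 2 * (cov_mz - cov_dz)
    e2_0 = max(var_mz - a2_0, 0.05 * var_mz)
    res = optimize.minimize(
        discrepancy, x0=[a2_0, e2_0], method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
    )
    return float(res.x[0]), float(res.x[1])


def true_shared_proportions(
    config: CohortConfig,
    outcome: str | None = None,
    n_draws: int = 1_000_000,
    seed: int | None = None,
) -> VarianceShareResult:
    """Generating-model shared/unique variance decomposition by simulation.

    Draws ``n_draws`` MZ and ``n_draws`` DZ latent twin pairs (class
    liability, class means, genetic and environmental outcome parts; no
    covariates, no missingness) and derives every quantity the analysis
    pipeline targets: AE components of the *total* outcome from its
    population pair moments, and AE components of the *residual* — the
    outcome minus its population class-conditional mean.  When the
    outcome's genetic part is shared with the class liability
    (``shared_a_frac > 0``), the class-conditional means absorb part of
    that genetic variance even if the structural class means are equal, so
    the residual genetic component is below ``a2``; this is the estimand a
    class-conditional (BCH) residualisation recovers, and it is what makes
    the shared-genetic proportion a genetic-correlation measure rather
    than a causal-effect measure.
    """
    config.validate()
    if outcome is None:
        if len(config.outcome_params) != 1:
            raise ValueError("specify the outcome when several are configured")
        outcome = next(iter(config.outcome_params))
    op = config.outcome_params[outcome]
    rng = np.random.default_rng(config.seed if seed is None else seed)
    props = np.asarray(config.class_props, dtype=float)

    ys, cls = {}, {}
    for zyg_label in ("MZ", "DZ_ss"):
        zyg = np.full(n_draws, zyg_label)
        classes, g_liab = _draw_classes(rng, zyg, props, config.class_liability_h2)
        g_unique = _pair_correlated_normal(rng, zyg)
        a = np.sqrt(op.a2) * (
            np.sqrt(op.shared_a_frac) * g_liab + np.sqrt(1 - op.shared_a_frac) * g_unique
        )
        e = np.sqrt(op.e2) * rng.standard_normal((n_draws, 2))
        ys[zyg_label] = op.class_means[classes] + a + e
        cls[zyg_label] = classes

    # class-conditional outcome means over the pooled population: these are
    # what a distal-outcome model estimates, and they absorb E[A | class]
    # whenever the outcome's genetic part is shared with the class liability
    all_y = np.concatenate([ys[z].ravel() for z in ys])
    all_c = np.concatenate([cls[z].ravel() for z in cls])
    m = np.array([all_y[all_c == k].mean() for k in range(config.K)])

    def pair_moments(y: np.ndarray) -> tuple[float, float]:
        var = float(y.var())
        cov = float(np.cov(y[:, 0], y[:, 1])[0, 1])
        return var, cov

    var_mz, cov_mz = pair_moments(ys["MZ"])
    var_dz, cov_dz = pair_moments(ys["DZ_ss"])
    a2_tot, e2_tot = _ae_from_pair_moments(var_mz, cov_mz, var_dz, cov_dz)

    res_mz = ys["MZ"] - m[cls["MZ"]]
    res_dz = ys["DZ_ss"] - m[cls["DZ_ss"]]
    a2_res, e2_res = _ae_from_pair_moments(
        *pair_moments(res_mz), *pair_moments(res_dz)
    )

    var_tot = a2_tot + e2_tot
    var_res = a2_res + e2_res
    return VarianceShareResult(
        var_tot=var_tot,
        var_model=var_tot - var_res,
        var_res=var_res,
        a2_tot=a2_tot,
        e2_tot=e2_tot,
        a2_res=a2_res,
        e2_res=e2_res,
    )
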