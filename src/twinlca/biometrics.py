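"""Univariate twin variance-component models (ACE, ADE, AE, CE, E) by FIML.

The classical twin design decomposes trait variance using the different
genetic resemblance of monozygotic (MZ) and dizygotic (DZ) pairs.  Expected
moments under each model (common grand mean ``m`` for both members and both
groups):

=======  =================  =====================  =====================
model    total variance     MZ within-pair cov     DZ within-pair cov
=======  =================  =====================  =====================
ACE      A + C + E          A + C                  0.5 A + C
ADE      A + D + E          A + D                  0.5 A + 0.25 D
AE       A + E              A                      0.5 A
CE       C + E              C                      C
E        E                  0                      0
=======  =================  =====================  =====================

Variance components are parameterized directly and left unconstrained
(negative estimates are allowed; standardized shares are computed from the
unconstrained solution).  Pairs with one missing member contribute their
univariate marginal to the likelihood (FIML under MAR).  Opposite-sex DZ
pairs are pooled with same-sex DZ pairs.

Fit indices are normal-theory: the model chi-square compares against a
saturated model (common mean; free per-member, per-group variances and
per-group covariances — 7 parameters) and the incremental indices against
the independence baseline, which coincides with the E model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

MODELS = ("ACE", "ADE", "AE", "CE", "E")

# component labels and (MZ, DZ) covariance loadings per model
_MODEL_STRUCTURE: dict[str, list[tuple[str, float, float]]] = {
    "ACE": [("a2", 1.0, 0.5), ("c2", 1.0, 1.0), ("e2", 0.0, 0.0)],
    "ADE": [("a2", 1.0, 0.5), ("d2", 1.0, 0.25), ("e2", 0.0, 0.0)],
    "AE": [("a2", 1.0, 0.5), ("e2", 0.0, 0.0)],
    "CE": [("c2", 1.0, 1.0), ("e2", 0.0, 0.0)],
    "E": [("e2", 0.0, 0.0)],
}

_N_SATURATED_PARAMS = 7  # mean + 4 variances + 2 covariances


@dataclass
class _GroupStats:
    """Sufficient statistics for one zygosity group."""

    n_complete: int
    s1: np.ndarray       # (2,) sum of complete-pair vectors
    M: np.ndarray        # (2,2) raw cross-product of complete pairs
    n_single: np.ndarray  # (2,) singletons observed as member 1 / member 2
    sy: np.ndarray
    syy: np.ndarray

    @classmethod
    def from_pairs(cls, pairs: np.ndarray) -> "_GroupStats":
        p = np.asarray(pairs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 2:
            raise ValueError("pair matrix must be (n, 2)")
        obs = np.isfinite(p)
        keep = obs.any(axis=1)
        p, obs = p[keep], obs[keep]
        comp = obs.all(axis=1)
        pc = p[comp]
        n_single = np.zeros(2, dtype=int)
        sy = np.zeros(2)
        syy = np.zeros(2)
        for j in range(2):
            only_j = obs[:, j] & ~obs[:, 1 - j]
            vals = p[only_j, j]
            n_single[j] = vals.size
            sy[j] = vals.sum()
            syy[j] = (vals**2).sum()
        return cls(
            n_complete=pc.shape[0],
            s1=pc.sum(axis=0),
            M=pc.T @ pc,
            n_single=n_single,
            sy=sy,
            syy=syy,
        )

    @property
    def n_pairs(self) -> int:
        return self.n_complete + int(self.n_single.sum())

    @property
    def n_individuals(self) -> int:
        return 2 * self.n_complete + int(self.n_single.sum())

    def loglik(self, mean: float, v1: float, v2: float, cov: float) -> float:
        if v1 <= 0 or v2 <= 0:
            return -np.inf
        det = v1 * v2 - cov * cov
        if det <= 0:
            return -np.inf
        ll = 0.0
        if self.n_complete:
            mu = np.array([mean, mean])
            scatter = (
                self.M - np.outer(mu, self.s1) - np.outer(self.s1, mu)
                + self.n_complete * np.outer(mu, mu)
            )
            inv = np.array([[v2, -cov], [-cov, v1]]) / det
            ll += (
                -self.n_complete * np.log(2 * np.pi)
                - 0.5 * self.n_complete * np.log(det)
                - 0.5 * float(np.sum(inv * scatter))
            )
        for j, v in enumerate((v1, v2)):
            n = self.n_single[j]
            if n:
                ss = self.syy[j] - 2 * mean * self.sy[j] + n * mean**2
                ll += -0.5 * n * np.log(2 * np.pi * v) - 0.5 * ss / v
        return ll


def pairs_from_cohort(cohort: pd.DataFrame, outcome: str) -> dict[str, np.ndarray]:
    """Assemble MZ and (pooled) DZ pair matrices from a per-individual table."""
    zyg = cohort["zygosity"].astype(str).str.upper()
    pooled = np.where(zyg.str.startswith("MZ"), "MZ", "DZ")
    out = {}
    for label in ("MZ", "DZ"):
        sub = cohort.loc[pooled == label, ["family_id", "member_index", outcome]]
        wide = sub.pivot(index="family_id", columns="member_index", values=outcome)
        arr = wide.to_numpy(dtype=float)
        out[label] = arr[np.isfinite(arr).any(axis=1)]
    return out


def simulate_twin_pairs(
    n_mz: int,
    n_dz: int,
    components: dict[str, float],
    mean: float = 0.0,
    rng: np.random.Generator | None = None,
    model: str = "AE",
) -> dict[str, np.ndarray]:
    """Simulate complete MZ/DZ pair matrices under a biometric model."""
    rng = rng or np.random.default_rng()
    struct = _MODEL_STRUCTURE[model]
    var = sum(components.get(name, 0.0) for name, _, _ in struct)
    out = {}
    for label, n, idx in (("MZ", n_mz, 1), ("DZ", n_dz, 2)):
        cov = sum(components.get(name, 0.0) * loads[idx - 1] for name, *loads in struct)
        sigma = np.array([[var, cov], [cov, var]])
        chol = np.linalg.cholesky(sigma)
        out[label] = mean + rng.standard_normal((n, 2)) @ chol.T
    return out


class TwinBiometricModel:
    """Two-group twin variance-component model for one continuous outcome.

    Parameters
    ----------
    mz, dz : arrays (n, 2)
        Outcome values for MZ and DZ pairs; NaN marks a missing member.
    model : str
        One of ACE, ADE, AE, CE, E.  The DE model (dominance without
        additive effects) is not offered — dominance in the absence of
        additive variance is biologically implausible.
    """

    def __init__(self, mz: np.ndarray, dz: np.ndarray, model: str = "AE",
                 min_pairs: int = 10):
        model = model.upper()
        if model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        self.model = model
        self.stats = {"MZ": _GroupStats.from_pairs(mz), "DZ": _GroupStats.from_pairs(dz)}
        for label, st in self.stats.items():
            if st.n_pairs < min_pairs:
                raise ValueError(f"need at least {min_pairs} {label} pairs")
        self._struct = _MODEL_STRUCTURE[model]

    @property
    def n_params(self) -> int:
        return 1 + len(self._struct)

    @property
    def n_individuals(self) -> int:
        return sum(st.n_individuals for st in self.stats.values())

    def loglik(self, params: np.ndarray) -> float:
        """FIML log-likelihood at (mean, components...)."""
        mean, comps = params[0], params[1:]
        var = float(np.sum(comps))
        cov_mz = float(sum(c * s[1] for c, s in zip(comps, self._struct)))
        cov_dz = float(sum(c * s[2] for c, s in zip(comps, self._struct)))
        return (
            self.stats["MZ"].loglik(mean, var, var, cov_mz)
            + self.stats["DZ"].loglik(mean, var, var, cov_dz)
        )

    def _moment_start(self) -> np.ndarray:
        """Method-of-moments start from complete-pair moments."""
        moms = {}
        for label, st in self.stats.items():
            if st.n_complete >= 2:
                mean = st.s1.sum() / (2 * st.n_complete)
                S = st.M / st.n_complete - np.outer(st.s1, st.s1) / st.n_complete**2
                moms[label] = (mean, (S[0, 0] + S[1, 1]) / 2, S[0, 1])
            else:  # all singles: variance only
                n = st.n_single.sum()
                mean = st.sy.sum() / n
                moms[label] = (mean, st.syy.sum() / n - mean**2, 0.0)
        m0 = (moms["MZ"][0] + moms["DZ"][0]) / 2
        v0 = (moms["MZ"][1] + moms["DZ"][1]) / 2
        c_mz, c_dz = moms["MZ"][2], moms["DZ"][2]
        start = {"E": {"e2": v0}}
        a2_f = 2 * (c_mz - c_dz)
        start["AE"] = {"a2": c_mz, "e2": max(v0 - c_mz, 0.1 * v0)}
        start["CE"] = {"c2": (c_mz + c_dz) / 2, "e2": max(v0 - (c_mz + c_dz) / 2, 0.1 * v0)}
        start["ACE"] = {
            "a2": a2_f, "c2": c_mz - a2_f, "e2": max(v0 - c_mz, 0.1 * v0)
        }
        start["ADE"] = {
            "a2": max(4 * c_dz - c_mz, 0.0),
            "d2": max(2 * (c_mz - 2 * c_dz), 0.0),
            "e2": max(v0 - c_mz, 0.1 * v0),
        }
        comps = start[self.model]
        return np.array([m0] + [comps[name] for name, *_ in self._struct])

    def fit(self, n_starts: int = 5, seed: int | None = None) -> "TwinBiometricResults":
        """Maximize the FIML likelihood from several jittered starts."""
        rng = np.random.default_rng(seed)
        x0 = self._moment_start()
        scale = np.maximum(np.abs(x0), 0.1)
        best = None
        for s in range(max(1, n_starts)):
            xs = x0 if s == 0 else x0 + 0.3 * scale * rng.standard_normal(x0.size)
            res = optimize.minimize(
                lambda p: -self.loglik(p), xs, method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 20000, "maxfev": 20000},
            )
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise RuntimeError("optimizer failed to find a finite likelihood")
        params = best.x
        ll = -best.fun
        hess = _numerical_hessian(lambda p: -self.loglik(p), params)
        cov, flags = _safe_inverse(hess)
        if not best.success:
            flags = flags + ["optimizer reported non-convergence"]
        return TwinBiometricResults(
            model_obj=self,
            model=self.model,
            mean=float(params[0]),
            raw_components={name: float(v) for (name, *_), v in zip(self._struct, params[1:])},
            loglik=float(ll),
            cov_params=cov,
            flags=flags,
        )


def _numerical_hessian(f, x: np.ndarray, rel_h: float = 1e-4) -> np.ndarray:
    n = x.size
    h = rel_h * (1.0 + np.abs(x))
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


def _safe_inverse(H: np.ndarray) -> tuple[np.ndarray | None, list[str]]:
    try:
        eig = np.linalg.eigvalsh(H)
        if np.any(eig <= 0):
            return None, ["Hessian not positive definite; CIs unavailable"]
        return np.linalg.inv(H), []
    except np.linalg.LinAlgError:
        return None, ["Hessian inversion failed; CIs unavailable"]


@dataclass
class TwinBiometricResults:
    """Fitted twin model: raw and standardized components with delta-method CIs."""

    model_obj: TwinBiometricModel
    model: str
    mean: float
    raw_components: dict[str, float]
    loglik: float
    cov_params: np.ndarray | None
    flags: list[str] = field(default_factory=list)

    @property
    def total_variance(self) -> float:
        return float(sum(self.raw_components.values()))

    @property
    def n_params(self) -> int:
        return self.model_obj.n_params

    @property
    def standardized(self) -> dict[str, float]:
        """Component shares of total variance (sum to 1)."""
        tot = self.total_variance
        return {name: v / tot for name, v in self.raw_components.items()}

    def standardized_ci(self, conf_level: float = 0.95) -> dict[str, tuple[float, float]]:
        """Delta-method CIs for the standardized shares."""
        names = list(self.raw_components)
        shares = self.standardized
        if self.cov_params is None:
            return {n: (np.nan, np.nan) for n in names}
        comp = np.array([self.raw_components[n] for n in names])
        tot = comp.sum()
        V = self.cov_params[1:, 1:]  # drop the mean
        crit = stats.norm.ppf(0.5 + conf_level / 2)
        out = {}
        for i, name in enumerate(names):
            grad = -comp[i] / tot**2 * np.ones(len(names))
            grad[i] += 1.0 / tot
            se = float(np.sqrt(max(grad @ V @ grad, 0.0)))
            out[name] = (shares[name] - crit * se, shares[name] + crit * se)
        return out

    def total_variance_ci(self, conf_level: float = 0.95) -> tuple[float, float]:
        if self.cov_params is None:
            return (np.nan, np.nan)
        g = np.ones(len(self.raw_components))
        se = float(np.sqrt(max(g @ self.cov_params[1:, 1:] @ g, 0.0)))
        crit = stats.norm.ppf(0.5 + conf_level / 2)
        return (self.total_variance - crit * se, self.total_variance + crit * se)

    def summary(self) -> str:
        ci = self.standardized_ci()
        lines = [
            f"{self.model} model: loglik={self.loglik:.3f}, "
            f"params={self.n_params}, n={self.model_obj.n_individuals} individuals",
            f"grand mean={self.mean:.3f}, total variance={self.total_variance:.3f}",
        ]
        for name, share in self.standardized.items():
            lo, hi = ci[name]
            lines.append(f"  {name}/total = {share:.3f} (95% CI {lo:.3f}, {hi:.3f})")
        if self.flags:
            lines.append("flags: " + "; ".join(self.flags))
        return "\n".join(lines)


def _fit_saturated(stats_groups: dict[str, _GroupStats]) -> tuple[float, int]:
    """Saturated model: common mean, free per-member variances and covariances."""

    def neg_ll(theta: np.ndarray) -> float:
        m = theta[0]
        v = theta[1:5]
        c = theta[5:7]
        if np.any(v <= 0):
            return np.inf
        ll = stats_groups["MZ"].loglik(m, v[0], v[1], c[0])
        ll += stats_groups["DZ"].loglik(m, v[2], v[3], c[1])
        return -ll if np.isfinite(ll) else np.inf

    # start at group moments
    starts = []
    for st in (stats_groups["MZ"], stats_groups["DZ"]):
        if st.n_complete >= 2:
            mean = st.s1.sum() / (2 * st.n_complete)
            S = st.M / st.n_complete - np.outer(st.s1, st.s1) / st.n_complete**2
            starts.append((mean, S[0, 0], S[1, 1], S[0, 1]))
        else:
            n = max(int(st.n_single.sum()), 1)
            mean = st.sy.sum() / n
            v = max(st.syy.sum() / n - mean**2, 1e-3)
            starts.append((mean, v, v, 0.0))
    x0 = np.array([
        (starts[0][0] + starts[1][0]) / 2,
        starts[0][1], starts[0][2], starts[1][1], starts[1][2],
        starts[0][3], starts[1][3],
    ])
    res = optimize.minimize(
        neg_ll, x0, method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 40000, "maxfev": 40000},
    )
    return -float(res.fun), _N_SATURATED_PARAMS


@dataclass
class FitIndices:
    chi2: float
    df: int
    p: float
    cfi: float
    tli: float
    rmsea: float
    srmr: float
    bic: float

    def as_dict(self) -> dict[str, float]:
        return {
            "chi2": self.chi2, "df": self.df, "p": self.p, "CFI": self.cfi,
            "TLI": self.tli, "RMSEA": self.rmsea, "SRMR": self.srmr, "BIC": self.bic,
        }


def fit_indices(result: TwinBiometricResults) -> FitIndices:
    """Normal-theory fit indices against the saturated and independence models.

    chi2 = 2(L_saturated - L_model) with df = 7 - n_params; CFI/TLI against
    the independence baseline (zero within-pair covariance, common mean and
    variance — the E model), clamped to [0, 1]; multigroup RMSEA
    sqrt(G) * sqrt(max(chi2 - df, 0) / (df * N)) with N the number of
    individuals; SRMR is the root-mean-square of standardized residuals
    between saturated and model-implied moments; BIC = -2L + p ln(N).
    """
    model_obj = result.model_obj
    ll_sat, p_sat = _fit_saturated(model_obj.stats)
    n_ind = model_obj.n_individuals

    chi2 = max(2 * (ll_sat - result.loglik), 0.0)
    df = p_sat - result.n_params
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0

    if result.model == "E":
        chi2_b, df_b = chi2, df
    else:
        base = TwinBiometricModel(
            _stats_placeholder(model_obj.stats["MZ"]),
            _stats_placeholder(model_obj.stats["DZ"]),
            model="E", min_pairs=1,
        )
        # reuse the existing sufficient statistics directly
        base.stats = model_obj.stats
        ll_b = base.fit(n_starts=1).loglik
        chi2_b = max(2 * (ll_sat - ll_b), 0.0)
        df_b = p_sat - base.n_params

    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 if den == 0 else float(np.clip(1 - num / den, 0.0, 1.0))
    if df > 0 and df_b > 0 and chi2_b / df_b > 1:
        tli = ((chi2_b / df_b) - (chi2 / df)) / ((chi2_b / df_b) - 1)
        tli = float(np.clip(tli, 0.0, 1.0))
    else:
        tli = 1.0
    rmsea = 0.0 if df == 0 else float(np.sqrt(2.0) * np.sqrt(num / (df * n_ind)))
    srmr = _srmr(result, ll_sat)
    bic = -2 * result.loglik + result.n_params * np.log(n_ind)
    return FitIndices(chi2=chi2, df=df, p=p, cfi=cfi, tli=tli, rmsea=rmsea,
                      srmr=srmr, bic=bic)


def _stats_placeholder(st: _GroupStats) -> np.ndarray:
    # minimal valid pair matrix; the stats are overwritten by the caller
    return np.zeros((2, 2)) + np.array([[0.0, 1.0], [1.0, 0.0]])


def _srmr(result: TwinBiometricResults, ll_sat: float) -> float:
    """RMS of standardized residuals between saturated and implied moments."""
    model_obj = result.model_obj
    # saturated moments per group re-estimated from complete pairs (FIML
    # saturated point estimates coincide for complete data; singles shift
    # only slightly)
    resids = []
    var = result.total_variance
    struct = _MODEL_STRUCTURE[result.model]
    comps = result.raw_components
    for label, r_idx in (("MZ", 0), ("DZ", 1)):
        st = model_obj.stats[label]
        if st.n_complete < 2:
            continue
        mean_s = st.s1.sum() / (2 * st.n_complete)
        S = st.M / st.n_complete - np.outer(st.s1, st.s1) / st.n_complete**2
        cov_model = sum(comps[name] * loads[r_idx] for name, *loads in struct)
        resids.extend([
            (S[0, 0] - var) / S[0, 0],
            (S[1, 1] - var) / S[1, 1],
            (S[0, 1] - cov_model) / np.sqrt(S[0, 0] * S[1, 1]),
            (mean_s - result.mean) / np.sqrt((S[0, 0] + S[1, 1]) / 2),
        ])
    return float(np.sqrt(np.mean(np.square(resids)))) if resids else np.nan


def compare_models(
    fits: list[TwinBiometricResults],
    p_threshold: float = 0.05,
    cfi_threshold: float = 0.95,
    rmsea_threshold: float = 0.06,
    srmr_threshold: float = 0.08,
) -> pd.DataFrame:
    """Rank a sequence of fits on the same data; flag the optimal model.

    The optimal model is the most parsimonious (fewest parameters, ties by
    lower BIC) among those whose chi-square p exceeds ``p_threshold`` and
    whose CFI/RMSEA/SRMR pass the conventional thresholds; if none passes,
    the lowest-BIC model is flagged instead.
    """
    rows = []
    for fit in fits:
        idx = fit_indices(fit)
        row = {"model": fit.model, "n_params": fit.n_params, "loglik": fit.loglik}
        row.update(idx.as_dict())
        std = fit.standardized
        for name in ("a2", "c2", "d2", "e2"):
            row[f"{name}_share"] = std.get(name, np.nan)
        row["total"] = fit.total_variance
        rows.append(row)
    table = pd.DataFrame(rows)
    passing = table[
        (table["p"] > p_threshold)
        & (table["CFI"] >= cfi_threshold)
        & (table["RMSEA"] <= rmsea_threshold)
        & (table["SRMR"] <= srmr_threshold)
    ]
    if len(passing):
        chosen = passing.sort_values(["n_params", "BIC"]).index[0]
    else:
        chosen = table.sort_values("BIC").index[0]
    table["selected"] = False
    table.loc[chosen, "selected"] = True
    return table
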