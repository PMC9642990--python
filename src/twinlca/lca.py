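"""Latent class analysis for mixed ordinal + continuous indicators.

The model is a finite mixture with local independence: conditional on class
``k`` (mixing proportions ``pi``), each ordinal indicator ``j`` follows a
class-specific multinomial over its categories and each continuous indicator
a class-specific normal with its own mean and variance.  Estimation is EM on
the observed-data log-likelihood

    sum_i log sum_k pi_k  prod_{j in obs(i)} f_jk(y_ij),

so individuals with missing items simply drop those items from the product —
full-information maximum likelihood, unbiased under missing-at-random.
Individuals with *all* indicators missing are excluded.

Class labels are fixed by a canonical ordering (descending mixing
proportion, ties broken by ascending mean of the last continuous indicator)
so reported solutions are invariant to label switching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .indicators import IndicatorSpec, validate_specs

_LOG_FLOOR = 1e-12


@dataclass
class _PreparedData:
    """Design arrays for the EM: one-hot ordinals, masked continuous columns."""

    n: int
    onehot: dict[str, np.ndarray]        # name -> (n, C), zero rows where missing
    cont_vals: dict[str, np.ndarray]     # name -> (n,), NaN where missing
    cont_mask: dict[str, np.ndarray]     # name -> (n,) bool
    index: np.ndarray                    # row positions retained from the input


def _prepare(data: pd.DataFrame, specs: list[IndicatorSpec]) -> _PreparedData:
    validate_specs(specs)
    n_all = len(data)
    any_obs = np.zeros(n_all, dtype=bool)
    onehot: dict[str, np.ndarray] = {}
    cont_vals: dict[str, np.ndarray] = {}
    cont_mask: dict[str, np.ndarray] = {}
    for spec in specs:
        col = data[spec.name].to_numpy(dtype=float)
        obs = np.isfinite(col)
        any_obs |= obs
        if spec.kind == "ordinal":
            C = spec.n_categories
            codes = np.where(obs, col, 0).astype(int)
            if np.any((codes[obs] < 0) | (codes[obs] >= C)):
                raise ValueError(f"{spec.name}: ordinal codes outside 0..{C - 1}")
            oh = np.zeros((n_all, C))
            oh[np.arange(n_all)[obs], codes[obs]] = 1.0
            onehot[spec.name] = oh
        else:
            cont_vals[spec.name] = col
            cont_mask[spec.name] = obs
    keep = np.flatnonzero(any_obs)
    return _PreparedData(
        n=keep.size,
        onehot={k: v[keep] for k, v in onehot.items()},
        cont_vals={k: v[keep] for k, v in cont_vals.items()},
        cont_mask={k: v[keep] for k, v in cont_mask.items()},
        index=keep,
    )


@dataclass
class _Params:
    pi: np.ndarray
    ordinal: dict[str, np.ndarray]                 # name -> (K, C)
    cont: dict[str, tuple[np.ndarray, np.ndarray]]  # name -> (means, variances)


def _log_density_matrix(prep: _PreparedData, params: _Params) -> np.ndarray:
    """(n, K) matrix of log pi_k + sum_j log f_jk over observed items."""
    logf = np.broadcast_to(
        np.log(np.clip(params.pi, _LOG_FLOOR, None)), (prep.n, params.pi.size)
    ).copy()
    for name, oh in prep.onehot.items():
        logp = np.log(np.clip(params.ordinal[name], _LOG_FLOOR, None))
        logf += oh @ logp.T
    for name, y in prep.cont_vals.items():
        mu, var = params.cont[name]
        obs = prep.cont_mask[name]
        contrib = -0.5 * (
            np.log(2 * np.pi * var)[None, :] + (y[:, None] - mu[None, :]) ** 2 / var[None, :]
        )
        logf += np.where(obs[:, None], np.nan_to_num(contrib, nan=0.0), 0.0)
    return logf


def _e_step(prep: _PreparedData, params: _Params) -> tuple[np.ndarray, float]:
    logf = _log_density_matrix(prep, params)
    ll_i = logsumexp(logf, axis=1)
    resp = np.exp(logf - ll_i[:, None])
    return resp, float(ll_i.sum())


def _m_step(
    prep: _PreparedData,
    resp: np.ndarray,
    var_floors: dict[str, float],
) -> tuple[_Params, list[str]]:
    flags: list[str] = []
    pi = resp.mean(axis=0)
    ordinal: dict[str, np.ndarray] = {}
    for name, oh in prep.onehot.items():
        counts = resp.T @ oh                      # (K, C)
        n_obs_k = counts.sum(axis=1, keepdims=True)
        ordinal[name] = np.where(n_obs_k > 0, counts / np.clip(n_obs_k, 1e-300, None), 1.0 / oh.shape[1])
    cont: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, y in prep.cont_vals.items():
        obs = prep.cont_mask[name]
        w = resp * obs[:, None]
        sw = w.sum(axis=0)
        y0 = np.where(obs, y, 0.0)
        mu = (w * y0[:, None]).sum(axis=0) / np.clip(sw, 1e-300, None)
        var = (w * (y0[:, None] - mu[None, :]) ** 2).sum(axis=0) / np.clip(sw, 1e-300, None)
        floor = var_floors[name]
        if np.any(var < floor):
            flags.append(f"variance floor hit for {name}")
            var = np.maximum(var, floor)
        cont[name] = (mu, var)
    return _Params(pi=pi, ordinal=ordinal, cont=cont), flags


def _run_em(
    prep: _PreparedData,
    params: _Params,
    var_floors: dict[str, float],
    tol: float,
    max_iter: int,
) -> tuple[_Params, float, bool, int, list[str]]:
    ll_old = -np.inf
    flags: list[str] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        resp, ll = _e_step(prep, params)
        params, step_flags = _m_step(prep, resp, var_floors)
        for f in step_flags:
            if f not in flags:
                flags.append(f)
        if np.isfinite(ll_old) and ll - ll_old <= tol * abs(ll_old):
            converged = True
            break
        ll_old = ll
    _, ll = _e_step(prep, params)
    return params, ll, converged, n_iter, flags


def n_free_parameters(specs: list[IndicatorSpec], K: int) -> int:
    """(K-1) mixing + K(C_j-1) per ordinal + 2K per continuous indicator."""
    p = K - 1
    for spec in specs:
        if spec.kind == "ordinal":
            p += K * (spec.n_categories - 1)
        else:
            p += 2 * K
    return p


class LatentClassModel:
    """Latent class model over a mixed indicator battery.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per individual; indicator columns named as in ``specs``,
        missing values as NaN.
    specs : list of IndicatorSpec
        The indicator battery.
    n_classes : int
        Number of latent classes, K >= 1.
    """

    def __init__(self, data: pd.DataFrame, specs: list[IndicatorSpec], n_classes: int):
        if n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        self.data = data
        self.specs = list(specs)
        self.n_classes = int(n_classes)
        self._prep = _prepare(data, self.specs)
        if self._prep.n == 0:
            raise ValueError("no individual has any observed indicator")
        self._var_floors = {
            name: 1e-4 * np.nanvar(vals[self._prep.cont_mask[name]])
            for name, vals in self._prep.cont_vals.items()
        }

    @property
    def n_effective(self) -> int:
        """Individuals contributing at least one observed indicator."""
        return self._prep.n

    def fit(
        self,
        n_starts: int = 50,
        tol: float = 1e-6,
        max_iter: int = 1000,
        seed: int | None = None,
        stage1_iter: int = 30,
        stage1_keep: int = 5,
    ) -> "LatentClassResults":
        """Fit by EM with a two-stage multistart.

        Every start initialises from a random Dirichlet posterior and runs
        ``stage1_iter`` EM iterations; the ``stage1_keep`` best starts by
        log-likelihood are then run to convergence (``tol`` on the relative
        log-likelihood increment) and the best solution is kept.
        """
        rng = np.random.default_rng(seed)
        K = self.n_classes
        prep = self._prep
        if K == 1:
            params = self._single_class_params()
            _, ll = _e_step(prep, params)
            return self._make_results(params, ll, True, 0, [], n_starts=1)

        stage1: list[tuple[float, _Params]] = []
        for _ in range(max(1, n_starts)):
            resp0 = rng.dirichlet(np.ones(K), size=prep.n)
            params0, _ = _m_step(prep, resp0, self._var_floors)
            params1, ll1, *_ = _run_em(prep, params0, self._var_floors, tol, stage1_iter)
            stage1.append((ll1, params1))
        stage1.sort(key=lambda t: t[0], reverse=True)

        best: tuple[float, _Params, bool, int, list[str]] | None = None
        for ll1, params1 in stage1[: max(1, stage1_keep)]:
            params2, ll2, conv, n_iter, flags = _run_em(
                prep, params1, self._var_floors, tol, max_iter
            )
            if best is None or ll2 > best[0]:
                best = (ll2, params2, conv, n_iter, flags)
        ll, params, conv, n_iter, flags = best
        if not conv:
            flags.append("EM did not converge within max_iter")
        if np.any(params.pi < 1.0 / prep.n):
            flags.append("degenerate class: mixing proportion below 1/n")
        return self._make_results(params, ll, conv, n_iter, flags, n_starts=n_starts)

    def _single_class_params(self) -> _Params:
        prep = self._prep
        resp = np.ones((prep.n, 1))
        params, _ = _m_step(prep, resp, self._var_floors)
        return params

    def _canonical_order(self, params: _Params) -> np.ndarray:
        """Descending mixing proportion; ties by ascending last-continuous mean."""
        pi_round = np.round(params.pi, 10)
        cont_names = [s.name for s in self.specs if s.kind == "continuous"]
        if cont_names:
            tie = params.cont[cont_names[-1]][0]
        else:
            tie = np.zeros_like(params.pi)
        return np.lexsort((tie, -pi_round))

    def _make_results(
        self,
        params: _Params,
        loglik: float,
        converged: bool,
        n_iter: int,
        flags: list[str],
        n_starts: int,
    ) -> "LatentClassResults":
        order = self._canonical_order(params)
        params = _Params(
            pi=params.pi[order],
            ordinal={k: v[order] for k, v in params.ordinal.items()},
            cont={k: (m[order], v[order]) for k, (m, v) in params.cont.items()},
        )
        return LatentClassResults(
            model=self,
            pi=params.pi,
            ordinal_params=params.ordinal,
            cont_params=params.cont,
            loglik=loglik,
            converged=converged,
            n_iter=n_iter,
            flags=flags,
            n_starts=n_starts,
        )


@dataclass
class LatentClassResults:
    """Fitted latent class solution, canonically labelled."""

    model: LatentClassModel
    pi: np.ndarray
    ordinal_params: dict[str, np.ndarray]
    cont_params: dict[str, tuple[np.ndarray, np.ndarray]]
    loglik: float
    converged: bool
    n_iter: int
    flags: list[str] = field(default_factory=list)
    n_starts: int = 1

    @property
    def n_classes(self) -> int:
        return self.pi.size

    @property
    def n_params(self) -> int:
        return n_free_parameters(self.model.specs, self.n_classes)

    @property
    def n_effective(self) -> int:
        return self.model.n_effective

    def _params(self) -> _Params:
        return _Params(pi=self.pi, ordinal=self.ordinal_params, cont=self.cont_params)

    def posterior(self, data: pd.DataFrame | None = None) -> np.ndarray:
        """Bayes posterior class probabilities given observed indicators.

        With no argument, returns posteriors for the individuals that
        entered the fit.  For new data, individuals with all indicators
        missing receive the prior (mixing proportions) as their posterior.
        """
        if data is None:
            prep = self.model._prep
        else:
            prep = _prepare_with_all_missing(data, self.model.specs)
        logf = _log_density_matrix(prep, self._params())
        return np.exp(logf - logsumexp(logf, axis=1)[:, None])

    def modal_assignment(self, data: pd.DataFrame | None = None) -> np.ndarray:
        return self.posterior(data).argmax(axis=1)

    def avepp(self) -> np.ndarray:
        return avepp(self.posterior())

    # --- information criteria -------------------------------------------------
    @property
    def aic(self) -> float:
        return information_criteria(self)[0]

    @property
    def bic(self) -> float:
        return information_criteria(self)[1]

    @property
    def abic(self) -> float:
        return information_criteria(self)[2]

    def class_proportion_se(self, family_ids: np.ndarray) -> np.ndarray:
        """Cluster-robust (family-level) SEs for the estimated class proportions.

        Linearisation estimator: the influence of individual i on pi_k is
        ``p_ik - pi_k``; influences are summed within families before the
        variance is taken, which accounts for the non-independence of twins.
        """
        post = self.posterior()
        fam = np.asarray(family_ids)[self.model._prep.index]
        resid = post - self.pi[None, :]
        df = pd.DataFrame(resid)
        df["fam"] = fam
        fam_sums = df.groupby("fam").sum().to_numpy()
        return np.sqrt((fam_sums**2).sum(axis=0)) / post.shape[0]

    def summary(self) -> str:
        lines = [
            f"Latent class model: K={self.n_classes}, n={self.n_effective}, "
            f"free parameters={self.n_params}",
            f"log-likelihood={self.loglik:.3f}  AIC={self.aic:.1f}  "
            f"BIC={self.bic:.1f}  aBIC={self.abic:.1f}",
            f"converged={self.converged} after {self.n_iter} iterations "
            f"({self.n_starts} starts)",
            "class proportions: " + ", ".join(f"{p:.3f}" for p in self.pi),
            "AvePP: " + ", ".join(f"{a:.3f}" for a in self.avepp()),
        ]
        if self.flags:
            lines.append("flags: " + "; ".join(self.flags))
        for name, (mu, var) in self.cont_params.items():
            lines.append(
                f"{name}: means " + ", ".join(f"{m:.2f}" for m in mu)
                + " | SDs " + ", ".join(f"{np.sqrt(v):.2f}" for v in var)
            )
        return "\n".join(lines)


def _prepare_with_all_missing(data: pd.DataFrame, specs: list[IndicatorSpec]) -> _PreparedData:
    """Like _prepare but keeps all rows (all-missing rows get the prior)."""
    prep = _prepare(data, specs)
    n_all = len(data)
    if prep.n == n_all:
        return prep
    onehot = {}
    for spec in specs:
        if spec.kind == "ordinal":
            oh = np.zeros((n_all, spec.n_categories))
            oh[prep.index] = prep.onehot[spec.name]
            onehot[spec.name] = oh
    cont_vals, cont_mask = {}, {}
    for name in prep.cont_vals:
        v = np.full(n_all, np.nan)
        m = np.zeros(n_all, dtype=bool)
        v[prep.index] = prep.cont_vals[name]
        m[prep.index] = prep.cont_mask[name]
        cont_vals[name] = v
        cont_mask[name] = m
    return _PreparedData(
        n=n_all, onehot=onehot, cont_vals=cont_vals, cont_mask=cont_mask,
        index=np.arange(n_all),
    )


def information_criteria(fit: LatentClassResults, n: int | None = None) -> tuple[float, float, float]:
    """AIC, BIC and sample-size-adjusted BIC for a fitted solution.

    AIC = -2L + 2p; BIC = -2L + p ln n; aBIC = -2L + p ln((n+2)/24).
    ``n`` defaults to the number of individuals contributing to the fit.
    """
    if n is None:
        n = fit.n_effective
    if n < 1:
        raise ValueError("n must be >= 1")
    L, p = fit.loglik, fit.n_params
    return (-2 * L + 2 * p, -2 * L + p * np.log(n), -2 * L + p * np.log((n + 2) / 24))


def avepp(posterior: np.ndarray) -> np.ndarray:
    """Average posterior probability among individuals modally assigned to each class.

    Classes with no modal members get NaN.
    """
    post = np.asarray(posterior, dtype=float)
    modal = post.argmax(axis=1)
    K = post.shape[1]
    out = np.full(K, np.nan)
    for k in range(K):
        members = modal == k
        if members.any():
            out[k] = post[members, k].mean()
    return out


def lmr_tests(
    fit_k: LatentClassResults, fit_km1: LatentClassResults, n: int | None = None
) -> tuple[float, float]:
    """Likelihood-ratio class-enumeration tests of K classes against K-1.

    Returns the (VLMR-style, LMR-adjusted) p-values for the null that the
    (K-1)-class model is adequate.  The statistic is ``T = 2(L_K - L_{K-1})``
    referred to a chi-square with the parameter-count difference as degrees
    of freedom — a conservative reference under the mixture null.  The
    adjusted variant scales T by ``1 + 1/(dp * ln n)`` (a parameter-difference
    and sample-size based correction).  A small p-value means the model with
    one class fewer should be rejected.
    """
    if fit_km1.n_classes != fit_k.n_classes - 1:
        raise ValueError("second fit must have exactly one class fewer")
    if n is None:
        n = fit_k.n_effective
    dL = fit_k.loglik - fit_km1.loglik
    if dL < -1e-6 * max(1.0, abs(fit_k.loglik)):
        raise ValueError(
            "the K-class log-likelihood is below the (K-1)-class one; "
            "increase n_starts for the larger model"
        )
    T = max(2 * dL, 0.0)
    dp = fit_k.n_params - fit_km1.n_params
    p_vlmr = float(stats.chi2.sf(T, dp))
    c = 1.0 + 1.0 / (dp * np.log(n))
    p_lmr = float(stats.chi2.sf(T / c, dp))
    return p_vlmr, p_lmr


def select_classes(
    data: pd.DataFrame,
    specs: list[IndicatorSpec],
    k_min: int = 1,
    k_max: int = 8,
    n_starts: int = 50,
    seed: int | None = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit a range of class counts and tabulate the selection statistics.

    One row per K: information criteria, enumeration-test p-values against
    K-1, class sizes and AvePP.  Returns the table; the individual fits are
    attached as ``table.attrs["fits"]``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    fits: dict[int, LatentClassResults] = {}
    prev: LatentClassResults | None = None
    for K in range(k_min, k_max + 1):
        fit = LatentClassModel(data, specs, K).fit(
            n_starts=n_starts, seed=int(rng.integers(2**31 - 1)), **fit_kwargs
        )
        aic, bic, abic = information_criteria(fit)
        row = {
            "K": K, "loglik": fit.loglik, "n_params": fit.n_params,
            "AIC": aic, "BIC": bic, "aBIC": abic,
            "VLMR_p": np.nan, "LMR_p": np.nan,
            "class_sizes": ", ".join(f"{p:.3f}" for p in fit.pi),
            "min_AvePP": float(np.nanmin(fit.avepp())),
            "converged": fit.converged,
        }
        if prev is not None:
            row["VLMR_p"], row["LMR_p"] = lmr_tests(fit, prev)
        rows.append(row)
        fits[K] = fit
        prev = fit
    table = pd.DataFrame(rows)
    table.attrs["fits"] = fits
    return table
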