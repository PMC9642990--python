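"""BCH three-step distal-outcome analysis for latent classes.

The Bolck–Croon–Hagenaars correction relates a fitted latent class solution
to an auxiliary ("distal") outcome without letting the outcome shift the
class solution.  From the posterior matrix the classification-error matrix
``D`` (rows: true class, columns: modal class) is estimated; each individual
then enters a weighted secondary model with the weight row ``H[w_i, :]``
where ``H = D^{-1}`` and ``w_i`` is the modal assignment.  The weights sum
to 1 per individual but can be negative — a documented property of the
method, which is what removes the attenuation that naive modal assignment
induces.

The secondary model here is weighted least squares of the outcome on K
class-indicator columns (no global intercept) plus optional shared covariate
columns, with family-clustered sandwich standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def classification_error_matrix(
    posterior: np.ndarray, modal: np.ndarray | None = None, assignment: str = "modal"
) -> np.ndarray:
    """Estimated P(modal class s | true class k) from the posterior matrix.

    ``D[k, s] = sum_i p_ik 1[w_i = s] / sum_i p_ik`` for modal assignment;
    the proportional variant replaces the indicator with ``p_is``.
    """
    post = np.asarray(posterior, dtype=float)
    n, K = post.shape
    col = post.sum(axis=0)
    if np.any(col < 1e-10):
        raise ValueError("empty class: some class has (near-)zero posterior mass")
    if assignment == "modal":
        if modal is None:
            modal = post.argmax(axis=1)
        modal = np.asarray(modal)
        onehot = np.zeros((n, K))
        onehot[np.arange(n), modal] = 1.0
        num = post.T @ onehot
    elif assignment == "proportional":
        num = post.T @ post
    else:
        raise ValueError(f"unknown assignment {assignment!r}")
    return num / col[:, None]


def bch_weights(
    D: np.ndarray, modal: np.ndarray | None = None, cond_limit: float = 1e8
) -> tuple[np.ndarray, np.ndarray | None]:
    """Inverse-error-matrix weights H = D^-1 and, if modal given, per-individual rows.

    Rows of H sum to 1 because rows of D do.  A near-singular D (very low
    classification entropy) is refused with a remedy: fit fewer classes or
    use more starts so the solution separates.
    """
    D = np.asarray(D, dtype=float)
    cond = np.linalg.cond(D)
    if not np.isfinite(cond) or cond > cond_limit:
        raise ValueError(
            f"classification-error matrix is near-singular (cond={cond:.2e}); "
            "the classes are too poorly separated for BCH weighting — "
            "consider fewer classes or more EM starts"
        )
    H = np.linalg.inv(D)
    if modal is None:
        return H, None
    return H, H[np.asarray(modal)]


@dataclass
class BCHWeights:
    """Posterior matrix, modal assignment, error matrix D and weights H = D^-1."""

    posterior: np.ndarray
    modal: np.ndarray
    D: np.ndarray
    H: np.ndarray
    weights: np.ndarray  # per-individual weight rows, (n, K)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.D))


def bch_from_posterior(posterior: np.ndarray, assignment: str = "modal") -> BCHWeights:
    """Build the full BCH weighting from a posterior matrix."""
    post = np.asarray(posterior, dtype=float)
    modal = post.argmax(axis=1)
    D = classification_error_matrix(post, modal, assignment=assignment)
    H, w = bch_weights(D, modal)
    return BCHWeights(posterior=post, modal=modal, D=D, H=H, weights=w)


def smd(diff: float, sd: float) -> float:
    """Standardized mean difference: contrast divided by the whole-sample SD.

    The denominator is the outcome's overall SD (not a pooled within-class
    SD), which is the convention that reproduces published contrast tables
    from their printed differences and marginal SDs.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    return diff / sd


class BCHDistalModel:
    """Weighted secondary model for one distal outcome.

    Parameters
    ----------
    outcome : array (n,)
        Continuous distal outcome; NaN rows are dropped listwise.
    weights : array (n, K)
        BCH weight rows (or one-hot rows for known classes).
    covariates : array (n, q) or None
        Shared covariate columns (already coded/standardized as desired).
    cluster_ids : array (n,) or None
        Family identifiers for the clustered sandwich; defaults to
        independent individuals.
    """

    def __init__(self, outcome, weights, covariates=None, cluster_ids=None):
        y = np.asarray(outcome, dtype=float)
        W = np.asarray(weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != y.shape[0]:
            raise ValueError("weights must be (n, K) aligned with the outcome")
        if covariates is None:
            X = np.empty((y.shape[0], 0))
        else:
            X = np.asarray(covariates, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
        if cluster_ids is None:
            clus = np.arange(y.shape[0])
        else:
            clus = np.asarray(cluster_ids)
        ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1) & np.all(np.isfinite(W), axis=1)
        self.y, self.W, self.X, self.clusters = y[ok], W[ok], X[ok], clus[ok]
        self.n, self.K = self.W.shape
        self.q = self.X.shape[1]
        if self.q:
            rank = np.linalg.matrix_rank(np.column_stack([np.ones(self.n), self.X]))
            if rank < self.q + 1:
                raise ValueError("collinear covariates")

    def fit(self) -> "BCHDistalResults":
        n, K, q = self.n, self.K, self.q
        # expand: K pseudo-observations per individual, weight w_ik on the
        # class-k mean column; covariates shared across the K rows
        y_big = np.repeat(self.y, K)
        w_big = self.W.ravel()
        dummies = np.tile(np.eye(K), (n, 1))
        X_big = np.column_stack([dummies, np.repeat(self.X, K, axis=0)]) if q else dummies
        XtW = X_big.T * w_big
        A = XtW @ X_big
        flags: list[str] = []
        eigmin = float(np.linalg.eigvalsh(A).min())
        if eigmin <= 0:
            flags.append(
                f"weighted cross-product not positive definite (min eig {eigmin:.3e}); "
                "negative BCH weights dominate — estimates unreliable"
            )
        beta = np.linalg.solve(A, XtW @ y_big)
        resid = y_big - X_big @ beta

        # family-clustered sandwich with G/(G-1) small-sample factor
        clus_big = np.repeat(self.clusters, K)
        scores = X_big * (w_big * resid)[:, None]
        sdf = pd.DataFrame(scores)
        sdf["g"] = clus_big
        S = sdf.groupby("g").sum().to_numpy()
        G = S.shape[0]
        bread = np.linalg.inv(A)
        cov = bread @ (S.T @ S) @ bread * (G / max(G - 1, 1))
        cov = (cov + cov.T) / 2

        # overall Wald test of equal class means
        C = np.zeros((K - 1, K + q))
        for j in range(K - 1):
            C[j, j], C[j, j + 1] = 1.0, -1.0
        cb = C @ beta
        wald = float(cb @ np.linalg.solve(C @ cov @ C.T, cb)) if K > 1 else 0.0
        wald_df = K - 1
        wald_p = float(stats.chi2.sf(wald, wald_df)) if K > 1 else 1.0

        return BCHDistalResults(
            model=self,
            params=beta,
            cov_params=cov,
            class_means=beta[:K],
            covariate_coefs=beta[K:],
            wald_stat=wald,
            wald_df=wald_df,
            wald_p=wald_p,
            n_clusters=G,
            outcome_sd=float(np.std(self.y, ddof=1)),
            flags=flags,
        )


@dataclass
class BCHDistalResults:
    """Class means, covariate effects and cluster-robust inference."""

    model: BCHDistalModel
    params: np.ndarray
    cov_params: np.ndarray
    class_means: np.ndarray
    covariate_coefs: np.ndarray
    wald_stat: float
    wald_df: int
    wald_p: float
    n_clusters: int
    outcome_sd: float
    flags: list[str] = field(default_factory=list)

    def contrasts(self, outcome_sd: float | None = None) -> pd.DataFrame:
        """All pairwise class-mean differences with 95%/99% CIs and SMDs.

        The SMD denominator defaults to the whole-sample SD of the outcome.
        Differences are antisymmetric: the table lists each unordered pair
        once as (a vs b) with a > b, matching `diff = mean_a - mean_b`.
        """
        sd = self.outcome_sd if outcome_sd is None else outcome_sd
        K = self.class_means.size
        z95 = stats.norm.ppf(0.975)
        z99 = stats.norm.ppf(0.995)
        rows = []
        for a in range(1, K):
            for b in range(a):
                diff = self.class_means[a] - self.class_means[b]
                var = (
                    self.cov_params[a, a] + self.cov_params[b, b] - 2 * self.cov_params[a, b]
                )
                se = float(np.sqrt(max(var, 0.0)))
                rows.append({
                    "contrast": f"C{a + 1} vs. C{b + 1}",
                    "diff": diff,
                    "se": se,
                    "ci95_low": diff - z95 * se, "ci95_high": diff + z95 * se,
                    "ci99_low": diff - z99 * se, "ci99_high": diff + z99 * se,
                    "smd": smd(diff, sd),
                })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"BCH distal outcome model: K={self.class_means.size}, "
            f"n={self.model.n}, clusters={self.n_clusters}",
            "class means: " + ", ".join(f"{m:.3f}" for m in self.class_means),
            f"Wald test of equal means: chi2({self.wald_df})={self.wald_stat:.2f}, "
            f"p={self.wald_p:.3g}",
        ]
        if self.covariate_coefs.size:
            lines.append(
                "covariate coefficients: "
                + ", ".join(f"{c:.3f}" for c in self.covariate_coefs)
            )
        if self.flags:
            lines.append("flags: " + "; ".join(self.flags))
        return "\n".join(lines)
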