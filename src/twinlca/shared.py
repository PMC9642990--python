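"""Decomposition of aging variance into parts shared with lifestyle classes.

The statistic implemented here splits the total variance of a biological
aging measure into four non-overlapping parts using two AE (or matching
family) biometric fits — one to the outcome itself ("total") and one to the
outcome residualised on the latent-class structure ("residual"):

* genetic variance shared with the lifestyle patterns: ``(aTot2 - aRes2) / VarTot``
* environmental variance shared with the patterns: ``(eTot2 - eRes2) / VarTot``
* genetic variance unique to aging: ``aRes2 / VarTot``
* environmental variance unique to aging: ``eRes2 / VarTot``

By construction the four shares sum to 1 when ``VarTot`` is taken from the
total-fit model (the default), and the shared parts sum to the proportion of
variance explained by the class structure, ``Var(Model)/VarTot``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class VarianceShareResult:
    """Variance decomposition of an aging outcome against lifestyle classes.

    All inputs are unstandardized variance components; the derived
    proportions are relative to ``var_tot``.
    """

    var_tot: float
    var_model: float
    var_res: float
    a2_tot: float
    e2_tot: float
    a2_res: float
    e2_res: float
    c2_tot: float = 0.0
    c2_res: float = 0.0

    @property
    def shared_genetic(self) -> float:
        return (self.a2_tot - self.a2_res) / self.var_tot

    @property
    def shared_environment(self) -> float:
        return (self.e2_tot - self.e2_res) / self.var_tot

    @property
    def unique_genetic(self) -> float:
        return self.a2_res / self.var_tot

    @property
    def unique_environment(self) -> float:
        return self.e2_res / self.var_tot

    @property
    def model_share(self) -> float:
        """Proportion of total variance explained by the class structure."""
        return self.var_model / self.var_tot

    def shares(self, clamp_zero: bool = False) -> dict[str, float]:
        out = {
            "shared_genetic": self.shared_genetic,
            "shared_environment": self.shared_environment,
            "unique_genetic": self.unique_genetic,
            "unique_environment": self.unique_environment,
        }
        if clamp_zero:
            out = {k: max(v, 0.0) for k, v in out.items()}
        return out

    def as_dict(self) -> dict[str, float]:
        return {
            "var_tot": self.var_tot,
            "var_model": self.var_model,
            "var_res": self.var_res,
            "a2_tot": self.a2_tot,
            "e2_tot": self.e2_tot,
            "c2_tot": self.c2_tot,
            "a2_res": self.a2_res,
            "e2_res": self.e2_res,
            "c2_res": self.c2_res,
            "model_share": self.model_share,
            **self.shares(),
        }


def residual_scores(
    outcome: np.ndarray, weights: np.ndarray, class_means: np.ndarray
) -> np.ndarray:
    """Outcome minus its class-structure expectation, per individual.

    ``residual_i = y_i - sum_k w_ik * mu_k`` where ``w`` is the individual's
    BCH weight row (or, by configuration upstream, the posterior row) and
    ``mu`` are the class means from a no-covariate distal fit.  Missing
    outcomes stay missing.
    """
    outcome = np.asarray(outcome, dtype=float)
    weights = np.asarray(weights, dtype=float)
    class_means = np.asarray(class_means, dtype=float)
    if weights.ndim != 2 or weights.shape[0] != outcome.shape[0]:
        raise ValueError("weights must be n x K aligned with the outcome")
    if class_means.shape != (weights.shape[1],):
        raise ValueError("class_means must have one entry per class")
    return outcome - weights @ class_means


def decompose_shared(total_fit, resid_fit, warn_negative: bool = True) -> VarianceShareResult:
    """Combine total and residual biometric fits into the shared-variance result.

    Both fits must be from the same model family (AE in the standard
    pipeline).  Negative shared estimates (``aRes2 > aTot2`` by sampling) are
    reported as-is with a warning rather than clamped, so the estimator stays
    unbiased across replicates; use ``VarianceShareResult.shares(clamp_zero=True)``
    for presentation-style non-negative stacks.
    """
    if total_fit.model != resid_fit.model:
        raise ValueError(
            f"mismatched model families: {total_fit.model} vs {resid_fit.model}"
        )
    comp_tot = total_fit.raw_components
    comp_res = resid_fit.raw_components
    var_tot = float(sum(comp_tot.values()))
    var_res = float(sum(comp_res.values()))
    result = VarianceShareResult(
        var_tot=var_tot,
        var_model=var_tot - var_res,
        var_res=var_res,
        a2_tot=comp_tot.get("a2", 0.0),
        e2_tot=comp_tot.get("e2", 0.0),
        a2_res=comp_res.get("a2", 0.0),
        e2_res=comp_res.get("e2", 0.0),
        c2_tot=comp_tot.get("c2", comp_tot.get("d2", 0.0)),
        c2_res=comp_res.get("c2", comp_res.get("d2", 0.0)),
    )
    if warn_negative and (result.shared_genetic < 0 or result.shared_environment < 0):
        warnings.warn(
            "negative shared variance estimate (residual component exceeds total); "
            "reported unclamped", stacklevel=2,
        )
    return result
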