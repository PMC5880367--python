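"""Model comparison: information criteria, likelihood-ratio tests, and
parametric-bootstrap goodness of fit.

Non-nested models (different numbers of classes) are compared by BIC with a
boundary-adjusted parameter count; nested models (same K, covariate added)
by a likelihood-ratio test; the absolute fit of a selected model by the
likelihood-ratio chi-square G² over the 2^J response-pattern table, whose
p-value is obtained by parametric bootstrap because sparse pattern tables
make the chi-square reference distribution unreliable.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .data import ResponseData
from .model import FittedModel, ModelSpec, fit_em


@dataclass
class InformationCriteria:
    loglik: float
    effective_params: int
    n: int
    bic: float
    aic: float


@dataclass
class TestResult:
    g2: float
    df: int
    p_value: float | None


@dataclass
class GOFResult:
    g2_observed: float
    df_reported: int
    n_bootstrap: int
    bootstrap_g2: np.ndarray = field(repr=False)
    p_value: float
    n_redraws: int = 0


def information_criteria(fitted: FittedModel, n: int) -> InformationCriteria:
    """BIC and AIC from the boundary-adjusted effective parameter count."""
    if n < 1:
        raise ValueError("n must be >= 1")
    k = fitted.effective_params
    return InformationCriteria(
        loglik=fitted.loglik, effective_params=k, n=n,
        bic=-2.0 * fitted.loglik + k * np.log(n),
        aic=-2.0 * fitted.loglik + 2.0 * k)


def _covariate_extra_params(spec: ModelSpec, n_items: int) -> int:
    if spec.covariate_mode == "membership":
        return spec.n_classes - 1
    if spec.covariate_mode == "response":
        return spec.n_classes * n_items
    return 0


def likelihood_ratio_test(nested: FittedModel,
                          extended: FittedModel) -> TestResult:
    """LRT for adding covariate terms at fixed K.

    G² = 2(ℓ_extended − ℓ_nested); df is the number of covariate
    coefficients added (one age slope per non-reference class for a
    membership covariate; one per class-item for a response covariate).
    A significant test favors the extended model.
    """
    if nested.spec.n_classes != extended.spec.n_classes:
        raise ValueError("LRT requires models with the same number of classes")
    if nested.spec.covariate_mode != "none" or \
            extended.spec.covariate_mode == "none":
        raise ValueError("models are not nested by covariate structure")
    g2 = 2.0 * (extended.loglik - nested.loglik)
    if g2 < -1e-6:
        raise ValueError(
            "extended model fits worse than nested model: failed fit")
    g2 = max(g2, 0.0)
    df = _covariate_extra_params(extended.spec,
                                 extended.params.n_items)
    return TestResult(g2=g2, df=df, p_value=float(chi2.sf(g2, df)))


# ---------------------------------------------------------------------------
# G² over the response-pattern table


def enumerate_patterns(n_items: int) -> np.ndarray:
    """All 2^J binary response patterns, in lexicographic order."""
    return np.array(list(itertools.product((0, 1), repeat=n_items)),
                    dtype=float)


def expected_pattern_counts(fitted: FittedModel,
                            data: ResponseData) -> np.ndarray:
    """Expected count of each of the 2^J patterns under the fitted model,
    marginalizing any covariate over the empirical age distribution."""
    spec, params = fitted.spec, fitted.params
    S = enumerate_patterns(data.n_items)  # (2^J, J)
    pi = params.class_probs(
        data.age_months if spec.covariate_mode == "membership" else None)
    P = params.response_probs(
        data.age_months if spec.covariate_mode == "response" else None)
    if P.ndim == 2:
        # (K, 2^J): 0**0 == 1 keeps exact boundary probabilities valid
        class_pat = np.prod(
            np.where(S[None, :, :] == 1, P[:, None, :], 1 - P[:, None, :]),
            axis=2)
        if pi.ndim == 1:
            return data.n * (pi @ class_pat)
        return (pi @ class_pat).sum(axis=0)
    per_subject = np.prod(
        np.where(S[None, None, :, :] == 1,
                 P[:, :, None, :], 1 - P[:, :, None, :]), axis=3)
    if pi.ndim == 1:
        pi = np.broadcast_to(pi, (data.n, spec.n_classes))
    return np.einsum("nk,nks->s", pi, per_subject)


def observed_pattern_counts(data: ResponseData) -> np.ndarray:
    S = enumerate_patterns(data.n_items)
    idx = data.responses @ (2 ** np.arange(data.n_items - 1, -1, -1))
    return np.bincount(idx, minlength=len(S)).astype(float)


def g2_statistic(fitted: FittedModel, data: ResponseData) -> TestResult:
    """Likelihood-ratio chi-square over the 2^J response-pattern table.

    G² = 2 Σ_s O_s ln(O_s / E_s) over patterns with O_s > 0.  The nominal
    df is (2^J − 1) − effective_params, floored at 0; with sparse tables
    the parametric bootstrap, not this df, is the authoritative reference.
    """
    O = observed_pattern_counts(data)
    E = expected_pattern_counts(fitted, data)
    bad = (O > 0) & (E <= 0)
    if bad.any():
        s = enumerate_patterns(data.n_items)[np.flatnonzero(bad)[0]]
        raise ValueError(
            f"pattern {s.astype(int).tolist()} observed but has zero "
            "expected count under the fitted model")
    mask = O > 0
    g2 = 2.0 * float((O[mask] * np.log(O[mask] / E[mask])).sum())
    g2 = max(g2, 0.0)
    df = (2 ** data.n_items - 1) - fitted.effective_params
    if df <= 0:
        warnings.warn("nonpositive nominal df for G²; floored at 0 — "
                      "use the bootstrap p-value")
        return TestResult(g2=g2, df=0, p_value=None)
    return TestResult(g2=g2, df=df, p_value=float(chi2.sf(g2, df)))


# ---------------------------------------------------------------------------
# Parametric bootstrap


def simulate_from_fitted(fitted: FittedModel, data: ResponseData,
                         rng) -> ResponseData:
    """Draw one replicate dataset from the fitted model, keeping each
    subject's observed age (and age group)."""
    spec, params = fitted.spec, fitted.params
    n, J = data.n, data.n_items
    pi = params.class_probs(
        data.age_months if spec.covariate_mode == "membership" else None)
    if pi.ndim == 1:
        pi = np.broadcast_to(pi, (n, spec.n_classes))
    cum = np.cumsum(pi, axis=1)
    z = (rng.random(n)[:, None] < cum).argmax(axis=1)
    P = params.response_probs(
        data.age_months if spec.covariate_mode == "response" else None)
    probs = P[np.arange(n), z] if P.ndim == 3 else P[z]
    Y = (rng.random((n, J)) < probs).astype(np.int8)
    return ResponseData(data.subject_id, Y, data.age_months,
                        data.age_group, data.item_names)


def bootstrap_gof_p(fitted: FittedModel, data: ResponseData,
                    B: int = 1000, seed: int = 0,
                    max_redraws: int = 20) -> GOFResult:
    """Parametric-bootstrap p-value for the G² of a fitted model.

    For each of B replicates: simulate a dataset of the same size from the
    fitted model (subjects keep their observed ages), refit the same model
    spec under the same restart policy, and record the replicate's G².
    p = (1 + #{G²_b ≥ G²_obs}) / (B + 1), hence p ≥ 1/(B+1).  Replicates
    whose refit does not converge are re-drawn with a fresh sub-seed (up to
    ``max_redraws`` in total, after which the non-converged fit is kept).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    obs = g2_statistic(fitted, data)
    master = np.random.default_rng(seed)
    sub_seeds = iter(master.integers(0, 2**31 - 1, size=B + max_redraws))
    g2_boot = np.empty(B)
    redraws = 0
    for b in range(B):
        while True:
            s = int(next(sub_seeds))
            rng = np.random.default_rng(s)
            rep = simulate_from_fitted(fitted, data, rng)
            refit = fit_em(rep, fitted.spec, n_restarts=fitted.restarts_run,
                           tol=fitted.tol, max_iter=fitted.max_iter, seed=s)
            if refit.converged or redraws >= max_redraws:
                break
            redraws += 1
        g2_boot[b] = g2_statistic(refit, rep).g2
    p = (1.0 + float((g2_boot >= obs.g2).sum())) / (B + 1.0)
    return GOFResult(g2_observed=obs.g2, df_reported=obs.df, n_bootstrap=B,
                     bootstrap_g2=g2_boot, p_value=p, n_redraws=redraws)


# ---------------------------------------------------------------------------
# Comparison report


def compare_models(fits: list[FittedModel], n: int,
                   labels: list[str] | None = None) -> pd.DataFrame:
    """Side-by-side table of log-likelihood, parameter counts, BIC and AIC,
    flagging the lowest-BIC model (ties broken toward the earlier entry).

    AIC is computed and reported but model selection is by BIC.
    """
    rows = []
    for fit in fits:
        ic = information_criteria(fit, n)
        rows.append({
            "n_classes": fit.spec.n_classes,
            "covariate": fit.spec.covariate_mode,
            "loglik": fit.loglik,
            "n_free": fit.n_free_params,
            "n_boundary": fit.n_boundary_params,
            "effective_params": fit.effective_params,
            "bic": ic.bic,
            "aic": ic.aic,
        })
    table = pd.DataFrame(rows)
    if labels is not None:
        table.insert(0, "model", labels)
    selected = int(np.argmin(table["bic"].to_numpy()))
    table["selected"] = [i == selected for i in range(len(fits))]
    return table
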