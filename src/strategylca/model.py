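"""Binary-response latent class models fitted by EM.

The model family: each subject i belongs to one of K latent classes
("strategies"); conditional on class c, responses on the J items are
independent Bernoulli draws with success probabilities p_cj.  The observed
likelihood is the finite mixture

    L = prod_i  sum_c  pi_c(x_i) * prod_j p_cj(x_i)^y_ij (1 - p_cj(x_i))^(1 - y_ij)

where x_i is the subject's age in months.  Age may enter in one of three
ways (``covariate_mode``):

* ``none`` — pi and p are constants;
* ``membership`` — pi_c(x) follows a multinomial logit in age
  (concomitant-variable latent class regression), p constant;
* ``response`` — p_cj(x) follows a per class-item logistic in age,
  pi constant.

Fitting is by EM with multiple random restarts.  Response probabilities are
clipped to [1e-10, 1 - 1e-10] inside likelihood evaluation only; the stored
estimates are unclipped, so probabilities estimated at exactly 0 or 1 are
visible to the boundary-parameter count used by the information criteria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit, logsumexp

from .data import ResponseData

#: Clipping bound applied to probabilities inside likelihood evaluation.
PROB_CLIP = 1e-10

#: A class whose total posterior weight falls below this is degenerate; its
#: parameters are frozen at their previous values for that M-step.
DEGENERATE_WEIGHT = 1e-8

#: Box constraint (on the standardized-age scale) for logistic coefficients,
#: guarding against divergence under quasi-complete separation.
COEF_BOUND = 50.0

COVARIATE_MODES = ("none", "membership", "response")


class DegenerateSubjectError(ValueError):
    """Raised when a subject has zero likelihood under every class."""


@dataclass(frozen=True)
class ModelSpec:
    """Number of latent classes and where the age covariate enters."""

    n_classes: int
    covariate_mode: str = "none"

    def __post_init__(self):
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.covariate_mode not in COVARIATE_MODES:
            raise ValueError(f"covariate_mode must be one of {COVARIATE_MODES}")
        if self.covariate_mode == "membership" and self.n_classes < 2:
            raise ValueError("membership covariate requires n_classes >= 2")

    def n_free_params(self, n_items: int) -> int:
        """Nominal free-parameter count (before boundary adjustment)."""
        K, J = self.n_classes, n_items
        mem = 1 if self.covariate_mode == "membership" else 0
        resp = 1 if self.covariate_mode == "response" else 0
        return (K - 1) * (1 + mem) + K * J * (1 + resp)


@dataclass
class Parameters:
    """Model parameters on the logit scale.

    ``membership_intercepts``/``membership_slopes`` are the multinomial-logit
    coefficients of classes 2..K against reference class 1 (slopes in
    logit units per month; all zero unless covariate_mode = membership).
    ``response_intercepts`` is K×J on the logit scale (±inf encodes exact
    boundary probabilities 0/1); ``response_slopes`` is K×J per-month logit
    slopes (all zero unless covariate_mode = response).
    """

    membership_intercepts: np.ndarray
    membership_slopes: np.ndarray
    response_intercepts: np.ndarray
    response_slopes: np.ndarray

    def __post_init__(self):
        self.membership_intercepts = np.atleast_1d(
            np.asarray(self.membership_intercepts, dtype=float))
        self.membership_slopes = np.atleast_1d(
            np.asarray(self.membership_slopes, dtype=float))
        self.response_intercepts = np.atleast_2d(
            np.asarray(self.response_intercepts, dtype=float))
        self.response_slopes = np.atleast_2d(
            np.asarray(self.response_slopes, dtype=float))

    @property
    def n_classes(self) -> int:
        return self.response_intercepts.shape[0]

    @property
    def n_items(self) -> int:
        return self.response_intercepts.shape[1]

    @classmethod
    def from_probs(cls, class_probs, response_probs) -> "Parameters":
        """Build covariate-free parameters from probability-scale inputs."""
        pi = np.asarray(class_probs, dtype=float)
        p = np.atleast_2d(np.asarray(response_probs, dtype=float))
        K = p.shape[0]
        if pi.shape != (K,):
            raise ValueError("class_probs length must match response rows")
        with np.errstate(divide="ignore"):
            logpi = np.log(np.maximum(pi, 1e-300))
            intercepts = np.where(
                (p == 0) | (p == 1),
                np.where(p == 1, np.inf, -np.inf),
                logit(np.clip(p, 1e-300, 1 - 1e-16)),
            )
        return cls(
            membership_intercepts=logpi[1:] - logpi[0] if K > 1 else np.zeros(0),
            membership_slopes=np.zeros(max(K - 1, 0)),
            response_intercepts=intercepts,
            response_slopes=np.zeros_like(p),
        )

    # -- probability-scale views ------------------------------------------

    def class_probs(self, age_months=None) -> np.ndarray:
        """Class membership probabilities.

        Returns shape (K,) when a scalar age (or no covariate) is given,
        else (n, K).
        """
        K = self.n_classes
        if K == 1:
            if age_months is None or np.ndim(age_months) == 0:
                return np.ones(1)
            return np.ones((len(np.atleast_1d(age_months)), 1))
        if age_months is None:
            if np.any(self.membership_slopes != 0):
                raise ValueError("age_months required: membership depends on age")
            age_months = 0.0
        age = np.atleast_1d(np.asarray(age_months, dtype=float))
        logits = np.zeros((len(age), K))
        logits[:, 1:] = (self.membership_intercepts[None, :]
                         + np.outer(age, self.membership_slopes))
        logits -= logsumexp(logits, axis=1, keepdims=True)
        pi = np.exp(logits)
        return pi[0] if np.ndim(age_months) == 0 else pi

    def response_probs(self, age_months=None) -> np.ndarray:
        """Success probabilities: (K, J), or (n, K, J) when age-dependent."""
        if not np.any(self.response_slopes != 0):
            return expit(self.response_intercepts)
        if age_months is None:
            raise ValueError("age_months required: responses depend on age")
        age = np.atleast_1d(np.asarray(age_months, dtype=float))
        eta = (self.response_intercepts[None, :, :]
               + age[:, None, None] * self.response_slopes[None, :, :])
        return expit(eta)

    def permute_classes(self, order) -> "Parameters":
        """Relabel classes by ``order`` (new class c = old class order[c]),
        re-referencing the membership logit to the new class 1."""
        order = np.asarray(order)
        K = self.n_classes
        full_int = np.concatenate([[0.0], self.membership_intercepts])
        full_slp = np.concatenate([[0.0], self.membership_slopes])
        new_int = full_int[order] - full_int[order[0]]
        new_slp = full_slp[order] - full_slp[order[0]]
        return Parameters(
            membership_intercepts=new_int[1:] if K > 1 else np.zeros(0),
            membership_slopes=new_slp[1:] if K > 1 else np.zeros(0),
            response_intercepts=self.response_intercepts[order],
            response_slopes=self.response_slopes[order],
        )


@dataclass
class FittedModel:
    """Result of an EM fit, including boundary-adjusted parameter counts."""

    spec: ModelSpec
    params: Parameters
    loglik: float
    posteriors: np.ndarray
    n_free_params: int
    n_boundary_params: int
    effective_params: int
    converged: bool
    restarts_run: int
    best_restart_seed: int
    loglik_history: np.ndarray = field(default=None, repr=False)
    age_mean: float = np.nan
    n_obs: int = 0
    tol: float = 1e-8
    max_iter: int = 1000

    def to_json(self) -> str:
        """Serialize spec, parameter blocks, fit summary and seed."""
        import json

        from . import __version__

        def _clean(a):
            return [[None if not np.isfinite(v) else v for v in row]
                    for row in np.atleast_2d(a).tolist()]

        return json.dumps({
            "software": {"name": "strategylca", "version": __version__},
            "spec": {"n_classes": self.spec.n_classes,
                     "covariate_mode": self.spec.covariate_mode},
            "params": {
                "membership_intercepts":
                    self.params.membership_intercepts.tolist(),
                "membership_slopes": self.params.membership_slopes.tolist(),
                "response_intercepts_logit":
                    _clean(self.params.response_intercepts),
                "response_slopes": self.params.response_slopes.tolist(),
                "response_probs": np.asarray(
                    self.params.response_probs(
                        self.age_mean
                        if self.spec.covariate_mode == "response"
                        else None)).reshape(
                            self.spec.n_classes, -1).tolist(),
            },
            "loglik": self.loglik,
            "n_free_params": self.n_free_params,
            "n_boundary_params": self.n_boundary_params,
            "effective_params": self.effective_params,
            "converged": self.converged,
            "restarts_run": self.restarts_run,
            "best_restart_seed": self.best_restart_seed,
            "n_obs": self.n_obs,
        }, indent=2)


# ---------------------------------------------------------------------------
# Likelihood machinery


def _check_dims(data: ResponseData, spec: ModelSpec, params: Parameters):
    if params.n_classes != spec.n_classes:
        raise ValueError("parameter class count does not match spec")
    if params.n_items != data.n_items:
        raise ValueError("parameter item count does not match data")


def _log_class_conditionals(data, params) -> np.ndarray:
    """(n, K) matrix of log Pr(y_i | class c, x_i), with clipping."""
    Y = data.responses.astype(float)
    P = params.response_probs(
        data.age_months if np.any(params.response_slopes != 0) else None)
    P = np.clip(P, PROB_CLIP, 1 - PROB_CLIP)
    logP, log1P = np.log(P), np.log1p(-P)
    if P.ndim == 2:
        return Y @ logP.T + (1 - Y) @ log1P.T
    return (np.einsum("nj,nkj->nk", Y, logP)
            + np.einsum("nj,nkj->nk", 1 - Y, log1P))


def _log_joint(data, spec, params) -> np.ndarray:
    """(n, K) matrix of log [pi_c(x_i) Pr(y_i | c, x_i)]."""
    pi = params.class_probs(
        data.age_months if spec.covariate_mode == "membership" else None)
    if pi.ndim == 1:
        pi = np.broadcast_to(pi, (data.n, spec.n_classes))
    with np.errstate(divide="ignore"):
        return np.log(pi) + _log_class_conditionals(data, params)


def log_likelihood(data: ResponseData, spec: ModelSpec,
                   params: Parameters) -> float:
    """Observed-data log-likelihood of the mixture model.

    Returns -inf (with a warning, not an exception) if some subject has
    probability zero under every class.
    """
    _check_dims(data, spec, params)
    per_subject = logsumexp(_log_joint(data, spec, params), axis=1)
    if np.isneginf(per_subject).any():
        warnings.warn("some subject has zero likelihood under every class")
        return -np.inf
    return float(per_subject.sum())


def e_step(data: ResponseData, spec: ModelSpec,
           params: Parameters) -> np.ndarray:
    """Posterior class responsibilities; each row sums to 1."""
    _check_dims(data, spec, params)
    lj = _log_joint(data, spec, params)
    norm = logsumexp(lj, axis=1, keepdims=True)
    bad = np.isneginf(norm[:, 0])
    if bad.any():
        raise DegenerateSubjectError(
            f"subject index {int(np.flatnonzero(bad)[0])} has zero "
            f"likelihood under every class for the given parameters")
    return np.exp(lj - norm)


# ---------------------------------------------------------------------------
# M-step


def _standardize(age: np.ndarray):
    mean = float(age.mean())
    sd = float(age.std())
    if sd <= 0:
        sd = 1.0  # constant ages: slope carries no information
    return (age - mean) / sd, mean, sd


def _fit_weighted_multinomial_logit(z, post, warm, max_newton=30):
    """Maximize sum_i sum_c post_ic log softmax_c([0, a + b z_i]).

    Damped Newton iterations from the (2(K-1),) warm start [a..., b...] on
    the standardized scale; the objective is concave and the result is
    never worse than the warm start (generalized EM).
    """
    n, K = post.shape
    zz = z * z

    def q_and_pi(theta):
        logits = np.zeros((n, K))
        logits[:, 1:] = theta[:K - 1] + np.outer(z, theta[K - 1:])
        m = logits.max(axis=1, keepdims=True)
        e = np.exp(logits - m)
        s = e.sum(axis=1, keepdims=True)
        return float((post * (logits - m - np.log(s))).sum()), e / s

    theta = np.clip(warm, -COEF_BOUND, COEF_BOUND)
    q, pi = q_and_pi(theta)
    for _ in range(max_newton):
        P = pi[:, 1:]
        resid = post[:, 1:] - P
        grad = np.concatenate([resid.sum(axis=0), z @ resid])
        if np.abs(grad).max() < 1e-8:
            break
        # Hessian blocks of the concave objective
        S0 = np.einsum("ic,id->cd", P, P) - np.diag(P.sum(axis=0))
        S1 = np.einsum("i,ic,id->cd", z, P, P) - np.diag(z @ P)
        S2 = np.einsum("i,ic,id->cd", zz, P, P) - np.diag(zz @ P)
        H = np.block([[S0, S1], [S1, S2]])
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            break
        improved = False
        t = 1.0
        for _ in range(30):  # backtracking keeps Q non-decreasing
            cand = np.clip(theta + t * step, -COEF_BOUND, COEF_BOUND)
            qc, pic = q_and_pi(cand)
            if qc > q:
                theta, q, pi = cand, qc, pic
                improved = True
                break
            t *= 0.5
        if not improved:
            break
    return theta


def _fit_weighted_logistic(z, y, w, warm, max_newton=30):
    """Weighted logistic regression of y on z (2 coefficients), by damped
    Newton from the warm start; never worse than the warm start."""

    def q_and_p(theta):
        eta = theta[0] + theta[1] * z
        return float(w @ (y * eta - np.logaddexp(0.0, eta))), expit(eta)

    theta = np.clip(warm, -COEF_BOUND, COEF_BOUND)
    q, p = q_and_p(theta)
    for _ in range(max_newton):
        r = w * (y - p)
        grad = np.array([r.sum(), z @ r])
        if np.abs(grad).max() < 1e-8:
            break
        s = w * p * (1.0 - p)
        H = -np.array([[s.sum(), z @ s], [z @ s, (z * z) @ s]])
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            break
        improved = False
        t = 1.0
        for _ in range(30):
            cand = np.clip(theta + t * step, -COEF_BOUND, COEF_BOUND)
            qc, pc = q_and_p(cand)
            if qc > q:
                theta, q, p = cand, qc, pc
                improved = True
                break
            t *= 0.5
        if not improved:
            break
    return theta


def m_step(data: ResponseData, spec: ModelSpec, posteriors: np.ndarray,
           prev_params: Parameters | None = None,
           newton_cap: int = 30) -> Parameters:
    """Maximize the expected complete-data log-likelihood.

    Closed form for the covariate-free blocks; iterative weighted
    multinomial-logit / logistic fits (warm-started at ``prev_params`` so
    the objective never decreases) for the covariate blocks.  Classes with
    total posterior weight below ``DEGENERATE_WEIGHT`` keep their previous
    parameters.
    """
    Y = data.responses.astype(float)
    n, J = Y.shape
    K = spec.n_classes
    post = np.asarray(posteriors, dtype=float)
    w = post.sum(axis=0)
    degenerate = w < DEGENERATE_WEIGHT
    if degenerate.any():
        warnings.warn(
            f"degenerate class(es) {np.flatnonzero(degenerate).tolist()}: "
            "posterior weight ~ 0; parameters held at previous values")

    # response probabilities (posterior-weighted item means) --------------
    if spec.covariate_mode != "response":
        with np.errstate(invalid="ignore"):
            p = (post.T @ Y) / np.maximum(w[:, None], DEGENERATE_WEIGHT)
        p = np.clip(p, 0.0, 1.0)
        with np.errstate(divide="ignore"):
            resp_int = np.where(
                (p == 0) | (p == 1),
                np.where(p == 1, np.inf, -np.inf),
                logit(np.clip(p, 1e-300, 1 - 1e-16)))
        resp_slp = np.zeros((K, J))
        if degenerate.any() and prev_params is not None:
            resp_int[degenerate] = prev_params.response_intercepts[degenerate]
    else:
        z, mean, sd = _standardize(data.age_months)
        resp_int = np.empty((K, J))
        resp_slp = np.empty((K, J))
        for c in range(K):
            for j in range(J):
                if degenerate[c] and prev_params is not None:
                    resp_int[c, j] = prev_params.response_intercepts[c, j]
                    resp_slp[c, j] = prev_params.response_slopes[c, j]
                    continue
                if prev_params is not None:
                    A = prev_params.response_intercepts[c, j]
                    B = prev_params.response_slopes[c, j]
                    warm = np.array([A + B * mean, B * sd])
                    warm = np.nan_to_num(warm, posinf=COEF_BOUND,
                                         neginf=-COEF_BOUND)
                else:
                    warm = np.zeros(2)
                a, b = _fit_weighted_logistic(z, Y[:, j], post[:, c], warm,
                                              max_newton=newton_cap)
                resp_slp[c, j] = b / sd
                resp_int[c, j] = a - b * mean / sd

    # class membership ----------------------------------------------------
    if K == 1:
        mem_int = np.zeros(0)
        mem_slp = np.zeros(0)
    elif spec.covariate_mode != "membership":
        pi = w / n
        with np.errstate(divide="ignore"):
            logpi = np.log(np.maximum(pi, 1e-300))
        mem_int = logpi[1:] - logpi[0]
        mem_slp = np.zeros(K - 1)
    else:
        z, mean, sd = _standardize(data.age_months)
        if prev_params is not None:
            A = prev_params.membership_intercepts
            B = prev_params.membership_slopes
            warm = np.concatenate([A + B * mean, B * sd])
        else:
            warm = np.zeros(2 * (K - 1))
        theta = _fit_weighted_multinomial_logit(z, post, warm,
                                                max_newton=newton_cap)
        a, b = theta[:K - 1], theta[K - 1:]
        mem_slp = b / sd
        mem_int = a - b * mean / sd

    return Parameters(mem_int, mem_slp, resp_int, resp_slp)


# ---------------------------------------------------------------------------
# EM driver


def _random_init(spec: ModelSpec, n_items: int, rng) -> Parameters:
    """Random start: response probs ~ U(0.2, 0.8), class weights ~
    symmetric Dirichlet(1), covariate slopes zero."""
    K, J = spec.n_classes, n_items
    p = rng.uniform(0.2, 0.8, size=(K, J))
    pi = rng.dirichlet(np.ones(K)) if K > 1 else np.ones(1)
    return Parameters.from_probs(pi, p)


def _single_run_fast(data, spec, params, tol, max_iter):
    """Specialized EM loop for covariate_mode='none': closed-form M-step on
    probability arrays, with Parameters rebuilt only on exit."""
    Y = data.responses.astype(float)
    Yc = 1.0 - Y
    n, J = Y.shape
    K = spec.n_classes
    pi = params.class_probs()
    P = np.clip(params.response_probs(), 0.0, 1.0)
    ll = -np.inf
    history = []
    converged = False
    with np.errstate(divide="ignore"):
        for _ in range(max_iter):
            Pc = np.clip(P, PROB_CLIP, 1 - PROB_CLIP)
            lj = (np.log(np.maximum(pi, 1e-300))[None, :]
                  + Y @ np.log(Pc).T + Yc @ np.log1p(-Pc).T)
            m = lj.max(axis=1)
            B = np.exp(lj - m[:, None])
            sB = B.sum(axis=1)
            ll_new = float((m + np.log(sB)).sum())
            if ll_new < ll - 1e-8:
                warnings.warn(
                    "EM log-likelihood decreased beyond numerical slack")
            history.append(ll_new)
            if np.isfinite(ll) and ll_new - ll < tol * (abs(ll_new) + 1):
                converged = True
                break
            ll = ll_new
            post = B / sB[:, None]
            w = post.sum(axis=0)
            keep = w >= DEGENERATE_WEIGHT
            pi_new = w / n
            P_new = (post.T @ Y) / np.maximum(w[:, None], DEGENERATE_WEIGHT)
            P = np.where(keep[:, None], np.clip(P_new, 0.0, 1.0), P)
            pi = pi_new
    params = Parameters.from_probs(pi, P)
    return params, float(max(history)), np.array(history), converged


def _single_run(data, spec, params, tol, max_iter):
    if spec.covariate_mode == "none":
        return _single_run_fast(data, spec, params, tol, max_iter)
    ll = -np.inf
    history = []
    converged = False
    for _ in range(max_iter):
        lj = _log_joint(data, spec, params)
        m = lj.max(axis=1)
        B = np.exp(lj - m[:, None])
        sB = B.sum(axis=1)
        ll_new = float((m + np.log(sB)).sum())
        if ll_new < ll - 1e-8:
            warnings.warn("EM log-likelihood decreased beyond numerical slack")
        history.append(ll_new)
        if np.isfinite(ll) and ll_new - ll < tol * (abs(ll_new) + 1):
            converged = True
            break
        ll = ll_new
        post = B / sB[:, None]
        # a couple of damped Newton steps per covariate block suffice: the
        # warm-started partial M-step still increases Q (generalized EM)
        params = m_step(data, spec, post, prev_params=params, newton_cap=2)
    return params, float(max(history)), np.array(history), converged


def fit_em(data: ResponseData, spec: ModelSpec, n_restarts: int = 20,
           tol: float = 1e-8, max_iter: int = 1000,
           seed: int = 0) -> FittedModel:
    """Fit the latent class model by EM with multiple random restarts.

    Returns the restart achieving the highest log-likelihood, with classes
    relabeled in order of descending membership probability at the mean age
    (so class 1 is the largest group).  Reproducible given ``seed``.

    ``tol`` is a *relative* convergence criterion: a run stops when the
    log-likelihood gain of an iteration falls below ``tol * (|loglik| + 1)``
    (the convention of standard EM software for latent class models, which
    avoids thousands of idle iterations creeping along a likelihood ridge).
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be positive")
    n_patterns = len(np.unique(data.responses, axis=0))
    if spec.n_classes > n_patterns:
        warnings.warn(
            f"K={spec.n_classes} exceeds the {n_patterns} distinct response "
            "pattern(s) observed; fit may overparameterize")

    master = np.random.default_rng(seed)
    restart_seeds = master.integers(0, 2**31 - 1, size=n_restarts)
    best = None
    for rs in restart_seeds:
        rng = np.random.default_rng(int(rs))
        params0 = _random_init(spec, data.n_items, rng)
        params, ll, history, converged = _single_run(
            data, spec, params0, tol, max_iter)
        if best is None or ll > best[1]:
            best = (params, ll, history, converged, int(rs))
    params, ll, history, converged, best_seed = best

    # report classes sorted by descending size at the mean age
    age_mean = float(data.age_months.mean())
    pi_bar = params.class_probs(
        age_mean if spec.covariate_mode == "membership" else None)
    order = np.argsort(-pi_bar, kind="stable")
    params = params.permute_classes(order)
    posteriors = e_step(data, spec, params)

    fitted = FittedModel(
        spec=spec, params=params, loglik=ll, posteriors=posteriors,
        n_free_params=0, n_boundary_params=0, effective_params=0,
        converged=converged, restarts_run=n_restarts,
        best_restart_seed=best_seed, loglik_history=history,
        age_mean=age_mean, n_obs=data.n, tol=tol, max_iter=max_iter)
    nf, nb, eff = count_effective_parameters(fitted)
    fitted.n_free_params, fitted.n_boundary_params = nf, nb
    fitted.effective_params = eff
    return fitted


def classify(fitted: FittedModel) -> np.ndarray:
    """Modal class assignment (1-based); ties go to the lower class index."""
    if fitted.posteriors is None:
        raise ValueError("fitted model has no posteriors")
    return np.argmax(fitted.posteriors, axis=1) + 1


def count_effective_parameters(fitted: FittedModel,
                               boundary_tol: float = 1e-3):
    """Free, boundary, and effective (free − boundary) parameter counts.

    A response probability within ``boundary_tol`` of 0 or 1 is a boundary
    parameter.  A class whose membership probability (at the mean age) is
    within ``boundary_tol`` of 0 is itself a boundary parameter and its row
    of response parameters is removed from the free count entirely.
    """
    if not 0 < boundary_tol <= 0.01:
        raise ValueError("boundary_tol must be in (0, 0.01]")
    spec, params = fitted.spec, fitted.params
    K, J = spec.n_classes, params.n_items
    resp_cols = 1 + (spec.covariate_mode == "response")
    n_free = spec.n_free_params(J)

    pi = params.class_probs(
        fitted.age_mean if spec.covariate_mode == "membership" else None)
    empty = pi < boundary_tol

    age_arg = (fitted.age_mean
               if spec.covariate_mode == "response" else None)
    P = params.response_probs(age_arg)
    if P.ndim == 3:
        P = P[0]
    at_boundary = (P < boundary_tol) | (P > 1 - boundary_tol)

    n_boundary = int(empty.sum())
    n_free -= int(empty.sum()) * J * resp_cols
    n_boundary += int(at_boundary[~empty].sum())
    return n_free, n_boundary, max(n_free - n_boundary, 0)
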