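"""The four-step "studying variability" analysis.

1. Fit latent class models with 1..K_max classes (no covariates) and select
   the number of classes K* by lowest BIC (ties toward fewer classes).
2. Refit the K*-class model with age as a covariate on class membership and
   test the improvement with a likelihood-ratio test.
3. Fit a 1-class model with age as a covariate on the response
   probabilities (accuracy growth) and compare its BIC with the step-2
   model's: strategy use versus accuracy of execution.
4. Report the winning model: its response-probability table, its G² with a
   parametric-bootstrap p-value, modal class assignments, and the
   strategy-by-age-group percentage table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ResponseData
from .model import FittedModel, ModelSpec, classify, fit_em
from .selection import (GOFResult, TestResult, bootstrap_gof_p,
                        compare_models, information_criteria,
                        likelihood_ratio_test)


@dataclass
class StudyConfig:
    max_classes: int = 4
    n_restarts: int = 20
    tol: float = 1e-8
    max_iter: int = 1000
    bootstrap_B: int = 1000
    lrt_alpha: float = 0.05
    seed: int = 0


@dataclass
class StudyReport:
    fit_table: pd.DataFrame
    selected_k: int
    step1_fits: list = field(repr=False)
    membership_fit: FittedModel | None
    lrt: TestResult | None
    accuracy_fit: FittedModel | None
    final_model: FittedModel
    final_label: str
    response_prob_table: pd.DataFrame
    gof: GOFResult
    classifications: np.ndarray
    class_by_age: pd.DataFrame | None

    def to_json(self) -> str:
        d = {
            "fit_table": self.fit_table.to_dict(orient="records"),
            "selected_k": self.selected_k,
            "final_model": self.final_label,
            "lrt": (None if self.lrt is None else
                    {"g2": self.lrt.g2, "df": self.lrt.df,
                     "p_value": self.lrt.p_value}),
            "response_probs": self.response_prob_table.to_dict(
                orient="records"),
            "gof": {"g2": self.gof.g2_observed, "df": self.gof.df_reported,
                    "B": self.gof.n_bootstrap, "p_value": self.gof.p_value},
            "class_sizes": np.bincount(
                self.classifications,
                minlength=self.final_model.spec.n_classes + 1)[1:].tolist(),
            "class_by_age": (None if self.class_by_age is None else
                             self.class_by_age.to_dict(orient="index")),
        }
        return json.dumps(d, indent=2, default=float)

    def to_text(self) -> str:
        lines = ["Studying variability: model comparison", "-" * 60,
                 self.fit_table.to_string(index=False, float_format="%.3f"),
                 "",
                 f"Step 1: {self.selected_k} class(es) selected by BIC."]
        if self.lrt is not None:
            lines.append(
                f"Step 2: LRT for age on class membership: "
                f"G2 = {self.lrt.g2:.2f}, df = {self.lrt.df}, "
                f"p = {self.lrt.p_value:.4g}")
        lines.append(f"Step 3/4: final model = {self.final_label}")
        lines += ["", "Response probabilities (classes x items):",
                  self.response_prob_table.to_string(float_format="%.2f"),
                  "",
                  f"Goodness of fit: G2 = {self.gof.g2_observed:.2f} "
                  f"(df = {self.gof.df_reported}), bootstrap p = "
                  f"{self.gof.p_value:.3f} (B = {self.gof.n_bootstrap})"]
        if self.class_by_age is not None:
            lines += ["", "Percentage of children per class by age group:",
                      self.class_by_age.to_string(float_format="%.1f")]
        return "\n".join(lines)


def class_by_age_summary(labels, age_group) -> pd.DataFrame:
    """Row-normalized crosstab: percentage of each class within each age
    group (rows sum to 100).  Empty groups are simply absent."""
    labels = np.asarray(labels)
    age_group = np.asarray(age_group)
    if len(labels) != len(age_group):
        raise ValueError("labels and age_group must have equal length")
    tab = pd.crosstab(pd.Series(age_group, name="age_group"),
                      pd.Series(labels, name="class"), normalize="index")
    return 100.0 * tab


def _response_prob_table(fitted: FittedModel, data: ResponseData
                         ) -> pd.DataFrame:
    if fitted.spec.covariate_mode == "response":
        P = fitted.params.response_probs(data.age_months).mean(axis=0)
    else:
        P = fitted.params.response_probs()
    return pd.DataFrame(
        P, columns=data.item_names,
        index=[f"class {c + 1}" for c in range(fitted.spec.n_classes)])


def run_variability_analysis(data: ResponseData,
                             config: StudyConfig | None = None
                             ) -> StudyReport:
    """Run the full four-step analysis on screened response data."""
    cfg = config or StudyConfig()
    if data.n_items < 2:
        raise ValueError("need at least two items after screening")
    master = np.random.default_rng(cfg.seed)
    seeds = master.integers(0, 2**31 - 1, size=cfg.max_classes + 2)

    def _fit(spec, s):
        fit = fit_em(data, spec, n_restarts=cfg.n_restarts, tol=cfg.tol,
                     max_iter=cfg.max_iter, seed=int(s))
        if not fit.converged:
            # overparameterized grids can ridge-walk; allow one long retry
            fit = fit_em(data, spec, n_restarts=cfg.n_restarts, tol=cfg.tol,
                         max_iter=10 * cfg.max_iter, seed=int(s))
        if not fit.converged:
            raise RuntimeError(
                f"EM did not converge for K={spec.n_classes}, "
                f"covariate={spec.covariate_mode}")
        return fit

    # Step 1: number of classes by BIC, ties toward fewer classes
    step1 = [_fit(ModelSpec(k), seeds[k - 1])
             for k in range(1, cfg.max_classes + 1)]
    bics = [information_criteria(f, data.n).bic for f in step1]
    k_star = int(np.argmin(bics)) + 1
    base_fit = step1[k_star - 1]
    fits, labels = list(step1), [f"{k}-class" for k in
                                 range(1, cfg.max_classes + 1)]

    # Step 2: age on class membership
    lrt = None
    membership_fit = None
    if k_star >= 2:
        membership_fit = _fit(ModelSpec(k_star, "membership"),
                              seeds[cfg.max_classes])
        lrt = likelihood_ratio_test(base_fit, membership_fit)
        fits.append(membership_fit)
        labels.append(f"{k_star}-class + age on membership")
        step2_model = (membership_fit if lrt.p_value < cfg.lrt_alpha
                       else base_fit)
    else:
        step2_model = base_fit

    # Step 3: one strategy with age-growing accuracy
    accuracy_fit = _fit(ModelSpec(1, "response"), seeds[cfg.max_classes + 1])
    fits.append(accuracy_fit)
    labels.append("1-class + age on response")
    step2_bic = information_criteria(step2_model, data.n).bic
    acc_bic = information_criteria(accuracy_fit, data.n).bic
    if acc_bic < step2_bic:
        final_model = accuracy_fit
        final_label = "1-class + age on response (accuracy of execution)"
    else:
        final_model = step2_model
        if final_model is membership_fit:
            final_label = f"{k_star}-class + age on membership (strategy use)"
        else:
            final_label = f"{k_star}-class (strategy use, age-independent)"

    fit_table = compare_models(fits, data.n, labels=labels)

    # Step 4: absolute fit and strategy-by-age summary
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # df floor warning handled via report
        gof = bootstrap_gof_p(final_model, data, B=cfg.bootstrap_B,
                              seed=int(master.integers(0, 2**31 - 1)))
    labels_hat = classify(final_model)
    class_by_age = (class_by_age_summary(labels_hat, data.age_group)
                    if data.age_group is not None else None)

    return StudyReport(
        fit_table=fit_table, selected_k=k_star, step1_fits=step1,
        membership_fit=membership_fit, lrt=lrt, accuracy_fit=accuracy_fit,
        final_model=final_model, final_label=final_label,
        response_prob_table=_response_prob_table(final_model, data),
        gof=gof, classifications=labels_hat, class_by_age=class_by_age)
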