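"""Latent class analysis of strategy use in binary response data.

Bernoulli-mixture latent class models with optional age covariates on
class membership or response probabilities, fitted by EM; model selection
by BIC/LRT with boundary-adjusted parameter counts; parametric-bootstrap
goodness of fit; contingency utilities; and a synthetic-data generator
emulating a developmental causal-inference study.
"""

__version__ = "0.1.0"

from .contingency import (ContingencyTable2x2, fisher_exact_2x2,
                          pearson_chi_square_2x2)
from .data import ResponseData
from .experiments import (align_classes, recovery_experiment,
                          selection_experiment)
from .model import (FittedModel, ModelSpec, Parameters, classify,
                    count_effective_parameters, e_step, fit_em,
                    log_likelihood, m_step)
from .pipeline import (StudyConfig, StudyReport, class_by_age_summary,
                       run_variability_analysis)
from .scoring import ScoringScheme, score_responses, screen_item_variability
from .selection import (GOFResult, InformationCriteria, TestResult,
                        bootstrap_gof_p, compare_models, g2_statistic,
                        information_criteria, likelihood_ratio_test)
from .simulate import (GeneratorConfig, PRESETS, sample_ages,
                       simulate_dataset, study_config, write_dataset)

__all__ = [
    "ContingencyTable2x2", "FittedModel", "GOFResult", "GeneratorConfig",
    "InformationCriteria", "ModelSpec", "PRESETS", "Parameters",
    "ResponseData", "ScoringScheme", "StudyConfig", "StudyReport",
    "TestResult", "align_classes", "bootstrap_gof_p", "class_by_age_summary",
    "classify", "compare_models", "count_effective_parameters", "e_step",
    "fisher_exact_2x2", "fit_em", "g2_statistic", "information_criteria",
    "likelihood_ratio_test", "log_likelihood", "m_step",
    "pearson_chi_square_2x2", "recovery_experiment",
    "run_variability_analysis", "sample_ages", "score_responses",
    "screen_item_variability", "selection_experiment", "simulate_dataset",
    "study_config", "write_dataset",
]
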