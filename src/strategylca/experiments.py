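"""Simulation-study drivers: class-count selection consistency and
response-probability recovery under the study-structured generator.

These are the experiments a user runs to check that, at realistic sample
sizes, BIC recovers the generating number of classes and EM recovers the
generating response probabilities (after resolving label switching by an
optimal class alignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .model import ModelSpec, fit_em
from .selection import information_criteria
from .simulate import simulate_dataset, study_config


def align_classes(fitted_probs: np.ndarray,
                  true_probs: np.ndarray) -> np.ndarray:
    """Permutation mapping generating classes to fitted classes.

    Minimizes the total absolute difference between matched
    response-probability rows (optimal assignment); returns ``perm`` with
    ``fitted_probs[perm[c]]`` aligned to ``true_probs[c]``.
    """
    cost = np.abs(true_probs[:, None, :] - fitted_probs[None, :, :]).sum(-1)
    _, perm = linear_sum_assignment(cost)
    return perm


def _scaled_groups(n_total: int) -> tuple:
    """Scale the 23/23/23/21 age-group mix to a total of ``n_total``."""
    base = np.array([23, 23, 23, 21], dtype=float)
    counts = np.floor(base / base.sum() * n_total).astype(int)
    counts[0] += n_total - counts.sum()
    return tuple(int(c) for c in counts)


@dataclass
class SelectionResult:
    selected: np.ndarray
    modal_k: int


def selection_experiment(n_datasets: int = 20, n_total: int = 500,
                         max_classes: int = 4, n_restarts: int = 20,
                         seed: int = 1,
                         config_factory=study_config) -> SelectionResult:
    """Fit K = 1..max_classes to each simulated dataset and record the
    lowest-BIC K (ties toward fewer classes); reports the modal choice."""
    selected = np.empty(n_datasets, dtype=int)
    for i in range(n_datasets):
        sim_seed = (seed * 10_000 + i) % (2**31 - 1)
        cfg = config_factory(seed=sim_seed,
                             n_per_group=_scaled_groups(n_total))
        data, _ = simulate_dataset(cfg)
        bics = []
        for k in range(1, max_classes + 1):
            fit = fit_em(data, ModelSpec(k), n_restarts=n_restarts,
                         seed=(sim_seed + 7 * k) % (2**31 - 1))
            bics.append(information_criteria(fit, data.n).bic)
        selected[i] = int(np.argmin(bics)) + 1
    values, counts = np.unique(selected, return_counts=True)
    return SelectionResult(selected=selected,
                           modal_k=int(values[np.argmax(counts)]))


@dataclass
class RecoveryResult:
    fitted_probs: np.ndarray  # (n_datasets, K, J), aligned to truth
    true_probs: np.ndarray
    mean_probs: np.ndarray = field(init=False)
    mean_abs_error: np.ndarray = field(init=False)

    def __post_init__(self):
        self.mean_probs = self.fitted_probs.mean(axis=0)
        self.mean_abs_error = np.abs(
            self.fitted_probs - self.true_probs).mean(axis=0)


def recovery_experiment(n_datasets: int = 50, n_total: int = 2000,
                        n_restarts: int = 20, seed: int = 1,
                        config_factory=study_config) -> RecoveryResult:
    """Fit the generating K to each simulated dataset, align fitted classes
    to the generating ones, and collect the fitted response probabilities."""
    cfg0 = config_factory(seed=0)
    true_probs = cfg0.response_probs
    K = cfg0.n_classes
    out = np.empty((n_datasets, K, cfg0.n_items))
    for i in range(n_datasets):
        sim_seed = (seed * 10_000 + i) % (2**31 - 1)
        cfg = config_factory(seed=sim_seed,
                             n_per_group=_scaled_groups(n_total))
        data, _ = simulate_dataset(cfg)
        fit = fit_em(data, ModelSpec(K), n_restarts=n_restarts,
                     seed=(sim_seed + 13) % (2**31 - 1))
        fitted = fit.params.response_probs()
        perm = align_classes(fitted, true_probs)
        out[i] = fitted[perm]
    return RecoveryResult(fitted_probs=out, true_probs=true_probs)
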