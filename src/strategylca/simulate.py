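"""Synthetic response-data generator.

Emulates the structure of a blicket-detector study with four age groups of
2- to 5-year-olds and four binary causal-inference test items.  The default
"study" preset reproduces the selected 3-class model: class proportions
51/90, 27/90, 12/90 and the class-by-item success probabilities

    class 1 (rational):              1    .67  .94  1
    class 2 (associative):           .48  .33  1    0
    class 3 (uncertainty avoidance): 0    0    1    1

Ages are drawn per group from a normal distribution truncated to the
group's 12-month band, so group labels stay consistent with ages.  True
class labels are returned in a sidecar, never inside the fitting data path.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.special import expit, logit, softmax
from scipy.stats import truncnorm

from .data import ResponseData

#: Per-group sample sizes for the study-sized default (total n = 90).
STUDY_N_PER_GROUP = (23, 23, 23, 21)
#: Per-group age means and SDs in months, youngest to oldest.
STUDY_AGE_MEANS = (30.04, 40.87, 54.39, 67.33)
STUDY_AGE_SDS = (3.16, 3.56, 2.98, 2.44)
#: 12-month age bands (months) for groups 2, 3, 4, 5 years.
AGE_BANDS = ((24.0, 36.0), (36.0, 48.0), (48.0, 60.0), (60.0, 72.0))
AGE_GROUP_LABELS = (2, 3, 4, 5)

#: Selected-model response probabilities (classes × items).
STUDY_RESPONSE_PROBS = np.array([
    [1.00, 0.67, 0.94, 1.00],
    [0.48, 0.33, 1.00, 0.00],
    [0.00, 0.00, 1.00, 1.00],
])
#: Class proportions 51/90, 27/90, 12/90.
STUDY_CLASS_PROBS = np.array([51, 27, 12]) / 90.0


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic-data generator.

    Class membership is governed either by fixed proportions
    (``class_probs``) or by an age logit (``membership_intercepts`` +
    ``membership_slopes`` · age, softmax over all K classes).  Response
    probabilities may optionally grow with age through per class-item logit
    slopes (``response_slopes``), in which case ``response_probs`` is the
    success probability at age 0 on the logit scale.
    """

    response_probs: np.ndarray = field(
        default_factory=lambda: STUDY_RESPONSE_PROBS.copy())
    class_probs: np.ndarray | None = field(
        default_factory=lambda: STUDY_CLASS_PROBS.copy())
    membership_intercepts: np.ndarray | None = None
    membership_slopes: np.ndarray | None = None
    response_slopes: np.ndarray | None = None
    n_per_group: tuple = STUDY_N_PER_GROUP
    age_means: tuple = STUDY_AGE_MEANS
    age_sds: tuple = STUDY_AGE_SDS
    seed: int = 0

    def __post_init__(self):
        self.response_probs = np.atleast_2d(
            np.asarray(self.response_probs, dtype=float))
        if ((self.response_probs < 0) | (self.response_probs > 1)).any():
            raise ValueError("response_probs must lie in [0, 1]")
        if self.class_probs is not None:
            self.class_probs = np.asarray(self.class_probs, dtype=float)
            if abs(self.class_probs.sum() - 1.0) > 1e-12:
                raise ValueError("class_probs must sum to 1")
            if len(self.class_probs) != self.n_classes:
                raise ValueError("class_probs length must match response rows")
        elif self.membership_intercepts is None:
            raise ValueError(
                "need class_probs or membership logit coefficients")
        if self.membership_intercepts is not None:
            self.membership_intercepts = np.asarray(
                self.membership_intercepts, dtype=float)
            self.membership_slopes = np.asarray(
                self.membership_slopes if self.membership_slopes is not None
                else np.zeros(self.n_classes), dtype=float)
        if self.response_slopes is not None:
            self.response_slopes = np.asarray(self.response_slopes,
                                              dtype=float)
            boundary = (self.response_probs == 0) | (self.response_probs == 1)
            if (boundary & (self.response_slopes != 0)).any():
                raise ValueError("nonzero response slope on a boundary "
                                 "probability: logit undefined")
        if len(self.n_per_group) != 4 or min(self.n_per_group) < 0:
            raise ValueError("n_per_group must be 4 nonnegative integers")
        if sum(self.n_per_group) < 1:
            raise ValueError("total sample size must be >= 1")
        if any(sd < 0 for sd in self.age_sds):
            raise ValueError("age SDs must be nonnegative")

    @property
    def n_classes(self) -> int:
        return self.response_probs.shape[0]

    @property
    def n_items(self) -> int:
        return self.response_probs.shape[1]

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(
            {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in d.items()})


def sample_ages(config: GeneratorConfig, rng=None):
    """Draw ages (months) per group from band-truncated normals.

    Returns ``(age_months, age_group)``; a zero SD gives every child in the
    group exactly the group mean.  Reproducible given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    ages, groups = [], []
    for g, n_g in enumerate(config.n_per_group):
        if n_g == 0:
            continue
        mu, sd = config.age_means[g], config.age_sds[g]
        lo, hi = AGE_BANDS[g]
        if sd == 0:
            draw = np.full(n_g, mu)
        else:
            a, b = (lo - mu) / sd, (hi - mu) / sd
            draw = truncnorm.rvs(a, b, loc=mu, scale=sd, size=n_g,
                                 random_state=rng)
        ages.append(draw)
        groups.append(np.full(n_g, AGE_GROUP_LABELS[g]))
    return np.concatenate(ages), np.concatenate(groups)


def simulate_dataset(config: GeneratorConfig):
    """Simulate one dataset; returns ``(ResponseData, true_class_labels)``.

    True labels are 1-based and sidecar-only: nothing in the fitting code
    path sees them.
    """
    rng = np.random.default_rng(config.seed)
    age, group = sample_ages(config, rng)
    n = len(age)
    K, J = config.n_classes, config.n_items

    if config.class_probs is not None:
        pi = np.broadcast_to(config.class_probs, (n, K))
    else:
        logits = (config.membership_intercepts[None, :]
                  + np.outer(age, config.membership_slopes))
        pi = softmax(logits, axis=1)
    z = (rng.random(n)[:, None] < np.cumsum(pi, axis=1)).argmax(axis=1)

    if config.response_slopes is None:
        probs = config.response_probs[z]
    else:
        eta = (logit(config.response_probs)[None, :, :]
               + age[:, None, None] * config.response_slopes[None, :, :])
        probs = expit(eta)[np.arange(n), z]
    Y = (rng.random((n, J)) < probs).astype(np.int8)

    data = ResponseData(
        subject_id=np.array([f"sim{i + 1:04d}" for i in range(n)]),
        responses=Y, age_months=age, age_group=group)
    return data, z + 1


# ---------------------------------------------------------------------------
# Presets


def study_config(seed: int = 0, n_per_group=STUDY_N_PER_GROUP
                 ) -> GeneratorConfig:
    """3-class study preset: fixed proportions 51/90, 27/90, 12/90 and the
    selected-model response probabilities."""
    return GeneratorConfig(seed=seed, n_per_group=tuple(n_per_group))


def age_logit_config(seed: int = 0, n_per_group=STUDY_N_PER_GROUP
                     ) -> GeneratorConfig:
    """Age-dependent membership preset.

    Calibrated so the class-1 ("rational") share rises and the class-2
    ("associative") share falls with age: the modal class is 2 in the
    youngest group and 1 from age 3 up, with a small class-3 share
    throughout.  A calibration device for qualitative structure, not a
    reconstruction of any fitted coefficients.
    """
    return GeneratorConfig(
        seed=seed, n_per_group=tuple(n_per_group),
        class_probs=None,
        # logits vs class 3, crossing class 1 over class 2 near 36 months
        membership_intercepts=np.array([1.7 - 0.10 * 48,
                                        -0.1 + 0.05 * 48, 0.0]),
        membership_slopes=np.array([0.10, -0.05, 0.0]))


def accuracy_growth_config(seed: int = 0, n_per_group=STUDY_N_PER_GROUP
                           ) -> GeneratorConfig:
    """Single-class preset whose accuracy grows with age: one strategy,
    executed better by older children (logit slope 0.06 per month, success
    ~0.34 at 30 months rising to ~0.82 at 67 months)."""
    return GeneratorConfig(
        seed=seed, n_per_group=tuple(n_per_group),
        response_probs=np.full((1, 4), expit(logit(0.6) - 0.06 * 48)),
        class_probs=np.ones(1),
        response_slopes=np.full((1, 4), 0.06))


def one_class_config(seed: int = 0, n_per_group=STUDY_N_PER_GROUP
                     ) -> GeneratorConfig:
    """Single-class, age-free null preset (moderate success rates)."""
    return GeneratorConfig(
        seed=seed, n_per_group=tuple(n_per_group),
        response_probs=np.array([[0.7, 0.5, 0.9, 0.6]]),
        class_probs=np.ones(1))


PRESETS = {
    "study": study_config,
    "age-logit": age_logit_config,
    "accuracy-growth": accuracy_growth_config,
    "one-class": one_class_config,
}


def write_dataset(data: ResponseData, true_labels, config: GeneratorConfig,
                  path) -> None:
    """Write the standard CSV plus a ``<name>.truth.csv`` sidecar carrying
    the true class labels and the generating config as JSON."""
    import pandas as pd

    path = str(path)
    data.to_csv(path)
    base = path[:-4] if path.endswith(".csv") else path
    truth = pd.DataFrame({"subject_id": data.subject_id,
                          "true_class": true_labels})
    truth["config_json"] = ""
    truth.loc[0, "config_json"] = config.to_json()
    truth.to_csv(base + ".truth.csv", index=False)
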