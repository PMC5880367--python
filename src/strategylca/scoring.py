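"""Scoring raw trial responses into binary successes, and screening items
for lack of variability.

Each test trial defines one intended causal inference, and a response is
scored 1 exactly when it is consistent with that inference:

* ``screening_off`` — place the causally efficacious object X alone;
* ``indirect_screening_off_a`` — place object Z alone;
* ``indirect_screening_off_b`` — label object Y a blicket;
* ``backwards_blocking`` — do *not* label object Y a blicket;
* ``non_causal_association`` — use a finger press.

Every other scorable response is 0; unscorable responses mark the subject
for listwise exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml

from .data import ResponseData

SUCCESS, FAILURE, UNSCORABLE = "success", "failure", "unscorable"
OUTCOMES = (SUCCESS, FAILURE, UNSCORABLE)

TRIAL_NAMES = (
    "screening_off",
    "indirect_screening_off_a",
    "indirect_screening_off_b",
    "backwards_blocking",
    "non_causal_association",
)

#: Default raw-code inventory.  ``strict_backwards_label`` (off by default):
#: the indirect-screening-off-B trial is scored on object Y's label only;
#: a strict variant additionally requiring X to be labeled a non-blicket
#: can be built by remapping ``Y_blicket_X_blicket`` to failure.
DEFAULT_CODES = {
    "screening_off": {
        "X_alone": SUCCESS, "Y_alone": FAILURE, "both_objects": FAILURE,
        "other": FAILURE, "no_response": UNSCORABLE,
    },
    "indirect_screening_off_a": {
        "Z_alone": SUCCESS, "X_alone": FAILURE, "Y_alone": FAILURE,
        "multiple_objects": FAILURE, "other": FAILURE,
        "no_response": UNSCORABLE,
    },
    "indirect_screening_off_b": {
        "Y_blicket": SUCCESS, "Y_blicket_X_blicket": SUCCESS,
        "Y_not_blicket": FAILURE, "other": FAILURE,
        "no_response": UNSCORABLE,
    },
    "backwards_blocking": {
        "Y_not_blicket": SUCCESS, "Y_blicket": FAILURE, "other": FAILURE,
        "no_response": UNSCORABLE,
    },
    "non_causal_association": {
        "finger_press": SUCCESS, "associated_objects": FAILURE,
        "non_associated_object": FAILURE, "other": FAILURE,
        "no_response": UNSCORABLE,
    },
}


@dataclass
class ScoringScheme:
    """Per-trial mapping from raw response codes to success indicators."""

    codes: dict = field(default_factory=lambda: {
        t: dict(m) for t, m in DEFAULT_CODES.items()})

    def __post_init__(self):
        for trial, mapping in self.codes.items():
            for code, outcome in mapping.items():
                if outcome not in OUTCOMES:
                    raise ValueError(
                        f"trial {trial!r}, code {code!r}: outcome must be "
                        f"one of {OUTCOMES}, got {outcome!r}")

    @property
    def trials(self) -> list[str]:
        return list(self.codes)

    @classmethod
    def from_yaml(cls, path) -> "ScoringScheme":
        with open(path) as fh:
            return cls(codes=yaml.safe_load(fh))

    def score_one(self, trial: str, code: str) -> str:
        if trial not in self.codes:
            raise KeyError(f"unknown trial {trial!r}")
        mapping = self.codes[trial]
        if code not in mapping:
            raise KeyError(f"unknown code {code!r} for trial {trial!r}")
        return mapping[code]


def score_responses(records: pd.DataFrame,
                    scheme: ScoringScheme | None = None) -> ResponseData:
    """Score a long-format raw-records table into a ``ResponseData``.

    ``records`` needs columns ``subject_id``, ``trial``, ``code`` and (once
    per subject) ``age_months`` and optionally ``age_group``.  Subjects
    with any unscorable response are excluded listwise; an unknown trial or
    code raises, naming the offending record.
    """
    scheme = scheme or ScoringScheme()
    records = records.copy()
    outcomes = []
    for _, row in records.iterrows():
        try:
            outcomes.append(scheme.score_one(row["trial"], row["code"]))
        except KeyError as err:
            raise ValueError(
                f"subject {row['subject_id']!r}: {err.args[0]}") from err
    records["outcome"] = outcomes

    flagged = set(records.loc[records["outcome"] == UNSCORABLE, "subject_id"])
    records = records[~records["subject_id"].isin(flagged)]
    if records.empty:
        raise ValueError("no scorable subjects remain")
    records["success"] = (records["outcome"] == SUCCESS).astype(int)

    trial_order = [t for t in scheme.trials
                   if t in set(records["trial"])]
    wide = records.pivot(index="subject_id", columns="trial",
                         values="success")[trial_order]
    if wide.isna().any().any():
        missing = wide.index[wide.isna().any(axis=1)][0]
        raise ValueError(f"subject {missing!r} is missing trial records")
    meta = records.drop_duplicates("subject_id").set_index("subject_id")
    meta = meta.loc[wide.index]
    return ResponseData(
        subject_id=wide.index.to_numpy(),
        responses=wide.to_numpy(),
        age_months=meta["age_months"].to_numpy(dtype=float),
        age_group=(meta["age_group"].to_numpy()
                   if "age_group" in meta.columns else None),
        item_names=trial_order)


def screen_item_variability(data: ResponseData,
                            min_success_prop: float = 0.05):
    """Drop items with too little success to carry information.

    One-sided screen: an item whose overall success proportion falls below
    ``min_success_prop`` is excluded (items with very *high* success are
    retained — near-ceiling performance is still an informative profile
    entry).  Returns ``(screened_data, report)`` where the report lists
    every item's success proportion and whether it was kept.
    """
    if not 0 <= min_success_prop < 0.5:
        raise ValueError("min_success_prop must be in [0, 0.5)")
    props = data.responses.mean(axis=0)
    keep = [j for j, p in enumerate(props) if p >= min_success_prop]
    if not keep:
        raise ValueError("variability screen would drop every item")
    report = pd.DataFrame({
        "item": data.item_names,
        "success_prop": props,
        "kept": [j in keep for j in range(data.n_items)],
    })
    return data.select_items(keep), report
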