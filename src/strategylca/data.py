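"""Container for binary response data with a per-subject age covariate.

The analyses in this package all consume a subjects-by-items matrix of 0/1
success indicators (1 = the intended causal inference was made on that
trial), together with each subject's age in months and, optionally, a
whole-year age-group label (2, 3, 4 or 5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Columns of the standard input CSV that are not response items.
ID_COLUMNS = ("subject_id", "age_months", "age_group")


@dataclass
class ResponseData:
    """Binary success matrix plus age covariate.

    Parameters
    ----------
    subject_id : array-like of shape (n,)
        Subject identifiers.
    responses : ndarray of shape (n, J)
        Binary success indicators; every entry must be exactly 0 or 1.
        Subjects with missing test-trial values are excluded *before*
        construction (listwise exclusion at load time).
    age_months : ndarray of shape (n,)
        Age in months, strictly positive.
    age_group : ndarray of shape (n,) or None
        Optional whole-year age group in {2, 3, 4, 5}.
    item_names : list of str or None
        Optional item labels; defaults to ``trial1..trialJ``.
    """

    subject_id: np.ndarray
    responses: np.ndarray
    age_months: np.ndarray
    age_group: np.ndarray | None = None
    item_names: list[str] | None = None

    def __init__(self, subject_id, responses, age_months, age_group=None,
                 item_names=None):
        self.subject_id = np.asarray(subject_id)
        self.responses = np.asarray(responses)
        self.age_months = np.asarray(age_months, dtype=float)
        self.age_group = None if age_group is None else np.asarray(age_group)
        if self.responses.ndim != 2:
            raise ValueError("responses must be a 2-d array")
        n, J = self.responses.shape
        if n < 1 or J < 1:
            raise ValueError("need at least one subject and one item")
        if not np.isin(self.responses, (0, 1)).all():
            raise ValueError("responses must contain only 0 and 1")
        self.responses = self.responses.astype(np.int8)
        if len(self.subject_id) != n or len(self.age_months) != n:
            raise ValueError("subject_id/age_months length mismatch")
        if not (self.age_months > 0).all():
            raise ValueError("age_months must be strictly positive")
        if self.age_group is not None and len(self.age_group) != n:
            raise ValueError("age_group length mismatch")
        if item_names is None:
            item_names = [f"trial{j + 1}" for j in range(J)]
        if len(item_names) != J:
            raise ValueError("item_names length mismatch")
        self.item_names = list(item_names)

    @property
    def n(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    def select_items(self, keep: list[int]) -> "ResponseData":
        """Return a copy restricted to the item columns in ``keep``."""
        return ResponseData(
            self.subject_id,
            self.responses[:, keep],
            self.age_months,
            self.age_group,
            [self.item_names[j] for j in keep],
        )

    # -- CSV round trip ----------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ResponseData":
        item_cols = [c for c in df.columns if c not in ID_COLUMNS]
        if not item_cols:
            raise ValueError("no response columns found")
        complete = df[item_cols].notna().all(axis=1)
        n_dropped = int((~complete).sum())
        if n_dropped:
            logger.info("excluding %d subject(s) with missing trial values",
                        n_dropped)
        df = df.loc[complete]
        return cls(
            subject_id=df["subject_id"].to_numpy(),
            responses=df[item_cols].to_numpy(dtype=float),
            age_months=df["age_months"].to_numpy(dtype=float),
            age_group=(df["age_group"].to_numpy()
                       if "age_group" in df.columns else None),
            item_names=item_cols,
        )

    @classmethod
    def from_csv(cls, path) -> "ResponseData":
        """Load the standard input CSV
        (``subject_id,age_months,age_group,trial1,...``)."""
        return cls.from_dataframe(pd.read_csv(path))

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"subject_id": self.subject_id,
                "age_months": self.age_months}
        if self.age_group is not None:
            cols["age_group"] = self.age_group
        for j, name in enumerate(self.item_names):
            cols[name] = self.responses[:, j]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)
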