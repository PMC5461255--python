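"""The battery dataset: subjects x (13 named predictors, response, age group).

The 13 canonical predictor names cover eight cognitive tests: Text Reception
Threshold (TRT), vocabulary (WST), Operation Span working memory, four
scores from the Verbal Learning and Retention Test pipeline, two lexical
decision reaction-time differences, four trail-making switching costs, and
the Stroop distraction-sensitivity difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CANONICAL_PREDICTORS: tuple[str, ...] = (
    "TRT",
    "WST",
    "OperationSpan",
    "Verbal_learning",
    "Recall",
    "Recognition",
    "RT_word",
    "RT_freq",
    "CTMT_1_2",
    "CTMT_1_3",
    "CTMT_1_4",
    "CTMT_1_5",
    "Distraction_sensitivity",
)

RESPONSE_COLUMN = "y_median"
GROUPS = ("young", "old")

CSV_COLUMNS = ("subject_id", "age_group") + CANONICAL_PREDICTORS + (RESPONSE_COLUMN,)


@dataclass
class BatteryDataset:
    """Thin wrapper around the canonical battery table.

    ``frame`` carries every subject, including those with missing
    predictors; :meth:`analysis_view` returns the complete-case table used
    for modelling (mirroring the exclusion of subjects who aborted the
    Operation Span task).
    """

    frame: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in CSV_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"battery table missing columns: {missing}")
        bad = set(self.frame["age_group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown age_group values: {sorted(bad)}")

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    def excluded_subjects(self) -> list:
        """Subject ids dropped from the analysis view (missing predictors)."""
        mask = self.frame[list(CANONICAL_PREDICTORS)].isna().any(axis=1)
        return self.frame.loc[mask, "subject_id"].tolist()

    def analysis_view(self) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
        """Complete-case (X, y, age_group) for the PLS analysis."""
        ok = ~self.frame[list(CANONICAL_PREDICTORS)].isna().any(axis=1)
        ok &= self.frame[RESPONSE_COLUMN].notna()
        sub = self.frame.loc[ok]
        X = sub[list(CANONICAL_PREDICTORS)].astype(float)
        return X, sub[RESPONSE_COLUMN].to_numpy(float), sub["age_group"].to_numpy()

    def to_csv(self, path) -> None:
        self.frame.loc[:, list(CSV_COLUMNS)].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BatteryDataset":
        frame = pd.read_csv(path)
        unknown = [c for c in frame.columns if c not in CSV_COLUMNS]
        if unknown:
            raise ValueError(f"unknown column(s) in battery CSV: {unknown}")
        return cls(frame=frame)
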