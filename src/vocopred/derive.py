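"""Derivation of the 13 canonical predictors from raw cognitive-test records.

Raw material per subject: eight verbal-learning trial counts (trials 1-5
list learning, 6 interference, 7 delayed recall, 8 recognition), the
Operation Span letter count, the Text Reception Threshold word count, the
vocabulary-test (WST) correct count, four lexical-decision mean reaction
times (word / nonword / low-frequency / high-frequency, ms), three Stroop
median reaction times (reading / bar naming / interference, s), and five
trail-making subtest times (s).

The derivation is a pure function; missing raw fields propagate to a
flagged missing predictor (NaN), never to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .battery import CANONICAL_PREDICTORS

__all__ = ["RawTestRecords", "derive_predictors", "derive_predictors_frame"]

RAW_COLUMNS = (
    "vlrt_t1", "vlrt_t2", "vlrt_t3", "vlrt_t4", "vlrt_t5",
    "vlrt_t6", "vlrt_t7", "vlrt_t8",
    "ospan_letters", "trt_words", "wst_correct",
    "ldt_rt_word", "ldt_rt_nonword", "ldt_rt_low_freq", "ldt_rt_high_freq",
    "stroop_reading", "stroop_bar_naming", "stroop_interference",
    "ctmt_1", "ctmt_2", "ctmt_3", "ctmt_4", "ctmt_5",
)


@dataclass
class RawTestRecords:
    """One subject's raw test results.

    ``vlrt_trials`` holds trials 1..8 of the verbal learning test (each a
    count of 0..15 recalled words; trial 8 counts recognized targets).
    Reaction times: lexical decision in ms (means over correct responses
    per condition), Stroop in s (per-task medians), trail-making subtests
    in s.
    """

    vlrt_trials: Sequence[float]
    ospan_letters: float
    trt_words: float
    wst_correct: float
    ldt_rt_word: float
    ldt_rt_nonword: float
    ldt_rt_low_freq: float
    ldt_rt_high_freq: float
    stroop_reading: float
    stroop_bar_naming: float
    stroop_interference: float
    ctmt_rts: Sequence[float]

    def validate(self) -> None:
        if len(self.vlrt_trials) != 8:
            raise ValueError("vlrt_trials must hold trials 1..8")
        for i, v in enumerate(self.vlrt_trials, start=1):
            if _present(v) and not 0 <= v <= 15:
                raise ValueError(f"vlrt trial {i} out of range [0, 15]: {v}")
        for name in ("ospan_letters", "trt_words", "wst_correct"):
            v = getattr(self, name)
            if _present(v) and v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")
        if _present(self.wst_correct) and self.wst_correct > 42:
            raise ValueError(f"wst_correct exceeds the 42 test rows: {self.wst_correct}")
        if len(self.ctmt_rts) != 5:
            raise ValueError("ctmt_rts must hold subtests 1..5")
        for i, v in enumerate(self.ctmt_rts, start=1):
            if _present(v) and v <= 0:
                raise ValueError(f"ctmt subtest {i} time must be > 0: {v}")
        for name in ("stroop_reading", "stroop_bar_naming", "stroop_interference"):
            v = getattr(self, name)
            if _present(v) and v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")


def _present(v) -> bool:
    return v is not None and not (isinstance(v, float) and math.isnan(v))


def _diff(a, b):
    if _present(a) and _present(b):
        return float(a) - float(b)
    return float("nan")


def derive_predictors(raw: RawTestRecords, *,
                      recall_sign: str = "t7_minus_t5") -> dict[str, float]:
    """Map raw records to the 13 canonical predictors.

    * TRT, WST, OperationSpan: the raw correct counts.
    * Verbal_learning: sum of list-learning trials 1-5.
    * Recall: trial 7 minus trial 5 by default (consolidation after delay);
      ``recall_sign='t5_minus_t7'`` flips the convention.
    * Recognition: trial 8.
    * RT_word: nonword minus word reaction time; RT_freq: low- minus
      high-frequency words.
    * CTMT_1_k: subtest k minus subtest 1 (switching cost), k = 2..5.
    * Distraction_sensitivity: Stroop interference minus bar naming.
    """
    if recall_sign not in ("t7_minus_t5", "t5_minus_t7"):
        raise ValueError(f"unknown recall_sign: {recall_sign!r}")
    raw.validate()
    t = list(raw.vlrt_trials)
    first_five = t[:5]
    verbal_learning = (
        float(sum(first_five)) if all(_present(v) for v in first_five) else float("nan")
    )
    recall = _diff(t[6], t[4]) if recall_sign == "t7_minus_t5" else _diff(t[4], t[6])
    out = {
        "TRT": float(raw.trt_words) if _present(raw.trt_words) else float("nan"),
        "WST": float(raw.wst_correct) if _present(raw.wst_correct) else float("nan"),
        "OperationSpan": (
            float(raw.ospan_letters) if _present(raw.ospan_letters) else float("nan")
        ),
        "Verbal_learning": verbal_learning,
        "Recall": recall,
        "Recognition": float(t[7]) if _present(t[7]) else float("nan"),
        "RT_word": _diff(raw.ldt_rt_nonword, raw.ldt_rt_word),
        "RT_freq": _diff(raw.ldt_rt_low_freq, raw.ldt_rt_high_freq),
        "CTMT_1_2": _diff(raw.ctmt_rts[1], raw.ctmt_rts[0]),
        "CTMT_1_3": _diff(raw.ctmt_rts[2], raw.ctmt_rts[0]),
        "CTMT_1_4": _diff(raw.ctmt_rts[3], raw.ctmt_rts[0]),
        "CTMT_1_5": _diff(raw.ctmt_rts[4], raw.ctmt_rts[0]),
        "Distraction_sensitivity": _diff(
            raw.stroop_interference, raw.stroop_bar_naming
        ),
    }
    assert tuple(out) == CANONICAL_PREDICTORS
    return out


def _row_to_records(row: pd.Series) -> RawTestRecords:
    return RawTestRecords(
        vlrt_trials=[row.get(f"vlrt_t{i}", np.nan) for i in range(1, 9)],
        ospan_letters=row.get("ospan_letters", np.nan),
        trt_words=row.get("trt_words", np.nan),
        wst_correct=row.get("wst_correct", np.nan),
        ldt_rt_word=row.get("ldt_rt_word", np.nan),
        ldt_rt_nonword=row.get("ldt_rt_nonword", np.nan),
        ldt_rt_low_freq=row.get("ldt_rt_low_freq", np.nan),
        ldt_rt_high_freq=row.get("ldt_rt_high_freq", np.nan),
        stroop_reading=row.get("stroop_reading", np.nan),
        stroop_bar_naming=row.get("stroop_bar_naming", np.nan),
        stroop_interference=row.get("stroop_interference", np.nan),
        ctmt_rts=[row.get(f"ctmt_{i}", np.nan) for i in range(1, 6)],
    )


def derive_predictors_frame(raw_frame: pd.DataFrame, *,
                            recall_sign: str = "t7_minus_t5") -> pd.DataFrame:
    """Vectorized derivation over a one-row-per-subject raw records table.

    Returns a table with subject_id (and age_group if present) plus the 13
    canonical predictor columns; missing raw fields yield NaN predictors.
    """
    rows = []
    for _, row in raw_frame.iterrows():
        derived = derive_predictors(_row_to_records(row), recall_sign=recall_sign)
        rec = {"subject_id": row.get("subject_id")}
        if "age_group" in raw_frame.columns:
            rec["age_group"] = row["age_group"]
        rec.update(derived)
        rows.append(rec)
    return pd.DataFrame(rows)
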