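"""Open-set sentence scoring and the subject-level response variable.

Each test sentence has seven target words; the score is the number of
accurately reported words (case-insensitive exact token match after
punctuation stripping, order-free, each target creditable once).  The
subject-level response entering the regression is the median score over the
60 test trials; learning curves summarize blocks of ten sentences.
"""

from __future__ import annotations

import re
from collections import Counter

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "normalize_token",
    "score_sentence",
    "median_performance",
    "learning_curve",
    "group_summary",
    "score_trials_frame",
]

WORDS_PER_SENTENCE = 7
_PUNCT = re.compile(r"[^\w]+", flags=re.UNICODE)


def normalize_token(token: str) -> str:
    """Lowercase and strip punctuation; umlauts and other letters are kept."""
    return _PUNCT.sub("", token.lower())


def score_sentence(target_words, reported_words) -> int:
    """Count of target words present in the report.

    Matching is order-free and each target can be credited at most once
    (a target word repeated in the report earns a single credit unless the
    target itself repeats).  No lemmatization or partial-word credit.
    """
    targets = [normalize_token(w) for w in target_words]
    if len(targets) != WORDS_PER_SENTENCE:
        raise ValueError(
            f"a sentence has exactly {WORDS_PER_SENTENCE} target words, "
            f"got {len(targets)}"
        )
    reported = Counter(normalize_token(w) for w in reported_words)
    reported.pop("", None)
    credit = Counter(targets) & reported
    return int(sum(credit.values()))


def median_performance(scores) -> float:
    """Median words-correct over a subject's test trials (practice trials
    are excluded upstream).  Lies on the integer/half-integer lattice for
    integer scores."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) == 0:
        raise ValueError("no trials to summarize")
    if (scores < 0).any() or (scores > WORDS_PER_SENTENCE).any():
        raise ValueError(f"scores must lie in [0, {WORDS_PER_SENTENCE}]")
    return float(np.median(scores))


def learning_curve(trials: pd.DataFrame, block_size: int = 10) -> pd.DataFrame:
    """Group learning curves: median across subjects of per-subject block
    medians.

    ``trials`` needs columns subject_id, trial_index, n_correct and
    optionally age_group.  Blocks partition the trials in presentation
    order (block b covers trial indices (b-1)*block_size+1 .. b*block_size).
    """
    t = trials.copy()
    t["block"] = (t["trial_index"] - 1) // block_size + 1
    per_subject = (
        t.groupby(["subject_id", "block"])["n_correct"].median().rename("median")
    )
    if "age_group" in t.columns:
        key = t.drop_duplicates("subject_id").set_index("subject_id")["age_group"]
        df = per_subject.reset_index()
        df["age_group"] = df["subject_id"].map(key)
        return (
            df.groupby(["age_group", "block"])["median"].median().unstack(0)
        )
    return per_subject.reset_index().groupby("block")["median"].median().to_frame()


def group_summary(responses, groups) -> dict:
    """Per-group mean/SD of the subject medians and the two-sample t test
    between the groups (both pooled-variance and Welch flavors)."""
    responses = np.asarray(responses, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {list(labels)}")
    a = responses[groups == labels[0]]
    b = responses[groups == labels[1]]
    pooled = stats.ttest_ind(a, b, equal_var=True)
    welch = stats.ttest_ind(a, b, equal_var=False)
    return {
        "groups": {
            str(lab): {
                "n": int((groups == lab).sum()),
                "mean": float(responses[groups == lab].mean()),
                "sd": float(responses[groups == lab].std(ddof=1)),
            }
            for lab in labels
        },
        "t_pooled": float(pooled.statistic),
        "p_pooled": float(pooled.pvalue),
        "df_pooled": int(len(a) + len(b) - 2),
        "t_welch": float(welch.statistic),
        "p_welch": float(welch.pvalue),
    }


def score_trials_frame(trials: pd.DataFrame) -> pd.DataFrame:
    """Fill in ``n_correct`` from target/report strings where absent and
    return per-subject medians.

    Trial CSV schema: subject_id, trial_index, target, report, n_correct
    (n_correct computed from the word columns when missing; words are
    whitespace-separated within the cell)."""
    t = trials.copy()
    if "n_correct" not in t.columns:
        t["n_correct"] = np.nan
    needs = t["n_correct"].isna()
    if needs.any():
        if not {"target", "report"} <= set(t.columns):
            raise ValueError("need target/report columns to score trials")
        t.loc[needs, "n_correct"] = [
            score_sentence(str(row.target).split(), str(row.report).split())
            for row in t.loc[needs].itertuples()
        ]
    t["n_correct"] = t["n_correct"].astype(int)
    medians = t.groupby("subject_id")["n_correct"].median().rename("y_median")
    return medians.reset_index()
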