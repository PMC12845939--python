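"""Stimulus-corpus labelling, inter-rater reliability, and session selection.

News items rated by independent evaluators on 9-point valence and arousal
scales are labelled negative (valence mean <= 3.5) or positive (>= 6.5);
items with extreme arousal (mean <= 2 or >= 8) or rater disagreement (range
exceeding two scale points on either scale) are excluded, as are items
neutral on valence.  Reliability is summarised by the two-way random-effects,
absolute-agreement, single-measure intraclass correlation, ICC(2,1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simgen import RatingMatrix

__all__ = [
    "CorpusConfig",
    "ItemLabel",
    "label_item",
    "label_corpus",
    "icc",
    "select_session",
]


@dataclass
class CorpusConfig:
    neg_valence_max: float = 3.5
    pos_valence_min: float = 6.5
    arousal_low_max: float = 2.0
    arousal_high_min: float = 8.0
    max_rater_range: int = 2
    session_pos: int = 3
    session_neg: int = 3

    def __post_init__(self) -> None:
        if self.neg_valence_max >= self.pos_valence_min:
            raise ValueError("neg_valence_max must be below pos_valence_min")


@dataclass
class ItemLabel:
    label: str  # 'negative' | 'positive' | 'excluded'
    reason: str | None = None  # 'disagreement' | 'arousal' | 'neutral'


def label_item(valence_ratings, arousal_ratings,
               cfg: CorpusConfig | None = None) -> ItemLabel:
    """Label one item from its complete rater vectors.

    Exclusion checks run first: rater disagreement (max-min range strictly
    greater than ``max_rater_range`` on either scale), then extreme arousal
    (inclusive bounds); surviving items are labelled by the valence mean, with
    the open interval between the thresholds excluded as neutral.
    """
    cfg = cfg or CorpusConfig()
    v = np.asarray(valence_ratings, dtype=float)
    a = np.asarray(arousal_ratings, dtype=float)
    if v.size == 0 or a.size == 0 or not (np.isfinite(v).all() and np.isfinite(a).all()):
        raise ValueError("complete valence and arousal ratings are required")
    if (v.max() - v.min()) > cfg.max_rater_range or \
            (a.max() - a.min()) > cfg.max_rater_range:
        return ItemLabel("excluded", "disagreement")
    if a.mean() <= cfg.arousal_low_max or a.mean() >= cfg.arousal_high_min:
        return ItemLabel("excluded", "arousal")
    if v.mean() <= cfg.neg_valence_max:
        return ItemLabel("negative")
    if v.mean() >= cfg.pos_valence_min:
        return ItemLabel("positive")
    return ItemLabel("excluded", "neutral")


def label_corpus(matrix: RatingMatrix,
                 cfg: CorpusConfig | None = None) -> pd.DataFrame:
    rows = []
    for i, item in enumerate(matrix.item_ids):
        lab = label_item(matrix.valence[i], matrix.arousal[i], cfg)
        rows.append({"item_id": item, "label": lab.label,
                     "reason": lab.reason or ""})
    return pd.DataFrame(rows)


def icc(matrix: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n) from the
    two-way ANOVA mean squares (rows = items/targets, columns = raters).
    Undefined (NaN) when the matrix has no variance at all.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 items and 2 raters")
    if not np.isfinite(x).all():
        raise ValueError("missing cells are not supported")
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        return float("nan")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    return float((msr - mse) / denom)


def select_session(labels: pd.DataFrame, history: set[str] | None = None,
                   seed: int = 0, cfg: CorpusConfig | None = None) -> list[str]:
    """Uniform draw without replacement of 3 positive + 3 negative unseen
    items.  Deterministic under the seed; raises naming the class that lacks
    unseen items."""
    cfg = cfg or CorpusConfig()
    history = history or set()
    rng = np.random.default_rng(int(seed) % (2 ** 31))
    chosen: list[str] = []
    for label, count in (("positive", cfg.session_pos), ("negative", cfg.session_neg)):
        pool = sorted(labels.loc[labels["label"] == label, "item_id"]
                      .pipe(lambda s: s[~s.isin(history)]))
        if len(pool) < count:
            raise ValueError(
                f"insufficient unseen {label} items: need {count}, "
                f"have {len(pool)}")
        chosen.extend(rng.choice(pool, size=count, replace=False).tolist())
    return chosen
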