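"""Word-level scores on trained semantic scales (word-cloud data).

Each distinct word occurring in the study responses is scored by applying
a trained scale to the word's own (single-word) embedding; scores are then
standardized to z-values over the distinct scored words. Together with the
word's corpus frequency these (word, z, frequency) triples are exactly the
data a word-cloud renderer needs — rendering itself is out of scope.

Three scales are of interest: the severity scale (trained elsewhere), a
logistic condition scale (physical = 1, psychological = 0) and a linear
calibration-bias scale (per-response P2 rating minus the event's P1
rating).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from semscale.scale import (
    RatedRecord,
    SemanticScaleModel,
    predict_scale,
    select_dimensions,
    train_scale,
)
from semscale.space import SemanticSpace

__all__ = ["WordScore", "train_condition_scale", "train_bias_scale", "score_words", "write_word_scores"]


@dataclass(frozen=True)
class WordScore:
    word: str
    z: float
    frequency: int
    scale_name: str

    def __post_init__(self) -> None:
        if self.frequency < 1:
            raise ValueError("word frequency must be >= 1")
        if not np.isfinite(self.z):
            raise ValueError("z must be finite")


def _fit_full_data_scale(
    records: Sequence[RatedRecord],
    family: str,
    grid: Sequence[int] | None,
    selection: str,
    seed: int,
) -> SemanticScaleModel:
    k = select_dimensions(records, grid=grid, family=family, selection=selection, seed=seed)
    return train_scale(records, k, family=family)


def train_condition_scale(
    records: Sequence[RatedRecord],
    grid: Sequence[int] | None = None,
    selection: str = "inner-cv",
    seed: int = 0,
) -> SemanticScaleModel:
    """Logistic scale separating physical (outcome 1) from psychological (0).

    ``records`` carry binary outcomes; both classes must be present.
    """
    outcomes = {r.outcome for r in records}
    if not outcomes <= {0.0, 1.0}:
        raise ValueError("condition scale outcomes must be coded 0/1")
    if len(outcomes) != 2:
        raise ValueError("both conditions must be present to train a condition scale")
    return _fit_full_data_scale(records, "logistic", grid, selection, seed)


def train_bias_scale(
    records: Sequence[RatedRecord],
    grid: Sequence[int] | None = None,
    selection: str = "inner-cv",
    seed: int = 0,
) -> SemanticScaleModel:
    """Linear scale predicting per-response calibration bias (P2 - P1).

    A dataset with zero bias variance yields a flat scale (zero slope,
    intercept at the constant bias) with a logged warning, since a fit
    quality r is undefined there.
    """
    outcomes = np.array([r.outcome for r in records], dtype=float)
    if outcomes.std() == 0:
        logging.getLogger(__name__).warning(
            "bias outcomes are constant (%.3f); returning a flat scale, fit r undefined",
            outcomes[0] if len(outcomes) else float("nan"),
        )
        k = 1
        return SemanticScaleModel(
            family="linear",
            coefficients=np.zeros(k),
            intercept=float(outcomes[0]),
            k_dims=k,
            training_meta={"n_train": len(records), "constant_outcome": True},
        )
    return _fit_full_data_scale(records, "linear", grid, selection, seed)


def make_bias_records(
    p2_records: Sequence[RatedRecord], p1_severity_by_event: Mapping
) -> list[RatedRecord]:
    """Replace each P2 record's outcome with its bias (P2 rating - P1 rating)."""
    out = []
    for rec in p2_records:
        if rec.group not in p1_severity_by_event:
            raise KeyError(f"no P1 rating for event {rec.group!r}")
        out.append(
            RatedRecord(
                record_id=rec.record_id,
                group=rec.group,
                embedding=rec.embedding,
                outcome=rec.outcome - float(p1_severity_by_event[rec.group]),
            )
        )
    return out


def score_words(
    model: SemanticScaleModel,
    space: SemanticSpace,
    corpus_words: Mapping[str, int] | Sequence[str],
    scale_name: str = "scale",
) -> list[WordScore]:
    """Score every distinct in-vocabulary word on a trained scale.

    Each word is scored by applying the model to the word's unit embedding;
    z standardizes the raw scores over the distinct scored words (mean 0,
    SD 1). Out-of-vocabulary words are dropped. Output is sorted by |z|
    descending, ties broken alphabetically for determinism.
    """
    freq = Counter(corpus_words) if not isinstance(corpus_words, Mapping) else dict(corpus_words)
    words = sorted(w for w in freq if w in space and freq[w] >= 1)
    if len(words) < 2:
        raise ValueError("need at least 2 distinct in-vocabulary words to standardize")
    raw = np.array([predict_scale(model, space.vector(w)) for w in words])
    sd = raw.std(ddof=0)
    if sd == 0:
        zs = np.zeros_like(raw)
    else:
        zs = (raw - raw.mean()) / sd
    scores = [
        WordScore(word=w, z=float(z), frequency=int(freq[w]), scale_name=scale_name)
        for w, z in zip(words, zs)
    ]
    scores.sort(key=lambda s: (-abs(s.z), s.word))
    return scores


def write_word_scores(scores: Sequence[WordScore], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {"word": s.word, "scale": s.scale_name, "z": s.z, "frequency": s.frequency}
            for s in scores
        ]
    ).to_csv(path, sep="\t", index=False)
    return path
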