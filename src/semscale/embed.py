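"""Keyword responses to unit-norm text embeddings.

A response (typically the five keywords a participant used to describe an
event) is mapped to one embedding by adding the embedding of each
in-vocabulary word and normalizing the sum to unit length. Out-of-vocabulary
words are skipped with a logged warning; a response whose words are all
out-of-vocabulary is an error, never a silent zero vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from semscale.space import SemanticSpace

__all__ = [
    "KeywordResponse",
    "TextEmbedding",
    "AllOovError",
    "DegenerateEmbeddingError",
    "embed_keywords",
    "embed_dataset",
]

log = logging.getLogger(__name__)


class AllOovError(ValueError):
    """Every word of a response is outside the semantic space vocabulary."""


class DegenerateEmbeddingError(ValueError):
    """The summed word vectors cancel to (numerically) zero length."""


@dataclass(frozen=True)
class KeywordResponse:
    """An ordered word list tied to a study record."""

    words: tuple[str, ...]
    source_phase: str = "P1"  # "P1" | "P2"
    owner_id: str = ""
    event_id: str = ""

    def __post_init__(self) -> None:
        if len(self.words) == 0:
            raise ValueError("KeywordResponse requires at least one word")


@dataclass(frozen=True)
class TextEmbedding:
    vector: np.ndarray
    n_known_words: int


def embed_keywords(
    response: KeywordResponse, space: SemanticSpace, lowercase: bool = True
) -> TextEmbedding:
    """Sum the embeddings of the in-vocabulary words and normalize to 1.

    Duplicated words contribute multiply to the sum (the scaling is removed
    again by the final normalization only when all words are identical).
    """
    words = [w.lower() for w in response.words] if lowercase else list(response.words)
    known = [w for w in words if w in space]
    oov = [w for w in words if w not in space]
    if oov:
        log.warning(
            "response %s/%s: skipping %d out-of-vocabulary word(s): %s",
            response.owner_id,
            response.event_id,
            len(oov),
            ", ".join(sorted(set(oov))),
        )
    if not known:
        raise AllOovError(
            f"all {len(words)} words of response "
            f"{response.owner_id or '?'}/{response.event_id or '?'} are out of vocabulary"
        )
    total = np.zeros(space.d)
    for w in known:
        total += space.vector(w)
    norm = float(np.linalg.norm(total))
    if norm < 1e-12:
        raise DegenerateEmbeddingError(
            "word vectors cancel exactly; response has no usable direction"
        )
    return TextEmbedding(vector=total / norm, n_known_words=len(known))


def embed_dataset(
    responses: Sequence[KeywordResponse],
    space: SemanticSpace,
    lowercase: bool = True,
    skip_all_oov: bool = False,
) -> tuple[list[TextEmbedding | None], dict]:
    """Embed a list of responses, order-preserving.

    Returns the embeddings and a summary dict with out-of-vocabulary
    statistics. With ``skip_all_oov`` an all-OOV response yields ``None``
    in its slot (a flagged skip) instead of raising.
    """
    if len(responses) == 0:
        raise ValueError("embed_dataset requires at least one response")
    embeddings: list[TextEmbedding | None] = []
    n_skipped = 0
    n_oov_words = 0
    for resp in responses:
        words = [w.lower() for w in resp.words] if lowercase else list(resp.words)
        n_oov_words += sum(1 for w in words if w not in space)
        try:
            embeddings.append(embed_keywords(resp, space, lowercase=lowercase))
        except AllOovError:
            if not skip_all_oov:
                raise
            n_skipped += 1
            embeddings.append(None)
    stats = {
        "n_responses": len(responses),
        "n_skipped_all_oov": n_skipped,
        "n_oov_words": n_oov_words,
    }
    if n_skipped:
        log.warning("embed_dataset: skipped %d all-OOV response(s)", n_skipped)
    return embeddings, stats
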