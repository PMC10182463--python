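"""LSA-style semantic spaces built from n-gram co-occurrence counts.

The space is constructed in three steps, each a separate operation so it
can be tested against independent oracles:

1. :func:`count_cooccurrences` — slide a symmetric window over each n-gram
   and count, for every ordered pair of distinct positions within the
   window, how often a row word and a column word co-occur (weighted by
   the n-gram's corpus count).
2. :func:`normalize_counts` — replace each cell with log(count + 1) to
   attenuate frequency artifacts.
3. :func:`build_space` — truncated SVD of the normalized matrix; word
   embeddings are the left singular vectors scaled by their singular
   values, then renormalized to unit Euclidean length.

Everything is dense and in-memory: the module targets desk-scale corpora
(vocabulary of a few thousand words), not the terabyte-scale corpora the
same construction is used on in production settings.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import scipy.linalg

__all__ = [
    "NGramRecord",
    "SpaceConfig",
    "CooccurrenceMatrix",
    "SemanticSpace",
    "NGramParseError",
    "read_ngram_counts",
    "write_ngram_counts",
    "count_cooccurrences",
    "normalize_counts",
    "build_space",
]


class NGramParseError(ValueError):
    """Raised when an n-gram count file line cannot be parsed."""


@dataclass(frozen=True)
class NGramRecord:
    """One n-gram and its corpus count."""

    tokens: tuple[str, ...]
    count: int

    def __post_init__(self) -> None:
        if len(self.tokens) == 0:
            raise ValueError("NGramRecord requires at least one token")
        if self.count < 0:
            raise ValueError(f"negative n-gram count: {self.count}")


@dataclass(frozen=True)
class SpaceConfig:
    """Configuration of the co-occurrence space.

    Parameters
    ----------
    n:
        n-gram order of the corpus (default 5).
    window:
        co-occurrence half-width; two positions i, j in an n-gram co-occur
        when ``0 < |i - j| <= window``. The default ±4 window spans a full
        5-gram.
    n_row_words, n_col_words:
        row/column vocabulary sizes, taken as the most frequent corpus
        words (defaults 120000 x 50000, truncated to the words actually
        present in small corpora).
    n_dims:
        number of singular dimensions retained (default 512).
    log_base:
        ``"natural"`` or ``"base10"`` for the log(count+1) normalization.
    lowercase:
        fold tokens to lower case while reading (default True).
    """

    n: int = 5
    window: int = 4
    n_row_words: int = 120_000
    n_col_words: int = 50_000
    n_dims: int = 512
    log_base: str = "natural"
    lowercase: bool = True

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n-gram order must be >= 2")
        if not 1 <= self.window <= self.n - 1:
            raise ValueError(f"window must lie in [1, {self.n - 1}], got {self.window}")
        if min(self.n_row_words, self.n_col_words, self.n_dims) < 1:
            raise ValueError("vocabulary sizes and n_dims must be positive")
        if self.n_dims > min(self.n_row_words, self.n_col_words):
            raise ValueError("n_dims cannot exceed the smaller vocabulary size")
        if self.log_base not in ("natural", "base10"):
            raise ValueError(f"unknown log_base: {self.log_base!r}")


@dataclass
class CooccurrenceMatrix:
    """Word-by-word co-occurrence matrix (raw counts or log-normalized)."""

    row_vocab: list[str]
    col_vocab: list[str]
    cells: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float)
        if self.cells.shape != (len(self.row_vocab), len(self.col_vocab)):
            raise ValueError(
                f"cells shape {self.cells.shape} does not match vocabularies "
                f"({len(self.row_vocab)} x {len(self.col_vocab)})"
            )
        if (self.cells < 0).any():
            raise ValueError("co-occurrence cells must be non-negative")

    def cell(self, row_word: str, col_word: str) -> float:
        return float(
            self.cells[self.row_vocab.index(row_word), self.col_vocab.index(col_word)]
        )


@dataclass
class SemanticSpace:
    """Vocabulary with unit-norm embeddings ordered by singular value."""

    vocab: list[str]
    embeddings: np.ndarray
    singular_values: np.ndarray

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings, dtype=float)
        self.singular_values = np.asarray(self.singular_values, dtype=float)
        if self.embeddings.shape[0] != len(self.vocab):
            raise ValueError("one embedding row per vocabulary word required")
        if self.embeddings.shape[1] != self.singular_values.shape[0]:
            raise ValueError("singular_values length must equal embedding width")
        if np.any(np.diff(self.singular_values) > 1e-9):
            raise ValueError("singular values must be non-increasing")
        self._index: dict[str, int] = {w: i for i, w in enumerate(self.vocab)}

    @property
    def d(self) -> int:
        return int(self.embeddings.shape[1])

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def __len__(self) -> int:
        return len(self.vocab)

    def vector(self, word: str) -> np.ndarray:
        try:
            return self.embeddings[self._index[word]]
        except KeyError:
            raise KeyError(f"word not in semantic space: {word!r}") from None

    # -- persistence ------------------------------------------------------
    # A space directory holds vocab.txt (one word per line), embeddings.tsv
    # and singular_values.txt at full float precision, plus meta.json with
    # the SpaceConfig used; the round-trip is exact.

    def save(self, directory: str | Path, config: SpaceConfig | None = None) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "vocab.txt").write_text(
            "\n".join(self.vocab) + "\n", encoding="utf-8"
        )
        np.savetxt(directory / "embeddings.tsv", self.embeddings, fmt="%.17e", delimiter="\t")
        np.savetxt(directory / "singular_values.txt", self.singular_values, fmt="%.17e")
        meta = {"d": self.d, "n_words": len(self.vocab)}
        if config is not None:
            meta["config"] = config.__dict__
        (directory / "meta.json").write_text(
            json.dumps(meta, indent=2) + "\n", encoding="utf-8"
        )
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "SemanticSpace":
        directory = Path(directory)
        vocab = (directory / "vocab.txt").read_text(encoding="utf-8").splitlines()
        embeddings = np.loadtxt(directory / "embeddings.tsv", delimiter="\t", ndmin=2)
        singular_values = np.loadtxt(directory / "singular_values.txt", ndmin=1)
        return cls(vocab=vocab, embeddings=embeddings, singular_values=singular_values)

    @staticmethod
    def load_config(directory: str | Path) -> SpaceConfig | None:
        meta = json.loads((Path(directory) / "meta.json").read_text(encoding="utf-8"))
        if "config" not in meta:
            return None
        return SpaceConfig(**meta["config"])


# ---------------------------------------------------------------------------
# n-gram count files


def read_ngram_counts(
    path: str | Path, n: int = 5, lowercase: bool = True
) -> Iterator[NGramRecord]:
    """Stream n-gram records from a count file.

    Each line is ``tok1 ... tokN<TAB>count``. Blank lines are skipped.
    Malformed lines raise :class:`NGramParseError` naming the line number.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if "\t" not in line:
                raise NGramParseError(f"{path}:{lineno}: missing tab separator")
            gram, _, count_str = line.rpartition("\t")
            tokens = gram.split()
            if len(tokens) != n:
                raise NGramParseError(
                    f"{path}:{lineno}: expected {n} tokens, found {len(tokens)}"
                )
            try:
                count = int(count_str)
            except ValueError:
                raise NGramParseError(
                    f"{path}:{lineno}: count is not an integer: {count_str!r}"
                ) from None
            if count < 0:
                raise NGramParseError(f"{path}:{lineno}: negative count {count}")
            if lowercase:
                tokens = [t.lower() for t in tokens]
            yield NGramRecord(tokens=tuple(tokens), count=count)


def write_ngram_counts(records: Iterable[NGramRecord], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for rec in records:
            handle.write(" ".join(rec.tokens) + f"\t{rec.count}\n")
    return path


# ---------------------------------------------------------------------------
# co-occurrence counting


def _rank_vocabulary(freq: Counter, limit: int) -> list[str]:
    # most frequent first; frequency ties broken lexicographically for
    # platform-independent determinism
    ranked = sorted(freq.items(), key=lambda item: (-item[1], item[0]))
    return [word for word, _ in ranked[:limit]]


def count_cooccurrences(
    ngrams: Iterable[NGramRecord], config: SpaceConfig | None = None
) -> CooccurrenceMatrix:
    """Count windowed word-pair co-occurrences over an n-gram corpus.

    ``cells[r, c]`` is the number of ordered position pairs (i, j) with
    ``0 < |i - j| <= window`` across all n-grams where position i holds row
    word r and position j holds column word c, each n-gram weighted by its
    corpus count. Counting is symmetric (both directions of every pair) and
    confined to single n-grams. Row/column vocabularies are the
    ``n_row_words`` / ``n_col_words`` most frequent words.
    """
    if config is None:
        config = SpaceConfig()
    records = list(ngrams)
    if not records:
        raise ValueError("empty n-gram corpus")

    freq: Counter = Counter()
    for rec in records:
        if len(rec.tokens) != config.n:
            raise ValueError(
                f"n-gram of length {len(rec.tokens)} in corpus configured for n={config.n}"
            )
        for tok in rec.tokens:
            freq[tok] += rec.count
    row_vocab = _rank_vocabulary(freq, config.n_row_words)
    col_vocab = _rank_vocabulary(freq, config.n_col_words)
    row_index = {w: i for i, w in enumerate(row_vocab)}
    col_index = {w: i for i, w in enumerate(col_vocab)}

    n = config.n
    token_ids_row = np.array(
        [[row_index.get(t, -1) for t in rec.tokens] for rec in records], dtype=np.int64
    )
    token_ids_col = np.array(
        [[col_index.get(t, -1) for t in rec.tokens] for rec in records], dtype=np.int64
    )
    counts = np.array([rec.count for rec in records], dtype=float)

    cells = np.zeros((len(row_vocab), len(col_vocab)), dtype=float)
    for i in range(n):
        for j in range(n):
            if i == j or abs(i - j) > config.window:
                continue
            rows = token_ids_row[:, i]
            cols = token_ids_col[:, j]
            mask = (rows >= 0) & (cols >= 0) & (counts > 0)
            np.add.at(cells, (rows[mask], cols[mask]), counts[mask])

    return CooccurrenceMatrix(
        row_vocab=row_vocab, col_vocab=col_vocab, cells=cells, normalized=False
    )


def normalize_counts(
    matrix: CooccurrenceMatrix, config: SpaceConfig | None = None
) -> CooccurrenceMatrix:
    """Replace each raw count x with log(x + 1)."""
    if config is None:
        config = SpaceConfig()
    if matrix.normalized:
        raise ValueError("matrix is already log-normalized; refusing to transform twice")
    if config.log_base == "natural":
        cells = np.log1p(matrix.cells)
    else:
        cells = np.log1p(matrix.cells) / math.log(10.0)
    return CooccurrenceMatrix(
        row_vocab=list(matrix.row_vocab),
        col_vocab=list(matrix.col_vocab),
        cells=cells,
        normalized=True,
    )


def build_space(
    matrix: CooccurrenceMatrix, config: SpaceConfig | None = None
) -> SemanticSpace:
    """Truncated SVD of the normalized co-occurrence matrix.

    Embeddings are U[:, :d] * S[:d] (left singular vectors scaled by their
    singular values) with rows renormalized to unit length, so the first
    dimensions carry the most information. Sign indeterminacy is fixed by
    forcing the largest-magnitude entry of each left singular vector to be
    positive.
    """
    if config is None:
        config = SpaceConfig()
    if not matrix.normalized:
        raise ValueError("build_space requires a log-normalized matrix")
    d = min(config.n_dims, min(matrix.cells.shape))

    u, s, _vt = scipy.linalg.svd(matrix.cells, full_matrices=False)
    tol = s[0] * max(matrix.cells.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    if config.n_dims > rank and config.n_dims <= min(matrix.cells.shape):
        raise ValueError(
            f"requested {config.n_dims} dimensions but the matrix has rank {rank}"
        )
    d = min(d, rank)

    u = u[:, :d].copy()
    s = s[:d].copy()
    # deterministic sign convention
    flip = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(d)])
    flip[flip == 0] = 1.0
    u *= flip

    embeddings = u * s
    norms = np.linalg.norm(embeddings, axis=1, keepdims=True)
    if np.any(norms <= 0):
        bad = [matrix.row_vocab[i] for i in np.where(norms.ravel() <= 0)[0][:5]]
        raise ValueError(f"zero-norm embedding for words {bad}; increase corpus coverage")
    embeddings = embeddings / norms

    return SemanticSpace(
        vocab=list(matrix.row_vocab), embeddings=embeddings, singular_values=s
    )
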