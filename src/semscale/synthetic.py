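"""Synthetic two-phase severity study and matching n-gram corpus.

The generator emulates a two-phase design for studying how severity of
intimate-partner-violence events is communicated:

* **Phase 1 (P1)** — one participant per event describes a self-experienced
  psychological or physical violence event with five keywords and rates its
  severity on a 0-10 scale.
* **Phase 2 (P2)** — a separate panel of raters reads the P1 descriptions
  and re-rates them; each rater rates every event of exactly one condition,
  half of the panel per condition, and also summarizes each event in five
  keywords.

Generative model, per condition c with parameters (mu_c, sigma_c, delta_c,
response-noise sd sigma_p2c):

* latent event severity  s_e ~ Normal(mu_c, sigma_c^2)
* P1 rating              round(clip(s_e + eps1)),  eps1 ~ N(0, sigma_p1^2)
* P2 rating (rater r)    round(clip(s_e + delta_c + u_r + eps2)),
                         u_r ~ N(0, tau^2), eps2 ~ N(0, sigma_p2c^2)
* keywords               five words drawn from the severity *bin* of a
                         noisy perception s_e (+ delta_c for P2) + keyword
                         noise; each (condition, bin) owns a disjoint word
                         set, so severity is linearly decodable from the
                         learned embedding space.

delta_c is the planted calibration shift; ratings are clipped to [0, 10]
and then rounded to the 11-point instrument. The matching corpus generator
emits 5-grams in which words of the same (condition, bin) co-occur
preferentially, so an LSA space built from it places same-bin words close
together. Ground truth (latent severities, shifts, rater effects) is
retained on the dataset for oracle-based testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from semscale.space import NGramRecord

__all__ = [
    "ConditionParams",
    "StudyConfig",
    "StudyDataset",
    "Vocabulary",
    "build_vocabulary",
    "generate_corpus",
    "generate_study",
    "rating_channel",
    "analytic_signal_fraction",
    "write_study",
    "read_study",
]

log = logging.getLogger(__name__)

PSYCHOLOGICAL = "psychological"
PHYSICAL = "physical"


@dataclass(frozen=True)
class ConditionParams:
    """Latent severity distribution and shift for one violence condition.

    mu / sigma: mean and SD of the latent event severity (rating units);
    delta: planted calibration shift added on the receiving (P2) side;
    rating_noise_sd: SD of the P2 response noise, i.e. the scatter a rater
    adds when turning a perceived severity into a number.
    """

    mu: float
    sigma: float
    delta: float
    rating_noise_sd: float

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.rating_noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")


def _default_conditions() -> Mapping[str, ConditionParams]:
    # Latent means/SDs sit at the P1 summary statistics of the emulated
    # study; the planted shifts reproduce its human calibration biases.
    # Response noise is condition-specific: psychological severity is much
    # harder to re-rate consistently than physical severity.
    return {
        PSYCHOLOGICAL: ConditionParams(
            mu=6.46, sigma=1.69, delta=-0.61, rating_noise_sd=2.5
        ),
        PHYSICAL: ConditionParams(
            mu=6.59, sigma=1.81, delta=0.95, rating_noise_sd=1.0
        ),
    }


@dataclass(frozen=True)
class StudyConfig:
    """Study-scale, noise and vocabulary parameters of the generator."""

    n_events_per_condition: int = 68
    n_p2_raters: int = 40  # split evenly between the two conditions
    keywords_per_response: int = 5
    conditions: Mapping[str, ConditionParams] = field(default_factory=_default_conditions)
    rater_sd: float = 0.4  # tau: per-rater calibration offset SD
    p1_noise_sd: float = 0.8  # sigma_p1: P1 response noise
    keyword_noise_sd: float = 0.75  # perception noise on the keyword channel
    n_severity_bins: int = 11
    words_per_bin: int = 12
    n_filler_words: int = 40
    ngrams_per_bin: int = 300
    mixing_prob: float = 0.1  # probability a corpus token leaks out of its bin
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_p2_raters % 2 != 0:
            raise ValueError("n_p2_raters must be even (half per condition)")
        for name in ("rater_sd", "p1_noise_sd", "keyword_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_severity_bins < 2:
            raise ValueError("need at least 2 severity bins")
        if not 0.0 <= self.mixing_prob <= 1.0:
            raise ValueError("mixing_prob must lie in [0, 1]")
        if self.words_per_bin < self.keywords_per_response:
            raise ValueError(
                "words_per_bin must be >= keywords_per_response "
                "(keywords are sampled without replacement within a bin)"
            )
        if set(self.conditions) != {PSYCHOLOGICAL, PHYSICAL}:
            raise ValueError("conditions must be exactly {psychological, physical}")


@dataclass
class Vocabulary:
    """Disjoint word sets per (condition, severity bin) plus shared fillers."""

    bins: dict  # (condition, bin index) -> list[str]
    fillers: list[str]
    _bin_of: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._bin_of = {}
        for key, words in self.bins.items():
            for w in words:
                if w in self._bin_of:
                    raise ValueError(f"word {w!r} assigned to two bins")
                self._bin_of[w] = key

    @property
    def all_words(self) -> list[str]:
        out = []
        for key in sorted(self.bins):
            out.extend(self.bins[key])
        out.extend(self.fillers)
        return out

    def bin_of(self, word: str):
        """(condition, bin) tag of a word, or None for fillers."""
        return self._bin_of.get(word)


@dataclass
class StudyDataset:
    """Generated P1/P2 tables plus retained ground truth.

    ``truth`` holds the latent per-event severities, the per-condition
    calibration shifts, the per-rater offsets and the config — everything
    an oracle needs to score a recovery.
    """

    p1: pd.DataFrame
    p2: pd.DataFrame
    truth: dict

    @property
    def n_p2_records(self) -> int:
        return len(self.p2)


# ---------------------------------------------------------------------------
# vocabulary and corpus


def build_vocabulary(config: StudyConfig | None = None) -> Vocabulary:
    """Deterministic severity- and condition-tagged synthetic vocabulary.

    Tokens are synthetic (e.g. ``psych04w07``): the corpus emulates the
    statistical structure of severity-graded language, not English.
    """
    if config is None:
        config = StudyConfig()
    if config.words_per_bin < 1:
        raise ValueError("words_per_bin must be positive")
    prefixes = {PSYCHOLOGICAL: "psych", PHYSICAL: "phys"}
    bins = {}
    for cond in (PSYCHOLOGICAL, PHYSICAL):
        for b in range(config.n_severity_bins):
            bins[(cond, b)] = [
                f"{prefixes[cond]}{b:02d}w{i:02d}" for i in range(config.words_per_bin)
            ]
    fillers = [f"filler{i:03d}" for i in range(config.n_filler_words)]
    return Vocabulary(bins=bins, fillers=fillers)


def generate_corpus(
    vocabulary: Vocabulary, config: StudyConfig | None = None
) -> Iterator[NGramRecord]:
    """Yield 5-grams in which same-bin words co-occur preferentially.

    Each (condition, bin) contributes ``ngrams_per_bin`` 5-grams; every
    token stays within the bin with probability 1 - mixing_prob and is
    otherwise drawn uniformly from the rest of the vocabulary (fillers
    included). With mixing_prob = 0 the corpus is bin-pure.
    """
    if config is None:
        config = StudyConfig()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    all_words = vocabulary.all_words
    n = 5
    for key in sorted(vocabulary.bins):
        bin_words = vocabulary.bins[key]
        others = [w for w in all_words if w not in bin_words]
        for _ in range(config.ngrams_per_bin):
            tokens = []
            for _pos in range(n):
                if config.mixing_prob > 0 and rng.random() < config.mixing_prob:
                    tokens.append(others[rng.integers(len(others))])
                else:
                    tokens.append(bin_words[rng.integers(len(bin_words))])
            yield NGramRecord(tokens=tuple(tokens), count=1)


# ---------------------------------------------------------------------------
# study generation


def rating_channel(x: np.ndarray, n_bins: int = 11) -> np.ndarray:
    """Turn continuous severities into the 11-point instrument.

    Clip to [0, 10] first, then round to the nearest scale point. Clipping
    before rounding slightly shrinks conditions whose mean sits near the
    scale ends.
    """
    step = 10.0 / (n_bins - 1)
    clipped = np.clip(np.asarray(x, dtype=float), 0.0, 10.0)
    return np.round(clipped / step) * step


def _severity_bin(x: np.ndarray, n_bins: int) -> np.ndarray:
    scaled = np.clip(np.asarray(x, dtype=float), 0.0, 10.0) / 10.0 * (n_bins - 1)
    return np.round(scaled).astype(int)


def _draw_keywords(
    rng: np.random.Generator,
    vocabulary: Vocabulary,
    condition: str,
    severity_bin: int,
    k: int,
) -> list[str]:
    words = vocabulary.bins[(condition, int(severity_bin))]
    idx = rng.choice(len(words), size=k, replace=False)
    return [words[i] for i in idx]


def generate_study(config: StudyConfig | None = None) -> StudyDataset:
    """Generate a full two-phase dataset; bitwise-deterministic per seed."""
    if config is None:
        config = StudyConfig()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    vocabulary = build_vocabulary(config)
    n_events = config.n_events_per_condition
    raters_per_cond = config.n_p2_raters // 2
    kpr = config.keywords_per_response
    nb = config.n_severity_bins

    p1_rows = []
    p2_rows = []
    latent_rows = []
    rater_effects = {}

    for cond in (PSYCHOLOGICAL, PHYSICAL):
        params = config.conditions[cond]
        latent = rng.normal(params.mu, params.sigma, size=n_events)
        p1_noise = rng.normal(0.0, config.p1_noise_sd, size=n_events) if config.p1_noise_sd else np.zeros(n_events)
        p1_ratings = rating_channel(latent + p1_noise, nb)
        p1_percept = latent + (
            rng.normal(0.0, config.keyword_noise_sd, size=n_events)
            if config.keyword_noise_sd
            else 0.0
        )
        p1_bins = _severity_bin(p1_percept, nb)

        event_ids = [f"{cond[:5]}-e{e:03d}" for e in range(n_events)]
        for e in range(n_events):
            p1_rows.append(
                {
                    "event_id": event_ids[e],
                    "condition": cond,
                    "participant_id": f"p1-{cond[:5]}-{e:03d}",
                    "keywords": " ".join(
                        _draw_keywords(rng, vocabulary, cond, p1_bins[e], kpr)
                    ),
                    "severity": p1_ratings[e],
                }
            )
            latent_rows.append(
                {"event_id": event_ids[e], "condition": cond, "latent": latent[e]}
            )

        for r in range(raters_per_cond):
            rater_id = f"r-{cond[:5]}-{r:02d}"
            u = rng.normal(0.0, config.rater_sd) if config.rater_sd else 0.0
            rater_effects[rater_id] = float(u)
            shifted = latent + params.delta
            noise = (
                rng.normal(0.0, params.rating_noise_sd, size=n_events)
                if params.rating_noise_sd
                else np.zeros(n_events)
            )
            ratings = rating_channel(shifted + u + noise, nb)
            percept = shifted + (
                rng.normal(0.0, config.keyword_noise_sd, size=n_events)
                if config.keyword_noise_sd
                else 0.0
            )
            bins = _severity_bin(percept, nb)
            for e in range(n_events):
                p2_rows.append(
                    {
                        "rater_id": rater_id,
                        "event_id": event_ids[e],
                        "condition": cond,
                        "keywords": " ".join(
                            _draw_keywords(rng, vocabulary, cond, bins[e], kpr)
                        ),
                        "severity": ratings[e],
                    }
                )

    p1 = pd.DataFrame(p1_rows)
    p2 = pd.DataFrame(p2_rows)
    truth = {
        "latent": pd.DataFrame(latent_rows),
        "delta": {c: config.conditions[c].delta for c in config.conditions},
        "rater_effects": rater_effects,
        "config": config,
    }
    return StudyDataset(p1=p1, p2=p2, truth=truth)


# ---------------------------------------------------------------------------
# analytic oracle


def analytic_signal_fraction(
    config: StudyConfig | None = None, n_samples: int = 200_000, seed: int = 12345
) -> float:
    """Fraction of P2-rating variance predictable from the keyword channel.

    Computed by large-sample simulation of the latent channel alone (no
    corpus, no embeddings, no regression): the best possible predictor
    given a response's (condition, severity bin) is E[rating | bin,
    condition], so the attainable cross-validated r^2 equals
    var(E[rating | bin, condition]) / var(rating). Deterministic given the
    oracle seed and independent of the fitted pipeline.
    """
    if config is None:
        config = StudyConfig()
    rng = np.random.default_rng(seed)
    n_half = n_samples // 2
    parts = []
    for cond in (PSYCHOLOGICAL, PHYSICAL):
        params = config.conditions[cond]
        s = rng.normal(params.mu, params.sigma, size=n_half)
        u = rng.normal(0.0, config.rater_sd, size=n_half)
        eps = rng.normal(0.0, params.rating_noise_sd, size=n_half)
        rating = rating_channel(s + params.delta + u + eps, config.n_severity_bins)
        percept = s + params.delta + rng.normal(0.0, config.keyword_noise_sd, size=n_half)
        b = _severity_bin(percept, config.n_severity_bins)
        parts.append(pd.DataFrame({"cond": cond, "bin": b, "rating": rating}))
    df = pd.concat(parts, ignore_index=True)
    overall_var = df["rating"].var(ddof=0)
    group_means = df.groupby(["cond", "bin"])["rating"].transform("mean")
    return float(group_means.var(ddof=0) / overall_var)


# ---------------------------------------------------------------------------
# study table I/O


def write_study(dataset: StudyDataset, directory: str | Path) -> Path:
    """Write p1.tsv / p2.tsv keyword-and-rating tables (truth not written)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dataset.p1.to_csv(directory / "p1.tsv", sep="\t", index=False)
    dataset.p2.to_csv(directory / "p2.tsv", sep="\t", index=False)
    return directory


def read_study(directory: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    directory = Path(directory)
    p1 = pd.read_csv(directory / "p1.tsv", sep="\t")
    p2 = pd.read_csv(directory / "p2.tsv", sep="\t")
    return p1, p2
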