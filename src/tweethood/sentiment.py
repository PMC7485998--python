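"""Trainable sentiment scorer producing a happiness score in [0, 1].

A multinomial naive-Bayes classifier with Laplace smoothing, trained on a
labeled happy / not-happy corpus.  The score is the posterior probability of
the happy class given a tweet's tokens, computed in log space; a tweet is
called happy when the score strictly exceeds a threshold (default 0.8).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .lexicon import tokenize

__all__ = ["SentimentModel", "train_sentiment", "score_sentiment", "is_happy"]

HAPPY = "happy"
NOT_HAPPY = "not_happy"
DEFAULT_HAPPY_THRESHOLD = 0.8


class TrainingError(ValueError):
    """Raised when the labeled corpus cannot support training."""


@dataclass(frozen=True)
class SentimentModel:
    """Fitted naive-Bayes sentiment model.

    ``log_prior`` maps class -> log prior; ``log_cond`` maps class ->
    {token: log conditional}; unseen-token mass is ``log_unseen`` per class
    (the smoothed probability of a vocabulary token with zero count).
    Tokens outside the vocabulary are ignored at scoring time.
    """

    log_prior: dict[str, float]
    log_cond: dict[str, dict[str, float]]
    log_unseen: dict[str, float]
    vocabulary: frozenset[str]
    alpha: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "alpha": self.alpha,
            "log_prior": self.log_prior,
            "log_cond": self.log_cond,
            "log_unseen": self.log_unseen,
            "vocabulary": sorted(self.vocabulary),
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SentimentModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            log_prior=payload["log_prior"],
            log_cond=payload["log_cond"],
            log_unseen=payload["log_unseen"],
            vocabulary=frozenset(payload["vocabulary"]),
            alpha=payload["alpha"],
        )


def train_sentiment(
    corpus: Iterable[tuple[str, str]], alpha: float = 1.0
) -> SentimentModel:
    """Fit the naive-Bayes model on (text, label) pairs.

    Priors are label frequencies; token conditionals are
    (count + alpha) / (class token total + alpha * |V|) over the pooled
    vocabulary V.  Raises :class:`TrainingError` if only one label is
    present, and ValueError for non-positive alpha.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    doc_counts = {HAPPY: 0, NOT_HAPPY: 0}
    token_counts: dict[str, dict[str, int]] = {HAPPY: {}, NOT_HAPPY: {}}
    for text, label in corpus:
        if label not in doc_counts:
            raise ValueError(f"unknown label {label!r}; expected {HAPPY!r}/{NOT_HAPPY!r}")
        doc_counts[label] += 1
        counts = token_counts[label]
        for tok in tokenize(text):
            counts[tok] = counts.get(tok, 0) + 1
    n_docs = sum(doc_counts.values())
    if doc_counts[HAPPY] == 0 or doc_counts[NOT_HAPPY] == 0:
        raise TrainingError("training corpus must contain both happy and not-happy labels")
    vocab = frozenset(token_counts[HAPPY]) | frozenset(token_counts[NOT_HAPPY])
    log_prior = {c: math.log(doc_counts[c] / n_docs) for c in doc_counts}
    log_cond: dict[str, dict[str, float]] = {}
    log_unseen: dict[str, float] = {}
    v = len(vocab)
    for c, counts in token_counts.items():
        total = sum(counts.values())
        denom = total + alpha * v
        log_cond[c] = {t: math.log((counts.get(t, 0) + alpha) / denom) for t in vocab}
        log_unseen[c] = math.log(alpha / denom) if v else 0.0
    return SentimentModel(
        log_prior=log_prior,
        log_cond=log_cond,
        log_unseen=log_unseen,
        vocabulary=vocab,
        alpha=alpha,
    )


def score_sentiment(model: SentimentModel, text: str | Sequence[str]) -> float:
    """Posterior probability of the happy class for a tweet.

    Accepts raw text or a pre-tokenized sequence.  Out-of-vocabulary tokens
    carry no evidence; an empty (or fully OOV) token set returns the happy
    prior.  Computed in log space and normalized, so the result is a valid
    probability in [0, 1].
    """
    tokens = tokenize(text) if isinstance(text, str) else list(text)
    log_post = dict(model.log_prior)
    for tok in tokens:
        if tok not in model.vocabulary:
            continue
        for c in log_post:
            log_post[c] += model.log_cond[c][tok]
    m = max(log_post.values())
    denom = sum(math.exp(v - m) for v in log_post.values())
    return math.exp(log_post[HAPPY] - m) / denom


def is_happy(score: float, threshold: float = DEFAULT_HAPPY_THRESHOLD) -> bool:
    """Happy iff the sentiment score strictly exceeds the threshold."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"sentiment score must be in [0, 1], got {score}")
    return score > threshold
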