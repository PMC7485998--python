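"""Tweet containers, stream preprocessing, and per-tweet classification.

The classification stage turns a raw geotagged tweet stream into one record
per surviving tweet with a sentiment score and five binary flags (happy,
food, healthy food, fast food, physical activity).  Preprocessing removes
exact-duplicate texts and job postings identified through hashtags before
any classifier runs.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .lexicon import Lexicon, match_food, match_physical_activity
from .sentiment import DEFAULT_HAPPY_THRESHOLD, SentimentModel, is_happy, score_sentiment

logger = logging.getLogger(__name__)

__all__ = [
    "Tweet",
    "ClassifiedTweet",
    "preprocess",
    "classify_stream",
    "read_tweets_jsonl",
    "write_tweets_jsonl",
]

_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class Tweet:
    """One geotagged message: point coordinates plus text and hashtags."""

    id: str
    user_id: str
    created_at: str
    lon: float
    lat: float
    text: str
    hashtags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} out of [-180, 180]")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} out of [-90, 90]")
        if not self.text.strip():
            raise ValueError("tweet text empty after whitespace normalization")

    @property
    def normalized_text(self) -> str:
        return _WS_RE.sub(" ", self.text.strip().lower())


@dataclass(frozen=True)
class ClassifiedTweet:
    """Per-tweet classification output; healthy/fast imply food by construction."""

    id: str
    sentiment_score: float
    happy: bool
    food: bool
    healthy_food: bool
    fast_food: bool
    physical_activity: bool


def preprocess(tweets: Iterable[Tweet], lexicon: Lexicon) -> Iterator[Tweet]:
    """Drop duplicate texts and job postings; keep input order otherwise.

    A tweet is a duplicate when its whitespace-normalized, lowercased text
    exactly matches an earlier tweet's (across all users).  Job postings are
    tweets carrying any blocklisted hashtag.  Idempotent by construction.
    """
    seen: set[str] = set()
    blocked = lexicon.jobpost_hashtags
    for tw in tweets:
        if any(h.lower().lstrip("#") in blocked for h in tw.hashtags):
            continue
        norm = tw.normalized_text
        if norm in seen:
            continue
        seen.add(norm)
        yield tw


def classify_tweet(
    tweet: Tweet,
    model: SentimentModel,
    lexicon: Lexicon,
    threshold: float = DEFAULT_HAPPY_THRESHOLD,
) -> ClassifiedTweet:
    score = score_sentiment(model, tweet.text)
    food, healthy, fast = match_food(tweet.text, lexicon)
    return ClassifiedTweet(
        id=tweet.id,
        sentiment_score=score,
        happy=is_happy(score, threshold),
        food=food,
        healthy_food=healthy,
        fast_food=fast,
        physical_activity=match_physical_activity(tweet.text, lexicon),
    )


def classify_stream(
    tweets: Iterable[Tweet],
    model: SentimentModel,
    lexicon: Lexicon,
    threshold: float = DEFAULT_HAPPY_THRESHOLD,
) -> Iterator[ClassifiedTweet]:
    """Preprocess then classify each surviving tweet."""
    for tw in preprocess(tweets, lexicon):
        yield classify_tweet(tw, model, lexicon, threshold)


def classified_to_frame(records: Iterable[ClassifiedTweet]) -> pd.DataFrame:
    rows = [
        (r.id, r.sentiment_score, r.happy, r.food, r.healthy_food, r.fast_food, r.physical_activity)
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["id", "score", "happy", "food", "healthy_food", "fast_food", "physical_activity"],
    )


# -- JSONL IO -------------------------------------------------------------


def read_tweets_jsonl(path: str | Path) -> tuple[list[Tweet], int]:
    """Read a JSONL tweet stream; malformed lines are logged and counted.

    Returns (tweets, n_skipped).  Never silently drops a line: each skip is
    logged at WARNING with the line number.
    """
    tweets: list[Tweet] = []
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                tweets.append(
                    Tweet(
                        id=str(obj["id"]),
                        user_id=str(obj["user_id"]),
                        created_at=str(obj["created_at"]),
                        lon=float(obj["lon"]),
                        lat=float(obj["lat"]),
                        text=str(obj["text"]),
                        hashtags=tuple(obj.get("hashtags", [])),
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                skipped += 1
                logger.warning("skipping unreadable tweet line %d: %s", lineno, exc)
    return tweets, skipped


def write_tweets_jsonl(tweets: Iterable[Tweet], path: str | Path) -> int:
    """Write tweets as JSONL with a stable key order; returns record count."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for tw in tweets:
            fh.write(
                json.dumps(
                    {
                        "id": tw.id,
                        "user_id": tw.user_id,
                        "created_at": tw.created_at,
                        "lon": tw.lon,
                        "lat": tw.lat,
                        "text": tw.text,
                        "hashtags": list(tw.hashtags),
                    },
                    sort_keys=True,
                )
                + "\n"
            )
            n += 1
    return n
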