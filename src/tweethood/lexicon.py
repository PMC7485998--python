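"""Dictionary-based topic matching for tweets: food and physical activity.

Tweets are matched against a phrase lexicon (healthy food, fast food, other
food, physical activity) with longest-match-first semantics over token runs.
Physical-activity matching applies three contextual rules, in order:

1. *Idiom veto* — an exclusion phrase ("running late", "walk away", ...)
   vetoes only the activity term it embeds, not the whole tweet.
2. *Spectator veto* — any form of watch/attend anywhere in the tweet vetoes
   every match (tweets about passively watching sports).
3. *Team-sport gate* — a team-sport phrase (basketball, soccer, ...) counts
   only when a form of "play" is present in the tweet.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "Lexicon",
    "tokenize",
    "match_food",
    "match_physical_activity",
    "SPECTATOR_VERBS",
    "PLAY_FORMS",
    "DEFAULT_JOBPOST_HASHTAGS",
]

SPECTATOR_VERBS = frozenset(
    {
        "watch", "watching", "watches", "watched",
        "attend", "attends", "attending", "attended",
    }
)
PLAY_FORMS = frozenset({"play", "plays", "playing", "played"})
DEFAULT_JOBPOST_HASHTAGS = frozenset({"job", "jobs", "hiring", "careerarc", "nowhiring"})

_URL_RE = re.compile(r"(?:https?://\S+|www\.\S+)")
_MENTION_RE = re.compile(r"@\w+")
_TOKEN_RE = re.compile(r"[a-z0-9']+")


def tokenize(text: str, *, keep_mentions: bool = False) -> list[str]:
    """Normalize tweet text into a token sequence.

    Lowercases, strips URLs and @-mentions, drops the '#' from hashtags
    (keeping the word), and splits on punctuation.  With ``keep_mentions``
    the handle word survives with its '@' removed — used by lexicon
    matching, where brand mentions like "@starbucks" are topical signal.
    """
    text = text.lower()
    text = _URL_RE.sub(" ", text)
    if keep_mentions:
        text = text.replace("@", " ")
    else:
        text = _MENTION_RE.sub(" ", text)
    return _TOKEN_RE.findall(text)


@dataclass(frozen=True)
class Lexicon:
    """Phrase -> category table plus the contextual-exclusion machinery.

    ``entries`` maps token-tuples to one of {healthy_food, fast_food,
    other_food, physical_activity}.  ``team_sport`` marks PA phrases subject
    to the play-form gate.  Exclusion phrases are stored as token-tuples.
    """

    entries: dict[tuple[str, ...], str]
    team_sport: frozenset[tuple[str, ...]] = frozenset()
    exclusion_phrases: tuple[tuple[str, ...], ...] = ()
    spectator_verbs: frozenset[str] = SPECTATOR_VERBS
    play_forms: frozenset[str] = PLAY_FORMS
    jobpost_hashtags: frozenset[str] = DEFAULT_JOBPOST_HASHTAGS
    _max_len: int = field(init=False, default=1)

    def __post_init__(self) -> None:
        for phrase, cat in self.entries.items():
            if not phrase or any(not t for t in phrase):
                raise ValueError(f"empty phrase token in {phrase!r}")
            if cat not in {"healthy_food", "fast_food", "other_food", "physical_activity"}:
                raise ValueError(f"unknown lexicon category {cat!r} for {phrase!r}")
        for phrase in self.exclusion_phrases:
            if not phrase:
                raise ValueError("empty exclusion phrase")
        lengths = [len(p) for p in self.entries] + [len(p) for p in self.exclusion_phrases]
        object.__setattr__(self, "_max_len", max(lengths, default=1))

    # -- construction -----------------------------------------------------

    @classmethod
    def from_tsv(
        cls,
        lexicon_path: str | Path,
        exclusions_path: str | Path | None = None,
        jobpost_hashtags: Iterable[str] | None = None,
    ) -> "Lexicon":
        """Load a lexicon from TSV (columns: phrase, category, team_sport)."""
        entries: dict[tuple[str, ...], str] = {}
        team: set[tuple[str, ...]] = set()
        with open(lexicon_path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                phrase = tuple(tokenize(row["phrase"]))
                entries[phrase] = row["category"].strip()
                if row.get("team_sport", "0").strip() == "1":
                    team.add(phrase)
        exclusions: list[tuple[str, ...]] = []
        if exclusions_path is not None:
            with open(exclusions_path, newline="", encoding="utf-8") as fh:
                for row in csv.DictReader(fh, delimiter="\t"):
                    exclusions.append(tuple(tokenize(row["phrase"])))
        jp = frozenset(h.lower().lstrip("#") for h in jobpost_hashtags) if jobpost_hashtags else DEFAULT_JOBPOST_HASHTAGS
        return cls(
            entries=entries,
            team_sport=frozenset(team),
            exclusion_phrases=tuple(exclusions),
            jobpost_hashtags=jp,
        )

    @classmethod
    def default(cls) -> "Lexicon":
        """The packaged default lexicon (~120 food/PA phrases)."""
        data = resources.files("tweethood.data")
        with resources.as_file(data / "lexicon.tsv") as lex, resources.as_file(
            data / "exclusions.tsv"
        ) as exc:
            return cls.from_tsv(lex, exc)

    # -- matching ---------------------------------------------------------

    def find_matches(self, tokens: list[str]) -> list[tuple[int, int, tuple[str, ...]]]:
        """Longest-match-first scan over token runs.

        Returns (start, end, phrase) spans; after a match the scan resumes
        past the matched span, so "green beans" is one healthy entry even
        when "beans" is also in the lexicon.
        """
        out: list[tuple[int, int, tuple[str, ...]]] = []
        i, n = 0, len(tokens)
        while i < n:
            matched = False
            for length in range(min(self._max_len, n - i), 0, -1):
                cand = tuple(tokens[i : i + length])
                if cand in self.entries:
                    out.append((i, i + length, cand))
                    i += length
                    matched = True
                    break
            if not matched:
                i += 1
        return out

    def exclusion_spans(self, tokens: list[str]) -> list[tuple[int, int]]:
        """Spans of every exclusion-phrase occurrence in the token list."""
        spans: list[tuple[int, int]] = []
        n = len(tokens)
        for phrase in self.exclusion_phrases:
            m = len(phrase)
            for i in range(n - m + 1):
                if tuple(tokens[i : i + m]) == phrase:
                    spans.append((i, i + m))
        return spans


def match_food(text: str, lexicon: Lexicon) -> tuple[bool, bool, bool]:
    """Flag a tweet's food mentions: (food, healthy_food, fast_food).

    ``food`` is true when any lexicon entry of a food category matches;
    the healthy/fast flags are independent, so a tweet naming both a kale
    salad and a burger chain sets both.
    """
    tokens = tokenize(text, keep_mentions=True)
    food = healthy = fast = False
    for _, _, phrase in lexicon.find_matches(tokens):
        cat = lexicon.entries[phrase]
        if cat in ("healthy_food", "fast_food", "other_food"):
            food = True
            healthy = healthy or cat == "healthy_food"
            fast = fast or cat == "fast_food"
    return food, healthy, fast


def match_physical_activity(text: str, lexicon: Lexicon) -> bool:
    """True when the tweet mentions doing (not watching) physical activity."""
    tokens = tokenize(text, keep_mentions=True)
    matches = [
        (s, e, p)
        for s, e, p in lexicon.find_matches(tokens)
        if lexicon.entries[p] == "physical_activity"
    ]
    if not matches:
        return False
    # rule 1: idiom veto — drop matches embedded in an exclusion occurrence
    excl = lexicon.exclusion_spans(tokens)
    matches = [
        (s, e, p)
        for s, e, p in matches
        if not any(s >= xs and e <= xe for xs, xe in excl)
    ]
    if not matches:
        return False
    # rule 2: spectator veto, tweet-wide
    if any(t in lexicon.spectator_verbs for t in tokens):
        return False
    # rule 3: team sports need a play-form
    has_play = any(t in lexicon.play_forms for t in tokens)
    matches = [(s, e, p) for s, e, p in matches if p not in lexicon.team_sport or has_play]
    return bool(matches)
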