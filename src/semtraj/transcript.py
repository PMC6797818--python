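"""Transcript tables and content-word filtering.

Converts transcribed feature responses into ordered content-word token
sequences per trial.  Function words are removed by explicit,
configurable exclusion lists; two profiles are shipped:

``strict``
    Articles, coordinating conjunctions, personal pronouns, possessive
    pronouns/determiners, and all inflections of *be*, *do* and *have*.
``extended`` (default)
    The strict lists plus common prepositions and modal auxiliaries,
    which observed scoring behaviour also leaves unscored.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ARTICLES",
    "COORDINATING_CONJUNCTIONS",
    "PERSONAL_PRONOUNS",
    "POSSESSIVE_PRONOUNS",
    "AUXILIARY_VERBS",
    "PREPOSITIONS",
    "MODAL_AUXILIARIES",
    "ExclusionLists",
    "TrialRecord",
    "FeatureTokens",
    "TranscriptError",
    "tokenize",
    "filter_content_words",
    "read_trials",
    "prepare_features",
]

ARTICLES = frozenset({"a", "an", "the"})
COORDINATING_CONJUNCTIONS = frozenset({"and", "but", "or", "nor", "for", "so", "yet"})
PERSONAL_PRONOUNS = frozenset(
    {"i", "you", "he", "she", "it", "we", "they", "me", "him", "her", "us", "them"}
)
POSSESSIVE_PRONOUNS = frozenset(
    {"my", "your", "his", "her", "its", "our", "their",
     "mine", "yours", "hers", "ours", "theirs"}
)
AUXILIARY_VERBS = frozenset(
    {"be", "am", "is", "are", "was", "were", "been", "being",
     "do", "does", "did", "doing", "done",
     "have", "has", "had", "having"}
)
PREPOSITIONS = frozenset(
    {"in", "on", "at", "of", "to", "from", "with", "by", "for", "about",
     "as", "into", "onto", "over", "under", "between", "through", "during",
     "before", "after", "above", "below", "up", "down", "off", "out",
     "against", "among", "around", "near", "without", "within", "upon"}
)
MODAL_AUXILIARIES = frozenset(
    {"can", "could", "will", "would", "shall", "should", "may", "might", "must"}
)

#: extra words left unscored in practice that no grammatical class covers
_EXTENDED_MISC = frozenset({"either", "neither"})

VALID_GROUPS = ("CO", "HP")

_PUNCT = string.punctuation + "‘’“”–—"


class TranscriptError(ValueError):
    """Raised when a transcript table violates its schema."""


@dataclass(frozen=True)
class ExclusionLists:
    """The set of function words removed before similarity scoring."""

    words: frozenset[str]
    profile: str = "extended"

    @classmethod
    def from_profile(cls, profile: str = "extended",
                     extra: Iterable[str] = ()) -> "ExclusionLists":
        strict = (ARTICLES | COORDINATING_CONJUNCTIONS | PERSONAL_PRONOUNS
                  | POSSESSIVE_PRONOUNS | AUXILIARY_VERBS)
        if profile == "strict":
            words = strict
        elif profile == "extended":
            words = strict | PREPOSITIONS | MODAL_AUXILIARIES | _EXTENDED_MISC
        else:
            raise ValueError(f"unknown exclusion profile {profile!r}")
        words = words | frozenset(w.lower() for w in extra)
        return cls(words=words, profile=profile)

    def __contains__(self, word: str) -> bool:
        return word in self.words


@dataclass
class TrialRecord:
    """One subject x target-word trial: the ordered raw feature strings."""

    subject_id: str
    group: str
    target_word: str
    features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise TranscriptError(
                f"unknown group label {self.group!r} (expected one of {VALID_GROUPS})"
            )


@dataclass
class FeatureTokens:
    """A single feature response reduced to ordered content-word tokens.

    ``tokens`` may be empty when every word was excluded; such features
    are flagged via :attr:`all_excluded` and skipped downstream, never
    silently dropped, so response positions stay aligned.
    """

    position: int
    tokens: list[str]
    raw_text: str

    @property
    def all_excluded(self) -> bool:
        return not self.tokens


def tokenize(text: str, lowercase: bool = True) -> list[str]:
    """Split on whitespace, strip punctuation from token edges, case-fold."""
    out = []
    for tok in text.split():
        tok = tok.strip(_PUNCT)
        if not tok:
            continue
        out.append(tok.lower() if lowercase else tok)
    return out


def filter_content_words(tokens: Sequence[str],
                         exclusions: ExclusionLists) -> list[str]:
    """Remove excluded function words, preserving order. Idempotent."""
    return [t for t in tokens if t not in exclusions]


def prepare_features(trial: TrialRecord, exclusions: ExclusionLists,
                     lowercase: bool = True) -> list[FeatureTokens]:
    """Tokenize and filter every feature of a trial, keeping positions."""
    return [
        FeatureTokens(
            position=i,
            tokens=filter_content_words(tokenize(raw, lowercase=lowercase), exclusions),
            raw_text=raw,
        )
        for i, raw in enumerate(trial.features, start=1)
    ]


_REQUIRED_COLUMNS = ["subject_id", "group", "target_word", "position", "feature_text"]


def read_trials(path: str | Path, sep: str | None = None) -> list[TrialRecord]:
    """Read a transcript table (TSV default, CSV by extension) into trials.

    The table needs columns ``subject_id, group, target_word, position,
    feature_text``.  Rows are grouped into one :class:`TrialRecord` per
    (subject, target); positions must be contiguous from 1 and unique.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TranscriptError(f"{path}: missing columns {missing}")
    try:
        df["position"] = df["position"].astype(int)
    except ValueError as exc:
        raise TranscriptError(f"{path}: non-integer position value") from exc
    bad = sorted(set(df["group"]) - set(VALID_GROUPS))
    if bad:
        raise TranscriptError(f"{path}: unknown group label(s) {bad}")

    trials: list[TrialRecord] = []
    # preserve order of first appearance
    for (subject, target), sub in df.groupby(["subject_id", "target_word"], sort=False):
        groups = set(sub["group"])
        if len(groups) > 1:
            raise TranscriptError(
                f"{path}: subject {subject!r} carries multiple group labels {sorted(groups)}"
            )
        sub = sub.sort_values("position")
        positions = sub["position"].tolist()
        if len(set(positions)) != len(positions):
            raise TranscriptError(
                f"{path}: duplicate position in trial (subject={subject!r}, "
                f"target={target!r})"
            )
        if positions != list(range(1, len(positions) + 1)):
            raise TranscriptError(
                f"{path}: positions not contiguous from 1 in trial "
                f"(subject={subject!r}, target={target!r}): {positions}"
            )
        trials.append(
            TrialRecord(
                subject_id=str(subject),
                group=groups.pop(),
                target_word=str(target),
                features=sub["feature_text"].tolist(),
            )
        )
    return trials
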