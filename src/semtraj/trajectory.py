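"""Similarity trajectories: target-to-feature and feature-to-feature scores.

Each multi-word feature is scored against the trial's target word by
averaging the per-word cosines of its in-vocabulary content words
(position records), and against other features of the same trial by
averaging all cross-feature word-pair cosines (lag records).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .embeddings import EmbeddingSpace, cosine
from .transcript import ExclusionLists, FeatureTokens, TrialRecord, prepare_features

__all__ = [
    "SimilarityRecord",
    "LagRecord",
    "TargetNotInVocabulary",
    "target_feature_similarity",
    "feature_feature_similarity",
    "build_position_records",
    "build_lag_records",
    "group_summary",
    "records_to_frame",
    "write_records_csv",
]

log = logging.getLogger(__name__)


class TargetNotInVocabulary(KeyError):
    """The target word anchors every score; its absence is fatal for a trial."""


@dataclass
class SimilarityRecord:
    """Target-to-feature cosine at one response position of one trial."""

    subject_id: str
    group: str
    target_word: str
    position: int
    score: float
    n_scored_words: int


@dataclass
class LagRecord:
    """Feature-to-feature cosine for one ordered pair within a trial."""

    subject_id: str
    group: str
    target_word: str
    lag: int
    from_position: int
    to_position: int
    score: float


def target_feature_similarity(
    target: str, feature: FeatureTokens, space: EmbeddingSpace
) -> Optional[tuple[float, int]]:
    """Mean cosine between the target word and each scorable feature word.

    Out-of-vocabulary feature words are skipped; ``None`` is returned
    when no word is scorable.  An out-of-vocabulary *target* raises
    :class:`TargetNotInVocabulary`.
    """
    tvec = space.vector(target)
    if tvec is None:
        raise TargetNotInVocabulary(target)
    scores = [cosine(tvec, wvec)
              for tok in feature.tokens
              if (wvec := space.vector(tok)) is not None]
    if not scores:
        return None
    return float(np.mean(scores)), len(scores)


def feature_feature_similarity(
    f1: FeatureTokens, f2: FeatureTokens, space: EmbeddingSpace
) -> Optional[float]:
    """Mean cosine over all in-vocabulary word pairs drawn one from each feature."""
    v1 = [v for tok in f1.tokens if (v := space.vector(tok)) is not None]
    v2 = [v for tok in f2.tokens if (v := space.vector(tok)) is not None]
    if not v1 or not v2:
        return None
    m1 = np.vstack(v1)
    m2 = np.vstack(v2)
    m1 = m1 / np.linalg.norm(m1, axis=1, keepdims=True)
    m2 = m2 / np.linalg.norm(m2, axis=1, keepdims=True)
    return float(np.mean(m1 @ m2.T))


def _prepared(trials, exclusions, lowercase):
    for trial in trials:
        yield trial, prepare_features(trial, exclusions, lowercase=lowercase)


def build_position_records(
    trials: Sequence[TrialRecord],
    space: EmbeddingSpace,
    exclusions: Optional[ExclusionLists] = None,
    max_position: Optional[int] = 5,
    lowercase: bool = True,
) -> list[SimilarityRecord]:
    """One record per (trial, scorable position), capped at ``max_position``.

    ``max_position=None`` keeps every position (the uncapped overall
    analysis); the positional cap of 5 serves the early-trajectory
    analysis.
    """
    exclusions = exclusions or ExclusionLists.from_profile()
    records: list[SimilarityRecord] = []
    n_skipped = 0
    for trial, feats in _prepared(trials, exclusions, lowercase):
        for feat in feats:
            if max_position is not None and feat.position > max_position:
                break
            result = target_feature_similarity(trial.target_word, feat, space)
            if result is None:
                n_skipped += 1
                continue
            score, n_words = result
            records.append(
                SimilarityRecord(
                    subject_id=trial.subject_id,
                    group=trial.group,
                    target_word=trial.target_word,
                    position=feat.position,
                    score=score,
                    n_scored_words=n_words,
                )
            )
    if n_skipped:
        log.warning("skipped %d features with no scorable words", n_skipped)
    return records


def build_lag_records(
    trials: Sequence[TrialRecord],
    space: EmbeddingSpace,
    exclusions: Optional[ExclusionLists] = None,
    max_lag: int = 4,
    lowercase: bool = True,
) -> list[LagRecord]:
    """All ordered within-trial feature pairs separated by 1..``max_lag``.

    Scores never reference the target vector; ``target_word`` is kept
    only for the random-effect grouping downstream.
    """
    exclusions = exclusions or ExclusionLists.from_profile()
    records: list[LagRecord] = []
    for trial, feats in _prepared(trials, exclusions, lowercase):
        n = len(feats)
        for i in range(n):
            for lag in range(1, max_lag + 1):
                j = i + lag
                if j >= n:
                    break
                score = feature_feature_similarity(feats[i], feats[j], space)
                if score is None:
                    continue
                records.append(
                    LagRecord(
                        subject_id=trial.subject_id,
                        group=trial.group,
                        target_word=trial.target_word,
                        lag=lag,
                        from_position=feats[i].position,
                        to_position=feats[j].position,
                        score=score,
                    )
                )
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Records (dataclasses, dicts, or an existing frame) as a tidy frame."""
    import dataclasses

    if isinstance(records, pd.DataFrame):
        return records
    if len(records) == 0:
        raise ValueError("no records")
    if dataclasses.is_dataclass(records[0]):
        return pd.DataFrame([asdict(r) for r in records])
    return pd.DataFrame(records)


def write_records_csv(records, path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def group_summary(records: Sequence[SimilarityRecord | LagRecord]) -> pd.DataFrame:
    """Per-group mean, SD (ddof=1) and count of ``score``, for descriptives."""
    df = records_to_frame(records)
    out = (
        df.groupby("group")["score"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    if (out["n"] == 0).any():
        raise ValueError("empty group in summary")
    return out
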