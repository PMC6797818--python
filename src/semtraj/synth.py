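"""Synthetic data generation.

Everything the pipeline consumes can be generated here without any
download: deterministic fixture embedding spaces, power-law trajectory
datasets with known parameters for recovery tests, and full synthetic
cohorts produced by a compound-retrieval-cue search simulator.

The simulator is a formalization of a verbal mechanism: retrieval is
probed by a cue blending the target vector with the most recent
response, candidates are activated in proportion to their proximity to
the cue, and the restricted group (HP) additionally may not retrieve
candidates below a floor of similarity to the target.  It is a data
generator and hypothesis demonstrator, not a fitted cognitive model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .embeddings import EmbeddingSpace, write_embeddings
from .trajectory import SimilarityRecord
from .transcript import TrialRecord

__all__ = [
    "SearchSimConfig",
    "CohortConfig",
    "make_fixture_space",
    "make_anchored_space",
    "generate_power_law_records",
    "simulate_search",
    "generate_cohort",
    "write_cohort",
    "DEFAULT_TARGET_WORDS",
]

#: 35 everyday concrete nouns standing in for feature-norm targets.
DEFAULT_TARGET_WORDS = [
    "book", "grapefruit", "bed", "dolphin", "key", "chair", "apple", "train",
    "guitar", "mirror", "candle", "bridge", "hammer", "jacket", "lemon",
    "owl", "pencil", "river", "saddle", "tractor", "umbrella", "violin",
    "wagon", "anchor", "basket", "cabin", "drum", "engine", "fence",
    "garden", "helmet", "island", "kettle", "ladder", "magnet",
]


def make_fixture_space(
    words: Sequence[str], dims: int, seed: int, lowercase: bool = True
) -> EmbeddingSpace:
    """Deterministic unit vectors per word: same seed, bit-identical space."""
    if dims < 2:
        raise ValueError("dims must be >= 2")
    rng = np.random.default_rng(seed)
    vectors: dict[str, np.ndarray] = {}
    for word in words:
        key = word.lower() if lowercase else word
        v = rng.standard_normal(dims)
        vectors[key] = v / np.linalg.norm(v)
    return EmbeddingSpace(vectors=vectors, dims=dims, lowercase=lowercase)


def make_anchored_space(
    target: str, word_cosines: dict[str, float], lowercase: bool = True
) -> EmbeddingSpace:
    """A space where each word has a prescribed cosine to ``target``.

    The target sits on the first axis; word k is placed at
    ``c * e_1 + sqrt(1 - c^2) * e_{k+1}``, so its cosine to the target
    is exactly the requested value (to float rounding).  Useful for
    exercising the aggregation rules against known word-level scores.
    """
    dims = len(word_cosines) + 1
    vectors: dict[str, np.ndarray] = {}
    tvec = np.zeros(dims)
    tvec[0] = 1.0
    vectors[target.lower() if lowercase else target] = tvec
    for k, (word, c) in enumerate(word_cosines.items(), start=1):
        if not -1.0 <= c <= 1.0:
            raise ValueError(f"cosine for {word!r} outside [-1, 1]")
        v = np.zeros(dims)
        v[0] = c
        v[k] = np.sqrt(1.0 - c * c)
        vectors[word.lower() if lowercase else word] = v
    return EmbeddingSpace(vectors=vectors, dims=dims, lowercase=lowercase)


def generate_power_law_records(
    a: float,
    b: float,
    noise_sd: float,
    n_subjects: int,
    x_max: int,
    seed: int,
    n_reps: int = 35,
    group: str = "CO",
    subject_sd_a: float = 0.0,
    subject_sd_b: float = 0.0,
    x_field: str = "position",
    subject_prefix: Optional[str] = None,
) -> tuple[list[SimilarityRecord], dict]:
    """Scores ``a * x**b + Normal(0, noise_sd)`` with subject labels.

    ``n_reps`` pseudo-trials per subject contribute one record at each
    x in 1..x_max.  Optional per-subject jitter of (a, b) exercises the
    hierarchical structure.  Returns the records together with the
    generating truth for recovery tests.
    """
    if a <= 0:
        raise ValueError("a must be positive")
    if x_max < 2:
        raise ValueError("x_max must be >= 2")
    rng = np.random.default_rng(seed)
    prefix = subject_prefix or f"{group}_s"
    records: list[SimilarityRecord] = []
    xs = np.arange(1, x_max + 1)
    for j in range(n_subjects):
        a_j = a + subject_sd_a * rng.standard_normal()
        b_j = b + subject_sd_b * rng.standard_normal()
        a_j = max(a_j, 1e-3)
        for rep in range(n_reps):
            scores = a_j * xs.astype(float) ** b_j
            if noise_sd > 0:
                scores = scores + noise_sd * rng.standard_normal(x_max)
            for xi, sc in zip(xs, scores):
                records.append(
                    SimilarityRecord(
                        subject_id=f"{prefix}{j + 1:02d}",
                        group=group,
                        target_word=f"t{rep + 1:02d}",
                        position=int(xi),
                        score=float(sc),
                        n_scored_words=1,
                    )
                )
    truth = {
        "a": a, "b": b, "noise_sd": noise_sd, "n_subjects": n_subjects,
        "x_max": x_max, "n_reps": n_reps, "group": group, "seed": seed,
        "subject_sd_a": subject_sd_a, "subject_sd_b": subject_sd_b,
        "x_field": x_field,
    }
    return records, truth


@dataclass
class SearchSimConfig:
    """Parameters of the compound-retrieval-cue search simulator.

    At step t the cue is ``c_t = lam_t * v_target + (1 - lam_t) * v_prev``
    (normalized; the first cue is the target alone).  Candidates whose
    cosine to the *target* falls below ``range_limit`` are never
    eligible — the restricted-search analogue for the HP group; -1
    disables the restriction.  Among eligible unreported candidates the
    selection probability is proportional to
    ``max(cos(c_t, v), 0) ** selection_sharpness``; an infinite
    sharpness picks the argmax deterministically.
    """

    dims: int = 32
    n_candidates: int = 60
    target_spread: float = 0.35
    cue_weight_decay: float = 0.8
    cue_weight_floor: float = 0.3
    selection_sharpness: float = 10.0
    range_limit: float = -1.0
    max_responses: int = 20
    stop_probability: float = 0.0
    cue_weights: Optional[Sequence[float]] = None

    def cue_weight(self, step: int) -> float:
        """lam_t for 1-based step; non-increasing by construction."""
        if self.cue_weights is not None:
            t = min(step, len(self.cue_weights)) - 1
            return float(self.cue_weights[t])
        return max(self.cue_weight_floor, self.cue_weight_decay ** (step - 1))

    def __post_init__(self) -> None:
        if self.cue_weights is not None:
            w = np.asarray(self.cue_weights, dtype=float)
            if np.any(w < 0) or np.any(w > 1):
                raise ValueError("cue weights must lie in [0, 1]")
            if np.any(np.diff(w) > 0):
                raise ValueError("cue weights must be non-increasing")
        if self.n_candidates < self.max_responses:
            raise ValueError("n_candidates must cover max_responses")


def _candidate_cloud(tvec: np.ndarray, cfg: SearchSimConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """Unit candidate vectors scattered around the target.

    Each candidate is ``normalize(w * v_target + z)`` with z a random
    unit direction and ``w ~ Uniform(0, 2 * target_spread)``, so
    target-similarities span a broad band from near-orthogonal to
    close; larger ``target_spread`` concentrates candidates nearer the
    target on average.
    """
    z = rng.standard_normal((cfg.n_candidates, tvec.size))
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    w = rng.uniform(0.0, 2.0 * cfg.target_spread, size=cfg.n_candidates)
    c = w[:, None] * tvec[None, :] + z
    return c / np.linalg.norm(c, axis=1, keepdims=True)


def simulate_search(
    target: str,
    space: EmbeddingSpace,
    cfg: SearchSimConfig,
    seed: int | np.random.Generator,
    candidates: Optional[np.ndarray] = None,
) -> list[int]:
    """One trial of simulated memory search; returns candidate indices in order.

    Candidates default to a fresh cloud around the target.  Sampling is
    without replacement; the trial ends at ``max_responses``, on a
    per-step stop draw, or when no eligible candidate with positive
    support remains (a valid short trial).
    """
    tvec = space.vector(target)
    if tvec is None:
        raise KeyError(f"target {target!r} not in embedding space")
    tvec = tvec / np.linalg.norm(tvec)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if candidates is None:
        candidates = _candidate_cloud(tvec, cfg, rng)

    target_sim = candidates @ tvec
    eligible = target_sim >= cfg.range_limit
    reported: list[int] = []
    prev: Optional[np.ndarray] = None
    for step in range(1, cfg.max_responses + 1):
        if cfg.stop_probability > 0 and rng.uniform() < cfg.stop_probability:
            break
        lam = cfg.cue_weight(step)
        cue = tvec if prev is None else lam * tvec + (1.0 - lam) * prev
        norm = np.linalg.norm(cue)
        if norm == 0:
            break
        cue = cue / norm
        support = np.maximum(candidates @ cue, 0.0)
        support[~eligible] = 0.0
        support[reported] = 0.0
        if not np.any(support > 0):
            break
        if np.isinf(cfg.selection_sharpness):
            pick = int(np.argmax(support))
        else:
            p = support ** cfg.selection_sharpness
            p = p / p.sum()
            pick = int(rng.choice(candidates.shape[0], p=p))
        reported.append(pick)
        prev = candidates[pick]
    return reported


@dataclass
class CohortConfig:
    """Cohort layout mirroring the study defaults: 5 HP, 15 CO, 35 targets."""

    n_hp: int = 5
    n_co: int = 15
    n_targets: int = 35
    dims: int = 32
    hp_config: SearchSimConfig = field(default_factory=lambda: SearchSimConfig(
        range_limit=0.4, max_responses=10, stop_probability=0.05))
    co_config: SearchSimConfig = field(default_factory=lambda: SearchSimConfig(
        range_limit=-1.0, max_responses=20, stop_probability=0.02))
    max_extra_words: int = 2  # neighbour words appended to form phrases
    function_word_probability: float = 0.5
    target_words: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        if min(self.n_hp, self.n_co, self.n_targets) <= 0:
            raise ValueError("cohort counts must be positive")


_FILLERS = ["the", "is", "you", "a", "it", "and", "of", "in", "can"]


def generate_cohort(
    cfg: CohortConfig, seed: int
) -> tuple[list[TrialRecord], EmbeddingSpace, dict]:
    """A full synthetic cohort in the transcript schema plus its space.

    Each trial runs the search simulator over a per-target candidate
    cloud shared by all subjects; each retrieved candidate is rendered
    as a short phrase (the candidate word, up to ``max_extra_words`` of
    its nearest candidate neighbours, and optionally an interleaved
    function word so the content-word filter is exercised end to end).
    """
    rng = np.random.default_rng(seed)
    targets = list(cfg.target_words or DEFAULT_TARGET_WORDS[: cfg.n_targets])
    if len(targets) < cfg.n_targets:
        targets = targets + [f"target{k:02d}" for k in range(len(targets), cfg.n_targets)]
    targets = targets[: cfg.n_targets]

    # one shared candidate cloud per target so groups search the same space
    vectors: dict[str, np.ndarray] = {}
    cand_words: dict[str, list[str]] = {}
    cand_vecs: dict[str, np.ndarray] = {}
    n_cand = max(cfg.hp_config.n_candidates, cfg.co_config.n_candidates)
    for ti, target in enumerate(targets):
        tvec = rng.standard_normal(cfg.dims)
        tvec /= np.linalg.norm(tvec)
        vectors[target.lower()] = tvec
        cloud_cfg = SearchSimConfig(
            dims=cfg.dims, n_candidates=n_cand,
            target_spread=cfg.co_config.target_spread,
            max_responses=1,
        )
        cloud = _candidate_cloud(tvec, cloud_cfg, rng)
        words = [f"{target.lower()}f{k:03d}" for k in range(n_cand)]
        for w, v in zip(words, cloud):
            vectors[w] = v
        cand_words[target] = words
        cand_vecs[target] = cloud
    space = EmbeddingSpace(vectors=vectors, dims=cfg.dims, lowercase=True)

    trials: list[TrialRecord] = []
    for group, count, sim_cfg in (("HP", cfg.n_hp, cfg.hp_config),
                                  ("CO", cfg.n_co, cfg.co_config)):
        for j in range(count):
            subject = f"{group}{j + 1:02d}"
            for target in targets:
                picks = simulate_search(target, space, sim_cfg, rng,
                                        candidates=cand_vecs[target])
                features = []
                cloud = cand_vecs[target]
                words = cand_words[target]
                for pick in picks:
                    phrase = [words[pick]]
                    n_extra = int(rng.integers(0, cfg.max_extra_words + 1))
                    if n_extra:
                        sims = cloud @ cloud[pick]
                        sims[pick] = -np.inf
                        order = np.argsort(sims)[::-1][:5]
                        chosen = rng.choice(order, size=min(n_extra, order.size),
                                            replace=False)
                        phrase += [words[k] for k in chosen]
                    if rng.uniform() < cfg.function_word_probability:
                        filler = _FILLERS[int(rng.integers(0, len(_FILLERS)))]
                        pos = int(rng.integers(0, len(phrase) + 1))
                        phrase.insert(pos, filler)
                    features.append(" ".join(phrase))
                trials.append(TrialRecord(subject_id=subject, group=group,
                                          target_word=target, features=features))

    truth = {
        "seed": seed,
        "config": {
            "n_hp": cfg.n_hp, "n_co": cfg.n_co, "n_targets": cfg.n_targets,
            "dims": cfg.dims,
            "hp_config": asdict(cfg.hp_config),
            "co_config": asdict(cfg.co_config),
            "max_extra_words": cfg.max_extra_words,
            "function_word_probability": cfg.function_word_probability,
        },
        "targets": targets,
    }
    return trials, space, truth


def write_cohort(
    trials: Sequence[TrialRecord],
    space: EmbeddingSpace,
    truth: dict,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Serialize a cohort: transcript TSV, embedding text file, truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "transcript": out / "transcript.tsv",
        "embeddings": out / "embeddings.txt",
        "truth": out / "truth.json",
    }
    with paths["transcript"].open("w", encoding="utf-8") as fh:
        fh.write("subject_id\tgroup\ttarget_word\tposition\tfeature_text\n")
        for trial in trials:
            for pos, feat in enumerate(trial.features, start=1):
                fh.write(f"{trial.subject_id}\t{trial.group}\t{trial.target_word}"
                         f"\t{pos}\t{feat}\n")
    write_embeddings(space, paths["embeddings"])
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return paths
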