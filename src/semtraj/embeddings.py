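"""Word-embedding spaces: loading, lookup, and cosine similarity.

The on-disk format is the de-facto standard text layout: one word per
line followed by its D whitespace-separated float components, UTF-8,
no header.  All similarity scoring elsewhere in the package goes
through :func:`cosine`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "EmbeddingSpace",
    "EmbeddingFormatError",
    "load_embeddings",
    "write_embeddings",
    "cosine",
]


class EmbeddingFormatError(ValueError):
    """Raised when an embedding file violates the expected text layout."""


@dataclass
class EmbeddingSpace:
    """A vocabulary of fixed-dimension real vectors.

    Parameters
    ----------
    vectors
        Mapping from (already case-normalized) word to its vector.
    dims
        Dimensionality shared by every vector.
    lowercase
        Whether lookups case-fold their argument before lookup.  The
        vocabulary itself must already be normalized consistently.
    """

    vectors: dict[str, np.ndarray]
    dims: int
    lowercase: bool = True

    def __post_init__(self) -> None:
        if not self.vectors:
            raise ValueError("embedding space must contain at least one word")
        for word, vec in self.vectors.items():
            if vec.shape != (self.dims,):
                raise ValueError(
                    f"vector for {word!r} has shape {vec.shape}, expected ({self.dims},)"
                )
            if not np.any(vec):
                raise ValueError(f"vector for {word!r} is all-zero")

    def normalize(self, word: str) -> str:
        return word.lower() if self.lowercase else word

    def vector(self, word: str) -> Optional[np.ndarray]:
        """Return the vector for ``word``, or ``None`` if out of vocabulary.

        Missingness is a value, never an error and never a zero vector.
        """
        return self.vectors.get(self.normalize(word))

    def __contains__(self, word: str) -> bool:
        return self.normalize(word) in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    @property
    def words(self) -> list[str]:
        return list(self.vectors)


def load_embeddings(
    path: str | Path,
    expected_dims: Optional[int] = None,
    lowercase: bool = True,
) -> EmbeddingSpace:
    """Read an embedding text file into an :class:`EmbeddingSpace`.

    Raises
    ------
    EmbeddingFormatError
        On an empty file, a row whose length disagrees with the first
        row (the offending line number is named), a non-numeric
        component, a duplicate word with a conflicting vector, or an
        all-zero vector.
    """
    path = Path(path)
    vectors: dict[str, np.ndarray] = {}
    dims: Optional[int] = None
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            word = parts[0].lower() if lowercase else parts[0]
            try:
                vec = np.array([float(x) for x in parts[1:]], dtype=np.float64)
            except ValueError as exc:
                raise EmbeddingFormatError(
                    f"{path}:{lineno}: non-numeric vector component"
                ) from exc
            if vec.size == 0:
                raise EmbeddingFormatError(f"{path}:{lineno}: no vector components")
            if dims is None:
                dims = vec.size
            elif vec.size != dims:
                raise EmbeddingFormatError(
                    f"{path}:{lineno}: row has {vec.size} components, expected {dims}"
                )
            if not np.any(vec):
                raise EmbeddingFormatError(f"{path}:{lineno}: all-zero vector for {word!r}")
            if word in vectors:
                if not np.array_equal(vectors[word], vec):
                    raise EmbeddingFormatError(
                        f"{path}:{lineno}: duplicate word {word!r} with conflicting vector"
                    )
                continue
            vectors[word] = vec
    if dims is None:
        raise EmbeddingFormatError(f"{path}: empty embedding file")
    if expected_dims is not None and dims != expected_dims:
        raise EmbeddingFormatError(
            f"{path}: dimension {dims} does not match expected {expected_dims}"
        )
    return EmbeddingSpace(vectors=vectors, dims=dims, lowercase=lowercase)


def write_embeddings(space: EmbeddingSpace, path: str | Path) -> None:
    """Write ``space`` in the text layout; round-trips bit-exactly.

    Components are serialized with ``repr`` so that ``float`` parsing
    recovers the identical IEEE-754 doubles.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for word, vec in space.vectors.items():
            fh.write(word + " " + " ".join(repr(float(x)) for x in vec) + "\n")


def cosine(u: Iterable[float], v: Iterable[float]) -> float:
    """Cosine similarity ``dot(u, v) / (|u| * |v|)``.

    Raises
    ------
    ValueError
        If the vectors differ in length or either has zero norm.
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine is undefined for zero-norm vectors")
    return float(np.dot(u, v) / (nu * nv))
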