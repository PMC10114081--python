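"""Cosine-similarity matching of derived signatures to reference catalogs.

A signature is compared to each column of a reference catalog (e.g. the
COSMIC SBS set) by cosine similarity, ``dot(a, b) / (|a| |b|)``, which is 1
for identical shapes and 0 for disjoint channel support, and is invariant to
positive scaling — raw counts and probabilities give the same score.
Matches at or above a threshold (default 0.8, the conventional cut-off for
calling two signatures similar) are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .channels import ChannelAxis
from .spectra import Spectrum

__all__ = [
    "SignatureCatalog",
    "cosine_similarity",
    "match_catalog",
    "similarity_matrix",
    "SIMILARITY_THRESHOLD",
]

SIMILARITY_THRESHOLD = 0.8


@dataclass(frozen=True)
class SignatureCatalog:
    """Named probability vectors over one channel axis (COSMIC-style)."""

    axis: ChannelAxis
    names: tuple[str, ...]
    vectors: np.ndarray  # shape (n_channels, n_signatures)

    def __post_init__(self) -> None:
        vectors = np.asarray(self.vectors, dtype=float)
        if vectors.shape != (len(self.axis), len(self.names)):
            raise ValueError(
                f"catalog shape {vectors.shape} does not match "
                f"({len(self.axis)} channels, {len(self.names)} signatures)"
            )
        if (vectors < 0).any():
            raise ValueError("catalog contains negative entries")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate signature names")
        sums = vectors.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("catalog columns must each sum to 1 +- 1e-9")
        object.__setattr__(self, "vectors", vectors)

    def __len__(self) -> int:
        return len(self.names)

    def vector(self, name: str) -> np.ndarray:
        return self.vectors[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.vectors, index=list(self.axis.channels), columns=self.names)

    @staticmethod
    def from_spectra(spectra: list[Spectrum]) -> "SignatureCatalog":
        """Build a catalog from probability spectra (all-zero ones rejected)."""
        if not spectra:
            raise ValueError("need at least one spectrum")
        axis = spectra[0].axis
        for s in spectra:
            if s.axis is not axis:
                raise ValueError("spectra on mixed axes")
            if s.is_zero:
                raise ValueError(f"spectrum {s.sample_id!r} is all-zero")
        probs = np.stack([s.counts / s.counts.sum() for s in spectra], axis=1)
        return SignatureCatalog(axis, tuple(s.sample_id for s in spectra), probs)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity of two non-negative vectors, in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("cosine_similarity expects non-negative vectors")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity of an all-zero vector is undefined")
    return float(np.clip(a @ b / (na * nb), 0.0, 1.0))


def match_catalog(
    query: Spectrum,
    catalog: SignatureCatalog,
    threshold: float = SIMILARITY_THRESHOLD,
) -> list[tuple[str, float, bool]]:
    """Rank catalog signatures by similarity to the query.

    Returns ``(name, similarity, flagged)`` triples sorted by decreasing
    similarity, ties broken by catalog order; ``flagged`` marks similarity >=
    ``threshold``. An all-zero query is an error (propagate the flagged
    state upstream instead of scoring it).
    """
    if query.axis is not catalog.axis:
        raise ValueError(f"axis mismatch: query {query.axis.kind}, catalog {catalog.axis.kind}")
    if len(catalog) == 0:
        raise ValueError("empty catalog")
    if query.is_zero:
        raise ValueError(f"query spectrum {query.sample_id!r} is all-zero")
    sims = [cosine_similarity(query.counts, catalog.vectors[:, j]) for j in range(len(catalog))]
    ranked = sorted(range(len(catalog)), key=lambda j: (-sims[j], j))
    return [(catalog.names[j], sims[j], sims[j] >= threshold) for j in ranked]


def similarity_matrix(queries: list[Spectrum], catalog: SignatureCatalog) -> pd.DataFrame:
    """All-pairs cosine similarities: queries as rows, catalog as columns."""
    rows = {}
    for q in queries:
        if q.axis is not catalog.axis:
            raise ValueError(f"axis mismatch for query {q.sample_id!r}")
        rows[q.sample_id] = [
            cosine_similarity(q.counts, catalog.vectors[:, j]) for j in range(len(catalog))
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(catalog.names))
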