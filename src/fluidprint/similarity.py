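"""Adjusted-cosine similarity scores for reproducibility / intragroup coherence.

The adjusted cosine of two intensity vectors centers each vector by its
own mean before taking the cosine (equivalently, their Pearson
correlation), which removes per-sample offset effects; the
recommender-style variant that instead centers each feature by its cohort
mean is available as ``mode="item"``.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .core_io import FeatureMatrix
from .errors import DomainError, UndefinedSimilarityError


def adjusted_cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the two mean-centered vectors; in [-1, 1].

    Raises :class:`UndefinedSimilarityError` if either vector is constant
    (zero after centering).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise DomainError("adjusted cosine needs two equal-length vectors (n >= 2)")
    ac = a - a.mean()
    bc = b - b.mean()
    na, nb = np.linalg.norm(ac), np.linalg.norm(bc)
    if na == 0 or nb == 0:
        raise UndefinedSimilarityError("constant vector: similarity undefined")
    return float(np.clip(ac @ bc / (na * nb), -1.0, 1.0))


@dataclass
class SimilaritySummary:
    group: str
    pairwise_scores: np.ndarray      # condensed upper-triangle scores
    per_sample_score: dict[str, float]  # mean similarity to group peers
    mean: float
    cutoff: float
    fraction_above: float


def group_similarity(
    matrix: FeatureMatrix,
    groups,
    cutoff: float = 0.8,
    mode: str = "self",
) -> dict[str, SimilaritySummary]:
    """Within-group pairwise adjusted cosines for each group.

    Per-sample score is the mean similarity to the sample's group peers;
    ``fraction_above`` is the share of samples whose score exceeds
    ``cutoff``. Singleton groups are skipped with a warning.
    """
    if mode not in ("self", "item"):
        raise DomainError(f"unknown centering mode {mode!r}")
    groups = np.asarray(groups)
    if groups.size != matrix.n_samples():
        raise DomainError("group labels must match matrix rows")
    values = matrix.values
    if mode == "item":
        values = values - values.mean(axis=0, keepdims=True)

    out: dict[str, SimilaritySummary] = {}
    for g in dict.fromkeys(groups):  # preserve first-seen order
        rows = np.where(groups == g)[0]
        if rows.size < 2:
            warnings.warn(f"group {g!r} has fewer than 2 samples; skipped")
            continue
        k = rows.size
        sim = np.empty((k, k))
        np.fill_diagonal(sim, 1.0)
        pairwise = []
        for ii in range(k):
            for jj in range(ii + 1, k):
                s = (
                    adjusted_cosine(values[rows[ii]], values[rows[jj]])
                    if mode == "self"
                    else _plain_cosine(values[rows[ii]], values[rows[jj]])
                )
                sim[ii, jj] = sim[jj, ii] = s
                pairwise.append(s)
        per_sample = (sim.sum(axis=1) - 1.0) / (k - 1)
        ids = [matrix.sample_ids[r] for r in rows]
        out[str(g)] = SimilaritySummary(
            group=str(g),
            pairwise_scores=np.asarray(pairwise),
            per_sample_score=dict(zip(ids, per_sample.tolist())),
            mean=float(np.mean(pairwise)),
            cutoff=cutoff,
            fraction_above=float(np.mean(per_sample > cutoff)),
        )
    return out


def _plain_cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise UndefinedSimilarityError("zero vector: similarity undefined")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))
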