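"""Kinase-plate profile similarity and affinity-propagation clustering.

Each retested interaction yields a profile: the set of kinase-plate spots
that supported growth. Profiles are first restricted to the ``k`` spots that
came up most across all profiles (default 14, ties broken lexicographically);
pairwise similarity between non-empty restricted profiles is

    s(a, b) = |a ∩ b|^2 / (|a| * |b|),

a symmetric overlap measure in [0, 1] equal to 1 iff the spot sets coincide.
Profiles are then clustered by affinity propagation (Frey-Dueck
responsibility/availability message passing) with the preference set to the
median of all off-diagonal similarities, damping 0.9, and convergence
declared when the exemplar set is stable for a window of iterations.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .types import KinaseProfileVector, SimilarityMatrix


def top_k_spots(
    profiles: list[KinaseProfileVector], k: int = 14
) -> tuple[list[KinaseProfileVector], list[str]]:
    """Restrict profiles to the k most frequent spot labels.

    Spots are ranked by occurrence count across profiles, ties broken
    lexicographically. Returns the re-projected profiles (same order; possibly
    with empty spot sets) and the list of interaction ids whose restricted
    profile came out empty.
    """
    counts: Counter[str] = Counter()
    for p in profiles:
        counts.update(p.spots)
    keep = frozenset(
        sorted(counts, key=lambda s: (-counts[s], s))[:k]
    )
    restricted = [
        KinaseProfileVector(p.interaction_id, p.spots & keep) for p in profiles
    ]
    emptied = [p.interaction_id for p in restricted if not p.spots]
    return restricted, emptied


def profile_similarity(a: KinaseProfileVector, b: KinaseProfileVector) -> float:
    """Squared overlap over the product of profile sizes: |a∩b|² / (|a|·|b|)."""
    if not a.spots or not b.spots:
        raise ValueError("profile similarity is undefined for empty profiles")
    overlap = len(a.spots & b.spots)
    return overlap**2 / (len(a.spots) * len(b.spots))


def similarity_matrix(profiles: list[KinaseProfileVector]) -> SimilarityMatrix:
    """Pairwise similarity over non-empty profiles, with median preference.

    The preference recorded is the median of all off-diagonal similarity
    values ("the median globally"); the diagonal itself is 1.
    """
    if any(not p.spots for p in profiles):
        raise ValueError("drop empty profiles (see top_k_spots) before building S")
    n = len(profiles)
    s = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s[i, j] = s[j, i] = profile_similarity(profiles[i], profiles[j])
    if n > 1:
        off_diag = s[~np.eye(n, dtype=bool)]
        preference = float(np.median(off_diag))
    else:
        preference = 1.0
    return SimilarityMatrix([p.interaction_id for p in profiles], s, preference)


@dataclass
class ClusteringResult:
    """Exemplar clustering of a similarity matrix.

    ``labels[i]`` is the index of item i's exemplar; exemplars are assigned
    to themselves. ``converged`` is False when message passing hit
    ``max_iter`` without a stable exemplar set (the best-so-far partition is
    still returned, with a warning).
    """

    exemplars: np.ndarray  # indices of exemplar items
    labels: np.ndarray  # exemplar index per item
    converged: bool
    n_iter: int

    @property
    def n_clusters(self) -> int:
        return len(self.exemplars)


def affinity_propagation(
    S: SimilarityMatrix | np.ndarray,
    preference: float | None = None,
    damping: float = 0.9,
    max_iter: int = 1000,
    convergence_window: int = 50,
    jitter_seed: int = 0,
) -> ClusteringResult:
    """Affinity propagation on a precomputed similarity matrix.

    Standard responsibility/availability updates with the given damping; the
    diagonal is replaced by ``preference`` (the matrix's recorded preference,
    or the median off-diagonal similarity when none is given). A tiny seeded
    jitter (machine-epsilon scale) breaks exact ties so degenerate inputs
    converge deterministically.
    """
    if not 0.5 <= damping < 1.0:
        raise ValueError("damping must lie in [0.5, 1)")
    if isinstance(S, SimilarityMatrix):
        if preference is None and np.isfinite(S.preference):
            preference = S.preference
        S = np.asarray(S.values, dtype=float)
    s = np.array(S, dtype=float, copy=True)
    n = s.shape[0]
    if s.shape != (n, n):
        raise ValueError("similarity matrix must be square")
    if n == 1:
        return ClusteringResult(np.array([0]), np.array([0]), True, 0)
    if preference is None:
        preference = float(np.median(s[~np.eye(n, dtype=bool)]))
    s.flat[:: n + 1] = preference

    rng = np.random.default_rng(jitter_seed)
    s += (np.finfo(float).eps * s + np.finfo(float).tiny * 100) * rng.standard_normal(
        (n, n)
    )

    A = np.zeros((n, n))
    R = np.zeros((n, n))
    ind = np.arange(n)
    history = np.zeros((n, convergence_window), dtype=bool)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # responsibilities
        tmp = A + s
        I = np.argmax(tmp, axis=1)
        Y1 = tmp[ind, I]
        tmp[ind, I] = -np.inf
        Y2 = tmp.max(axis=1)
        Rnew = s - Y1[:, None]
        Rnew[ind, I] = s[ind, I] - Y2
        R = damping * R + (1 - damping) * Rnew

        # availabilities
        Rp = np.maximum(R, 0)
        Rp.flat[:: n + 1] = R.flat[:: n + 1]
        Anew = Rp - Rp.sum(axis=0)  # -(column sum excluding self contribution)
        dA = Anew.flat[:: n + 1].copy()
        Anew = np.clip(Anew, 0, None)
        Anew.flat[:: n + 1] = dA
        A = damping * A + (1 - damping) * (-Anew)

        exemplar_mask = (np.diag(A) + np.diag(R)) > 0
        history[:, (it - 1) % convergence_window] = exemplar_mask
        if it >= convergence_window:
            stable = (history.sum(axis=1) % convergence_window == 0).all()
            if stable and exemplar_mask.any():
                converged = True
                break

    exemplars = np.flatnonzero((np.diag(A) + np.diag(R)) > 0)
    if exemplars.size == 0:
        # degenerate: fall back to the single best self-similarity exemplar
        exemplars = np.array([int(np.argmax(np.diag(A) + np.diag(R)))])
    labels_k = np.argmax(s[:, exemplars], axis=1)
    labels_k[exemplars] = np.arange(exemplars.size)
    # refine exemplars to maximise within-cluster similarity, then re-assign
    for k in range(exemplars.size):
        members = np.flatnonzero(labels_k == k)
        j = np.argmax(s[np.ix_(members, members)].sum(axis=0))
        exemplars[k] = members[j]
    labels_k = np.argmax(s[:, exemplars], axis=1)
    labels_k[exemplars] = np.arange(exemplars.size)
    labels = exemplars[labels_k]
    if not converged:
        warnings.warn(
            "affinity propagation did not converge; returning best-so-far partition",
            stacklevel=2,
        )
    return ClusteringResult(exemplars, labels, converged, it)


def cluster_profiles(
    profiles: list[KinaseProfileVector],
    top_k: int = 14,
    damping: float = 0.9,
    max_iter: int = 1000,
    convergence_window: int = 50,
) -> tuple[dict[str, str], list[str], ClusteringResult]:
    """Full pipeline: top-k restriction, similarity, affinity propagation.

    Returns (interaction id -> exemplar interaction id, ids excluded for
    empty restricted profiles, raw clustering result).
    """
    restricted, emptied = top_k_spots(profiles, top_k)
    kept = [p for p in restricted if p.spots]
    if not kept:
        return {}, emptied, ClusteringResult(np.array([], int), np.array([], int), True, 0)
    sim = similarity_matrix(kept)
    result = affinity_propagation(
        sim, damping=damping, max_iter=max_iter, convergence_window=convergence_window
    )
    assignment = {
        p.interaction_id: kept[int(result.labels[i])].interaction_id
        for i, p in enumerate(kept)
    }
    return assignment, emptied, result
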