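"""Tree-likeness analysis: pairwise F_ST, split decomposition, Q-residual.

A strictly bifurcating history implies an additive (tree) metric on the
ancestries; gene flow breaks additivity.  This module quantifies that in
two ways:

* **Split decomposition** (Bandelt–Dress) decomposes a distance matrix into
  weighted bipartitions (d-splits).  A split's weight is its isolation
  index

      alpha(A|B) = 1/2 * min over i,i' in A and j,j' in B of
                   [ max( d(i,j) + d(i',j'),
                          d(i,j') + d(i',j),
                          d(i,i') + d(j,j') ) - d(i,i') - d(j,j') ],

  the minimum taken over all (not necessarily distinct) pairs.  Splits with
  positive index are retained; incompatible retained splits render as a
  network rather than a tree.  Computation is incremental — taxa are added
  one at a time, and each d-split of the extended set restricts to a
  d-split of the previous set (or is the new trivial split), which bounds
  the candidate set.  Exhaustive enumeration over all 2^(K-1) - 1
  bipartitions serves as an oracle for small K.

* The **Q-residual score** measures deviation from the four-point
  condition: after scaling distances so the mean off-diagonal entry is 1,
  each quartet contributes (s1 - s2)^2 where s1 >= s2 >= s3 are its three
  pairwise-sum pairings; the score is the mean over all C(K, 4) quartets.
  Additive metrics score exactly 0.  The leave-one-out table recomputes the
  score with each taxon excluded (re-normalizing the submatrix): a *lower*
  leave-one-out score means the excluded taxon contributed more to
  non-tree-like behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .tables import DistanceMatrix, FrequencyTable, Split, SplitSystem

__all__ = [
    "pairwise_fst",
    "isolation_index",
    "split_decomposition",
    "split_decomposition_exhaustive",
    "q_residual",
    "q_residual_leave_one_out",
    "QResidualReport",
]

#: isolation indices at or below this are treated as zero (split rejected)
_SPLIT_TOL = 1e-10


def pairwise_fst(table: FrequencyTable, corrected: bool = True) -> DistanceMatrix:
    """Hudson-type ratio-of-averages F_ST between every ancestry pair.

    Per pair (j, k) the estimate is

        sum_m [ (p_j - p_k)^2 - p_j(1-p_j)/(n_j - 1) - p_k(1-p_k)/(n_k - 1) ]
        -----------------------------------------------------------------
        sum_m [ p_j (1 - p_k) + p_k (1 - p_j) ]

    i.e. numerator and denominator are averaged over markers *before*
    taking the ratio, which avoids the per-marker ratio's bias.  With
    ``corrected=False`` (frequencies-only mode) the finite-sample
    correction terms are omitted.  Estimates are clamped to [0, 1].
    """
    if corrected:
        if table.counts is None:
            raise ValueError("corrected F_ST needs allele counts; "
                             "use corrected=False for frequencies-only mode")
        if np.any(table.counts < 2):
            raise ValueError("allele counts must be at least 2")
    p = table.freqs
    k = table.n_ancestries
    d = np.zeros((k, k))
    for i, j in combinations(range(k), 2):
        pi, pj = p[:, i], p[:, j]
        num = (pi - pj) ** 2
        if corrected:
            num = num - pi * (1 - pi) / (table.counts[i] - 1.0)
            num = num - pj * (1 - pj) / (table.counts[j] - 1.0)
        den = pi * (1 - pj) + pj * (1 - pi)
        den_sum = den.sum()
        fst = num.sum() / den_sum if den_sum > 0 else 0.0
        d[i, j] = d[j, i] = min(max(fst, 0.0), 1.0)
    return DistanceMatrix(list(table.ancestries), d)


def isolation_index(dm: DistanceMatrix, side_a) -> float:
    """Bandelt–Dress isolation index of the bipartition ``side_a`` vs rest."""
    a_idx = np.array(sorted(dm.index(x) for x in side_a))
    b_idx = np.array([i for i in range(dm.n_taxa) if i not in set(a_idx)])
    if len(a_idx) == 0 or len(b_idx) == 0:
        raise ValueError("both split sides must be nonempty")
    d = dm.d
    dA = d[np.ix_(a_idx, a_idx)]          # (a, a)
    dB = d[np.ix_(b_idx, b_idx)]          # (b, b)
    cross = d[np.ix_(a_idx, b_idx)]       # (a, b)
    # quartet term over (i, i', j, j'), pairs may repeat
    x1 = cross[:, None, :, None] + cross[None, :, None, :]   # d(i,j) + d(i',j')
    x2 = cross[:, None, None, :] + cross[None, :, :, None]   # d(i,j') + d(i',j)
    x3 = dA[:, :, None, None] + dB[None, None, :, :]         # d(i,i') + d(j,j')
    excess = np.maximum(np.maximum(x1, x2), x3) - x3
    return 0.5 * float(excess.min())


def _canonical_split(labels: list[str], side_a: frozenset, weight: float) -> Split:
    taxa = frozenset(labels)
    anchor = min(labels)
    a = side_a if anchor in side_a else taxa - side_a
    return Split(a, taxa - a, weight)


def split_decomposition(dm: DistanceMatrix) -> SplitSystem:
    """All d-splits (positive isolation index) of a distance matrix.

    Incremental Bandelt–Dress construction: starting from the two-taxon
    system, each new taxon x extends every current d-split A|B to the
    candidates A+x|B and A|B+x, plus the trivial split x|rest; candidates
    with positive isolation index on the enlarged taxon set survive.
    """
    labels = dm.labels
    if dm.n_taxa < 2:
        raise ValueError("split decomposition needs at least 2 taxa")
    current: list[frozenset] = [frozenset([labels[0]])]  # sides not containing new taxa
    for k in range(2, dm.n_taxa + 1):
        sub = dm.submatrix(labels[:k])
        new_taxon = labels[k - 1]
        prev_taxa = frozenset(labels[: k - 1])
        candidates: set[frozenset] = {frozenset([new_taxon])}
        for side in current:
            candidates.add(side)                        # new taxon joins other side
            candidates.add(side | {new_taxon})          # new taxon joins this side
        current = []
        for side in candidates:
            other = (prev_taxa | {new_taxon}) - side
            if not side or not other:
                continue
            if isolation_index(sub, side) > _SPLIT_TOL:
                # store the side not containing the last-added taxon where
                # possible; identity is the unordered bipartition either way
                current.append(side)
        # dedupe complements
        seen: set[frozenset] = set()
        deduped = []
        full = prev_taxa | {new_taxon}
        for side in current:
            key = frozenset((side, full - side))
            if key not in seen:
                seen.add(key)
                deduped.append(side)
        current = deduped
    splits = [
        _canonical_split(labels, side, isolation_index(dm, side)) for side in current
    ]
    splits.sort(key=lambda s: (len(s.side_a), sorted(s.side_a)))
    return SplitSystem(list(labels), splits)


def split_decomposition_exhaustive(dm: DistanceMatrix) -> SplitSystem:
    """Direct enumeration of all 2^(K-1) - 1 bipartitions (small K only)."""
    labels = dm.labels
    if dm.n_taxa < 2:
        raise ValueError("split decomposition needs at least 2 taxa")
    if dm.n_taxa > 12:
        raise ValueError("exhaustive enumeration is limited to 12 taxa")
    anchor, rest = labels[0], labels[1:]
    splits = []
    for r in range(len(rest) + 1):
        for combo in combinations(rest, r):
            side = frozenset((anchor, *combo))
            if len(side) == dm.n_taxa:
                continue
            w = isolation_index(dm, side)
            if w > _SPLIT_TOL:
                splits.append(_canonical_split(labels, side, w))
    splits.sort(key=lambda s: (len(s.side_a), sorted(s.side_a)))
    return SplitSystem(list(labels), splits)


def _normalized(d: np.ndarray) -> np.ndarray:
    k = d.shape[0]
    off_mean = d.sum() / (k * (k - 1))
    if off_mean <= 0:
        return d.copy()
    return d / off_mean


def q_residual(dm: DistanceMatrix) -> float:
    """Mean squared excess of the largest quartet pairing sum.

    Distances are scaled to mean off-diagonal 1 (making the score
    scale-free); each quartet {i, j, k, l} contributes (s1 - s2)^2 for its
    ordered pairing sums s1 >= s2 >= s3.  Zero iff the metric satisfies the
    four-point condition on every quartet.
    """
    if dm.n_taxa < 4:
        raise ValueError("Q-residual needs at least 4 taxa")
    d = _normalized(dm.d)
    quartets = np.array(list(combinations(range(dm.n_taxa), 4)))
    i, j, k, l = quartets.T
    s_a = d[i, j] + d[k, l]
    s_b = d[i, k] + d[j, l]
    s_c = d[i, l] + d[j, k]
    s = np.sort(np.stack([s_a, s_b, s_c], axis=1), axis=1)
    return float(np.mean((s[:, 2] - s[:, 1]) ** 2))


@dataclass
class QResidualReport:
    """Full-matrix Q-residual plus per-taxon leave-one-out scores."""

    full_score: float
    loo_scores: dict[str, float]
    ranking: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "excluded_ancestry": self.ranking,
                "q_residual": [self.loo_scores[x] for x in self.ranking],
            }
        )


def q_residual_leave_one_out(dm: DistanceMatrix) -> QResidualReport:
    """Q-residual with each taxon excluded in turn, ranked ascending.

    Each (K-1)-taxon submatrix is re-normalized before scoring, since the
    score is defined on the analyzed taxon set.  The top-ranked (lowest
    scoring) taxon is the one whose removal leaves the most tree-like
    matrix — i.e. the largest contributor to network-like behaviour.
    Ties break lexicographically.
    """
    if dm.n_taxa < 5:
        raise ValueError("leave-one-out needs at least 5 taxa")
    loo = {
        lab: q_residual(dm.submatrix([x for x in dm.labels if x != lab]))
        for lab in dm.labels
    }
    # scores at numerical zero (additive submatrices) tie lexicographically
    ranking = sorted(loo, key=lambda lab: (loo[lab] if loo[lab] > 1e-12 else 0.0, lab))
    return QResidualReport(full_score=q_residual(dm), loo_scores=loo, ranking=ranking)
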