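"""Core in-memory containers shared across the pipeline.

The pipeline operates on *ancestry-level* summaries rather than individual
genotypes: a matrix of allele frequencies per ancestry component (the layout
ADMIXTURE writes in its ``.P`` file), per-ancestry effective allele counts
derived from the ``.Q`` proportions, and pairwise distance matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrequencyTable",
    "AncestryProportions",
    "DistanceMatrix",
    "Split",
    "SplitSystem",
]


@dataclass
class FrequencyTable:
    """Allele frequencies for M biallelic markers across K named ancestries.

    Parameters
    ----------
    ancestries
        K unique ancestry labels, in column order.
    freqs
        M x K array of allele frequencies in [0, 1].
    counts
        Optional per-ancestry total allele counts (length K).  These are
        *effective* counts — twice the sum of per-individual ancestry
        proportions — and may be non-integral.  ``None`` means the table is
        in frequencies-only mode and finite-sample corrections cannot be
        applied.
    """

    ancestries: list[str]
    freqs: np.ndarray
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ancestries = list(self.ancestries)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2:
            raise ValueError("freqs must be a 2-D (markers x ancestries) array")
        if len(set(self.ancestries)) != len(self.ancestries):
            raise ValueError("ancestry labels must be unique")
        if len(self.ancestries) != self.freqs.shape[1]:
            raise ValueError(
                f"{len(self.ancestries)} labels but {self.freqs.shape[1]} columns"
            )
        if len(self.ancestries) < 2:
            raise ValueError("need at least 2 ancestries")
        if self.freqs.shape[0] < 1:
            raise ValueError("need at least 1 marker")
        if np.any(self.freqs < -1e-9) or np.any(self.freqs > 1 + 1e-9):
            raise ValueError("allele frequencies must lie in [0, 1]")
        np.clip(self.freqs, 0.0, 1.0, out=self.freqs)
        if self.counts is not None:
            self.counts = np.asarray(self.counts, dtype=float)
            if self.counts.shape != (len(self.ancestries),):
                raise ValueError("counts must have one entry per ancestry")
            if np.any(self.counts <= 0):
                raise ValueError("allele counts must be positive")

    @property
    def n_markers(self) -> int:
        return self.freqs.shape[0]

    @property
    def n_ancestries(self) -> int:
        return self.freqs.shape[1]

    def index(self, label: str) -> int:
        try:
            return self.ancestries.index(label)
        except ValueError:
            raise KeyError(f"unknown ancestry label: {label!r}") from None

    def column(self, label: str) -> np.ndarray:
        """Frequency vector (length M) for one ancestry."""
        return self.freqs[:, self.index(label)]

    def count(self, label: str) -> float:
        if self.counts is None:
            raise ValueError("table has no allele counts (frequencies-only mode)")
        return float(self.counts[self.index(label)])

    def with_counts(self, counts) -> "FrequencyTable":
        """Return a copy of the table with per-ancestry allele counts attached.

        ``counts`` may be a scalar (shared by all ancestries), a sequence of
        length K, or a mapping from label to count.
        """
        if np.isscalar(counts):
            arr = np.full(self.n_ancestries, float(counts))
        elif isinstance(counts, dict):
            arr = np.array([float(counts[a]) for a in self.ancestries])
        else:
            arr = np.asarray(counts, dtype=float)
        return FrequencyTable(list(self.ancestries), self.freqs.copy(), arr)


@dataclass
class AncestryProportions:
    """Per-individual ancestry proportions (the ADMIXTURE ``.Q`` matrix).

    Rows are individuals, columns are ancestries; each row sums to 1 within
    a tolerance of 1e-4.
    """

    props: np.ndarray
    individuals: list[str] | None = None
    ancestries: list[str] | None = None

    _ROW_SUM_TOL = 1e-4

    def __post_init__(self) -> None:
        self.props = np.asarray(self.props, dtype=float)
        if self.props.ndim != 2 or self.props.size == 0:
            raise ValueError("props must be a nonempty 2-D array")
        if np.any(self.props < -1e-9) or np.any(self.props > 1 + 1e-9):
            raise ValueError("proportions must lie in [0, 1]")
        row_sums = self.props.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > self._ROW_SUM_TOL):
            bad = int(np.argmax(np.abs(row_sums - 1.0)))
            raise ValueError(
                f"row {bad} sums to {row_sums[bad]:.6f}, not 1 within 1e-4"
            )
        if self.individuals is not None and len(self.individuals) != self.props.shape[0]:
            raise ValueError("individuals must match number of rows")
        if self.ancestries is not None and len(self.ancestries) != self.props.shape[1]:
            raise ValueError("ancestries must match number of columns")

    @property
    def n_individuals(self) -> int:
        return self.props.shape[0]

    @property
    def n_ancestries(self) -> int:
        return self.props.shape[1]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative pairwise distances between K labelled taxa."""

    labels: list[str]
    d: np.ndarray

    _SYM_TOL = 1e-9

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.d = np.asarray(self.d, dtype=float)
        k = len(self.labels)
        if len(set(self.labels)) != k:
            raise ValueError("taxon labels must be unique")
        if self.d.shape != (k, k):
            raise ValueError(f"distance matrix must be {k}x{k}")
        if np.any(self.d < 0):
            raise ValueError("distances must be nonnegative")
        if np.any(np.abs(np.diag(self.d)) > 0):
            raise ValueError("diagonal must be zero")
        if np.max(np.abs(self.d - self.d.T)) > self._SYM_TOL:
            raise ValueError("matrix is not symmetric within 1e-9")
        self.d = (self.d + self.d.T) / 2.0  # enforce exact symmetry

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown taxon label: {label!r}") from None

    def submatrix(self, keep: list[str]) -> "DistanceMatrix":
        """Restriction of the matrix to a subset of taxa, in the given order."""
        idx = [self.index(lab) for lab in keep]
        return DistanceMatrix(list(keep), self.d[np.ix_(idx, idx)])


@dataclass(frozen=True)
class Split:
    """A weighted bipartition of the taxon set.

    ``side_a`` is the canonical side (the one containing the
    lexicographically smallest taxon); ``weight`` is the isolation index.
    """

    side_a: frozenset
    side_b: frozenset
    weight: float

    def __post_init__(self) -> None:
        if not self.side_a or not self.side_b:
            raise ValueError("both sides of a split must be nonempty")
        if self.side_a & self.side_b:
            raise ValueError("split sides must be disjoint")
        if self.weight < 0:
            raise ValueError("split weight must be nonnegative")

    @property
    def taxa(self) -> frozenset:
        return self.side_a | self.side_b

    def separates(self, x: str, y: str) -> bool:
        return (x in self.side_a) != (y in self.side_a)

    def key(self) -> frozenset:
        """Orientation-free identity of the bipartition."""
        return frozenset((self.side_a, self.side_b))


@dataclass
class SplitSystem:
    """A collection of weighted splits over a common taxon set."""

    labels: list[str]
    splits: list[Split] = field(default_factory=list)

    def __post_init__(self) -> None:
        taxa = frozenset(self.labels)
        for s in self.splits:
            if s.taxa != taxa:
                raise ValueError("split taxa do not match the system's label set")

    def __len__(self) -> int:
        return len(self.splits)

    def split_metric(self) -> DistanceMatrix:
        """Pairwise distances induced by the splits (sum of separating weights).

        For additive input metrics split decomposition is conservative: the
        induced metric reproduces the input exactly.
        """
        k = len(self.labels)
        d = np.zeros((k, k))
        for s in self.splits:
            a_idx = [i for i, lab in enumerate(self.labels) if lab in s.side_a]
            b_idx = [i for i, lab in enumerate(self.labels) if lab in s.side_b]
            for i in a_idx:
                for j in b_idx:
                    d[i, j] += s.weight
                    d[j, i] += s.weight
        return DistanceMatrix(list(self.labels), d)
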