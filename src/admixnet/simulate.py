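"""Synthetic allele-frequency generator under a known demography.

Ancestry components evolve on a rooted drift tree: each branch carries a
drift parameter ``c`` in [0, 1), and the child frequency given the parent
frequency ``p`` is drawn from the Balding–Nichols Beta distribution

    Beta( p (1 - c) / c,  (1 - p)(1 - c) / c ),

whose mean is ``p`` and whose variance is ``c p (1 - p)`` — i.e. ``c`` plays
the role of an F_ST-like divergence along the branch.  Any mean-preserving
law would serve; Balding–Nichols is the field's standard choice and is what
this module implements.  With ``c = 0`` the child copies the parent.

Admixture events create a *new* leaf whose frequency is the mixture
``alpha * p_source_a + (1 - alpha) * p_source_b``, optionally followed by
extra drift.  Creating a new leaf (rather than overwriting a source) keeps
the ground-truth parents observable, which is what the recovery tests need.

Markers are independent — the same assumption the downstream f-statistics
make.  A single integer seed drives one ``numpy`` generator stream, so every
table is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np

from .tables import FrequencyTable

__all__ = [
    "AdmixtureEvent",
    "Demography",
    "simulate_frequencies",
    "sample_counts",
    "paper_like_demography",
]


@dataclass(frozen=True)
class AdmixtureEvent:
    """A two-way admixture creating a new ancestry ``target``.

    ``alpha`` is the mixture proportion contributed by ``source_a``;
    ``post_drift`` is Balding–Nichols drift applied to the admixed
    frequency after mixing (0 means none).
    """

    source_a: str
    source_b: str
    alpha: float
    target: str
    post_drift: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not 0.0 <= self.post_drift < 1.0:
            raise ValueError("post_drift must lie in [0, 1)")
        if self.source_a == self.source_b:
            raise ValueError("admixture sources must be distinct")


@dataclass
class Demography:
    """A rooted drift tree plus a list of admixture events.

    Parameters
    ----------
    newick
        Rooted tree over ancestry labels; branch lengths are drift
        parameters ``c`` in [0, 1).  A missing branch length is treated
        as 0 (no drift).
    admixture_events
        Applied in order; each event's sources must exist by the time the
        event fires (tree leaves or targets of earlier events).
    root_freq_low, root_freq_high
        The ancestral allele frequency at the root is drawn Uniform on
        (root_freq_low, root_freq_high); the default (0.05, 0.95) keeps
        ratio denominators away from boundary degeneracies.
    """

    newick: str
    admixture_events: list[AdmixtureEvent] = field(default_factory=list)
    root_freq_low: float = 0.05
    root_freq_high: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 <= self.root_freq_low < self.root_freq_high <= 1.0:
            raise ValueError("root frequency bounds must satisfy 0 <= low < high <= 1")
        tree = self._parse_tree()
        leaf_labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(leaf_labels) == 0:
            raise ValueError("demography tree has no leaves")
        for edge in tree.preorder_edge_iter():
            c = edge.length or 0.0
            if not 0.0 <= c < 1.0:
                raise ValueError(f"drift parameter {c} outside [0, 1)")
        known = set(leaf_labels)
        if len(known) != len(leaf_labels):
            raise ValueError("tree leaf labels must be unique")
        for ev in self.admixture_events:
            if ev.source_a not in known or ev.source_b not in known:
                raise ValueError(
                    f"admixture sources ({ev.source_a}, {ev.source_b}) must exist "
                    "when the event fires"
                )
            if ev.target in known:
                raise ValueError(f"duplicate ancestry label: {ev.target!r}")
            known.add(ev.target)
        self._leaf_labels = leaf_labels

    def _parse_tree(self) -> dendropy.Tree:
        try:
            return dendropy.Tree.get(
                data=self.newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:
            raise ValueError(f"invalid demography tree: {exc}") from exc

    @property
    def labels(self) -> list[str]:
        """All ancestry labels: tree leaves first, then admixture targets."""
        return list(self._leaf_labels) + [ev.target for ev in self.admixture_events]

    # --- JSON-config (de)serialization -------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "newick": self.newick,
                "admixture_events": [asdict(ev) for ev in self.admixture_events],
                "root_freq_low": self.root_freq_low,
                "root_freq_high": self.root_freq_high,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "Demography":
        obj = json.loads(text)
        return cls(
            newick=obj["newick"],
            admixture_events=[AdmixtureEvent(**ev) for ev in obj["admixture_events"]],
            root_freq_low=obj.get("root_freq_low", 0.05),
            root_freq_high=obj.get("root_freq_high", 0.95),
        )

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")

    @classmethod
    def from_file(cls, path) -> "Demography":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _drift(p: np.ndarray, c: float, rng: np.random.Generator) -> np.ndarray:
    """One Balding–Nichols step: child frequencies with mean p, variance c p(1-p).

    Fixed frequencies (p == 0 or 1) stay fixed, as they would under drift.
    """
    if c <= 0.0:
        return p.copy()
    out = p.copy()
    interior = (p > 0.0) & (p < 1.0)
    if np.any(interior):
        pi = p[interior]
        scale = (1.0 - c) / c
        out[interior] = rng.beta(pi * scale, (1.0 - pi) * scale)
    return out


def simulate_frequencies(
    demography: Demography,
    n_markers: int,
    seed: int,
    counts=None,
) -> FrequencyTable:
    """Simulate ancestry-specific allele frequencies at independent markers.

    For each marker the root frequency is drawn from the demography's root
    law, propagated down the tree with Balding–Nichols drift on each branch,
    and mixed at admixture events.  Deterministic given ``seed``.

    Parameters
    ----------
    counts
        Optional per-ancestry effective allele counts to attach to the
        returned table (scalar, sequence, or label->count mapping); the
        frequencies themselves are population frequencies, not samples —
        use :func:`sample_counts` to add binomial sampling noise.
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    rng = np.random.default_rng(seed)
    tree = demography._parse_tree()

    root_p = rng.uniform(demography.root_freq_low, demography.root_freq_high, n_markers)
    node_freq: dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            parent_p = root_p
        else:
            parent_p = node_freq[id(node.parent_node)]
        c = node.edge.length or 0.0
        node_freq[id(node)] = _drift(parent_p, c, rng)

    columns: dict[str, np.ndarray] = {
        lf.taxon.label: node_freq[id(lf)] for lf in tree.leaf_node_iter()
    }
    for ev in demography.admixture_events:
        mixed = ev.alpha * columns[ev.source_a] + (1.0 - ev.alpha) * columns[ev.source_b]
        columns[ev.target] = _drift(mixed, ev.post_drift, rng)

    labels = demography.labels
    freqs = np.column_stack([columns[lab] for lab in labels])
    table = FrequencyTable(labels, freqs)
    if counts is not None:
        table = table.with_counts(counts)
    return table


def sample_counts(table: FrequencyTable, seed: int) -> FrequencyTable:
    """Replace each frequency with a finite-sample binomial estimate.

    Each entry p becomes Binomial(round(n_k), p) / round(n_k), emulating the
    sampling noise in ancestry-level frequency estimates.  Counts are
    rounded to the nearest integer for the draw (they may be non-integral
    effective counts) and must round to at least 2.
    """
    if table.counts is None:
        raise ValueError("table has no allele counts; attach counts first")
    n_int = np.rint(table.counts).astype(np.int64)
    if np.any(n_int < 2):
        raise ValueError("each ancestry needs an allele count of at least 2")
    rng = np.random.default_rng(seed)
    sampled = rng.binomial(n_int[None, :], table.freqs) / n_int[None, :]
    return FrequencyTable(list(table.ancestries), sampled, table.counts.copy())


#: drift tree of the bundled demo fixture: an outgroup, an African clade and
#: a West-Eurasian clade, with branch lengths acting as drift parameters.
_FIXTURE_NEWICK = (
    "(Khoisan:0.08,"
    "((NigerCongo:0.030,(NiloSaharan:0.025,Omotic:0.025):0.012):0.020,"
    "(Arabian:0.030,(LevantineCaucasian:0.020,"
    "(NorthernEuropean:0.015,SouthernEuropean:0.015):0.010):0.012):0.020)"
    ":0.030);"
)


def paper_like_demography(seed: int = 0) -> Demography:
    """The bundled demo demography: 8 tree ancestries plus one admixed leaf.

    An East-African-style admixed ancestry ("Cushitic") is formed from
    41.2% of a Nilo-Saharan-like source and 58.8% of an Arabian-like
    source, with a little extra drift afterwards — the ground truth the
    end-to-end recovery tests aim to re-estimate.  The fixture itself is
    fixed; ``seed`` is accepted for interface uniformity with the other
    generators and feeds nothing (pass it to :func:`simulate_frequencies`
    to vary the simulated markers).
    """
    del seed
    return Demography(
        newick=_FIXTURE_NEWICK,
        admixture_events=[
            AdmixtureEvent(
                source_a="NiloSaharan",
                source_b="Arabian",
                alpha=0.412,
                target="Cushitic",
                post_drift=0.005,
            )
        ],
    )
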