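"""Readers and writers for every file format the pipeline touches.

Formats
-------
* ADMIXTURE ``.P`` — whitespace-delimited M x K matrix of allele
  frequencies, one marker per row, no header.  ADMIXTURE emits no ancestry
  names, so labels come from a sidecar list (one label per line) or are
  auto-named ``Anc1..AncK``; pass them explicitly to avoid silent column
  misassignment.
* ADMIXTURE ``.Q`` — whitespace-delimited N x K matrix of per-individual
  ancestry proportions; rows sum to 1.
* TreeMix input — gzipped text, header line of population labels, then per
  marker one ``a1,a2`` allele-count pair per population.
* PHYLIP square distance matrix — taxon count on the first line, then one
  labelled row per taxon.
* Newick tree lists — one tree per line (e.g. TreeMix ``.treeout`` output).
* NEXUS Taxa + Splits blocks — SplitsTree-compatible export of weighted
  split systems.
"""

from __future__ import annotations

import gzip
import re
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

from .tables import AncestryProportions, DistanceMatrix, FrequencyTable, Split, SplitSystem

__all__ = [
    "TopologyTally",
    "read_admixture_P",
    "write_admixture_P",
    "read_admixture_Q",
    "effective_allele_counts",
    "write_treemix_input",
    "read_treemix_input",
    "read_newick_trees",
    "tally_clade",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_nexus_splits",
    "read_nexus_splits",
]


def _read_matrix(path, what: str) -> np.ndarray:
    """Whitespace-delimited numeric matrix with an explicit ragged-row check."""
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            try:
                rows.append([float(x) for x in parts])
            except ValueError as exc:
                raise ValueError(f"{what}: non-numeric value on line {lineno}") from exc
            if len(rows) > 1 and len(rows[-1]) != len(rows[0]):
                raise ValueError(
                    f"{what}: ragged row on line {lineno} "
                    f"({len(rows[-1])} fields, expected {len(rows[0])})"
                )
    if not rows:
        raise ValueError(f"{what}: file is empty")
    return np.asarray(rows, dtype=float)


def _resolve_labels(labels, k: int) -> list[str]:
    if labels is None:
        return [f"Anc{i + 1}" for i in range(k)]
    labels = list(labels)
    if len(labels) != k:
        raise ValueError(f"{len(labels)} labels supplied for {k} columns")
    return labels


def read_admixture_P(path, labels=None) -> FrequencyTable:
    """Read an ADMIXTURE ``.P`` frequency matrix (no counts attached).

    ``labels`` may be a list of K ancestry names or a path to a sidecar
    file with one name per line; by default columns are named Anc1..AncK.
    """
    mat = _read_matrix(path, "ADMIXTURE P file")
    if mat.shape[1] < 2:
        raise ValueError("ADMIXTURE P file must have at least 2 ancestry columns")
    if np.any(mat < -1e-9) or np.any(mat > 1 + 1e-9):
        raise ValueError("ADMIXTURE P file contains values outside [0, 1]")
    if isinstance(labels, (str, bytes)) or hasattr(labels, "read_text"):
        with open(labels) as fh:
            labels = [ln.strip() for ln in fh if ln.strip()]
    return FrequencyTable(_resolve_labels(labels, mat.shape[1]), np.clip(mat, 0, 1))


def write_admixture_P(table: FrequencyTable, path, precision: int = 6) -> None:
    """Write frequencies in ADMIXTURE ``.P`` layout (no header, no labels)."""
    np.savetxt(path, table.freqs, fmt=f"%.{precision}f")


def read_admixture_Q(path, labels=None, individuals=None) -> AncestryProportions:
    """Read an ADMIXTURE ``.Q`` proportions matrix."""
    mat = _read_matrix(path, "ADMIXTURE Q file")
    lab = None if labels is None else _resolve_labels(labels, mat.shape[1])
    return AncestryProportions(mat, individuals=individuals, ancestries=lab)


def effective_allele_counts(q: AncestryProportions) -> np.ndarray:
    """Per-ancestry effective total allele counts from the Q matrix.

    The column sum of ancestry proportions estimates the effective number of
    (diploid) individuals carrying that ancestry, so twice the sum estimates
    the total allele count.  Counts are left unrounded; rounding only
    happens at TreeMix export.
    """
    return 2.0 * q.props.sum(axis=0)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (not banker's)."""
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


def write_treemix_input(table: FrequencyTable, path) -> None:
    """Write a gzipped TreeMix allele-count input file.

    Per marker and ancestry the pair ``a1,a2`` with ``a1 = round(p * n_k)``
    and ``a2 = round((1 - p) * n_k)``, rounding halves away from zero.  The
    two counts are rounded independently, so a line's total may differ from
    ``round(n_k)`` by one when both sides round the same way.
    """
    if table.counts is None:
        raise ValueError("TreeMix export needs allele counts; attach counts first")
    a1 = _round_half_away(table.freqs * table.counts[None, :]).astype(np.int64)
    a2 = _round_half_away((1.0 - table.freqs) * table.counts[None, :]).astype(np.int64)
    with gzip.open(path, "wt") as fh:
        fh.write(" ".join(table.ancestries) + "\n")
        for m in range(table.n_markers):
            fh.write(" ".join(f"{a1[m, k]},{a2[m, k]}" for k in range(table.n_ancestries)) + "\n")


def read_treemix_input(path) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Read a TreeMix count file back: (labels, ref counts, alt counts)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        header = fh.readline().split()
        if not header:
            raise ValueError("TreeMix file has no header line")
        k = len(header)
        a1_rows, a2_rows = [], []
        for lineno, line in enumerate(fh, 2):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != k:
                raise ValueError(
                    f"TreeMix line {lineno}: {len(fields)} fields, expected {k}"
                )
            pairs = [f.split(",") for f in fields]
            if any(len(p) != 2 for p in pairs):
                raise ValueError(f"TreeMix line {lineno}: malformed count pair")
            a1_rows.append([int(p[0]) for p in pairs])
            a2_rows.append([int(p[1]) for p in pairs])
    return header, np.asarray(a1_rows, dtype=np.int64), np.asarray(a2_rows, dtype=np.int64)


# --- Newick tree lists and clade tallying ---------------------------------

#: TreeMix decorates migration-edge nodes; strip anything a plain rooted
#: topology does not need before parsing.
_MIGRATION_ANNOT = re.compile(r"\[[^\]]*\]")


def read_newick_trees(path, expected_labels=None) -> list[dendropy.Tree]:
    """Parse a file with one Newick tree per line (e.g. TreeMix output trees).

    Migration-edge annotations (bracketed comments) are stripped; only the
    topology matters for clade tallying.  Unknown leaf labels trigger a
    warning but the tree is kept.
    """
    trees: list[dendropy.Tree] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = _MIGRATION_ANNOT.sub("", line).strip()
            if not line:
                continue
            try:
                tree = dendropy.Tree.get(
                    data=line, schema="newick", preserve_underscores=True
                )
            except Exception as exc:
                raise ValueError(f"malformed Newick on line {lineno}: {exc}") from exc
            if expected_labels is not None:
                unknown = {lf.taxon.label for lf in tree.leaf_node_iter()} - set(
                    expected_labels
                )
                if unknown:
                    warnings.warn(
                        f"line {lineno}: unknown leaf labels {sorted(unknown)}",
                        stacklevel=2,
                    )
            trees.append(tree)
    return trees


@dataclass(frozen=True)
class TopologyTally:
    """How often a query clade appears as a subtree across a set of trees."""

    query_clade: frozenset
    n_trees: int
    n_matching: int

    @property
    def fraction(self) -> float:
        return self.n_matching / self.n_trees


def _has_clade(tree: dendropy.Tree, clade: frozenset) -> bool:
    for node in tree.preorder_node_iter():
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if leaves == clade:
            return True
    return False


def tally_clade(trees, clade) -> TopologyTally:
    """Count trees containing a node whose leaf set equals ``clade`` exactly."""
    trees = list(trees)
    if not trees:
        raise ValueError("cannot tally an empty tree list")
    clade = frozenset(clade)
    if not clade:
        raise ValueError("query clade must be nonempty")
    n_match = sum(1 for t in trees if _has_clade(t, clade))
    return TopologyTally(clade, len(trees), n_match)


# --- PHYLIP distance matrices ---------------------------------------------

_ASYM_TOL = 1e-6


def read_distance_matrix(path) -> DistanceMatrix:
    """Read a PHYLIP-style square distance matrix with taxon labels.

    Asymmetric entries are symmetrized by averaging; asymmetry beyond 1e-6
    triggers a warning.
    """
    with open(path) as fh:
        lines = [ln for ln in (l.rstrip("\n") for l in fh) if ln.strip()]
    if not lines:
        raise ValueError("distance matrix file is empty")
    try:
        k = int(lines[0].split()[0])
    except ValueError as exc:
        raise ValueError("first line must give the number of taxa") from exc
    if len(lines) - 1 != k:
        raise ValueError(f"expected {k} matrix rows, found {len(lines) - 1}")
    labels, rows = [], []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != k + 1:
            raise ValueError(
                f"row {parts[0] if parts else '?'}: expected {k} distances, "
                f"found {len(parts) - 1}"
            )
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    d = np.asarray(rows, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    asym = np.max(np.abs(d - d.T))
    if asym > _ASYM_TOL:
        warnings.warn(
            f"distance matrix asymmetric by up to {asym:.3g}; symmetrizing by averaging",
            stacklevel=2,
        )
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, d)


def write_distance_matrix(dm: DistanceMatrix, path, precision: int = 9) -> None:
    with open(path, "w") as fh:
        fh.write(f"{dm.n_taxa}\n")
        for i, lab in enumerate(dm.labels):
            row = " ".join(f"{x:.{precision}f}" for x in dm.d[i])
            fh.write(f"{lab} {row}\n")


# --- NEXUS splits blocks ---------------------------------------------------


def write_nexus_splits(splits: SplitSystem, path) -> None:
    """Write a SplitsTree-compatible NEXUS file with Taxa and Splits blocks.

    Each split is encoded by the 1-based taxon indices of the side
    containing taxon 1, with its weight.
    """
    labels = splits.labels
    ntax = len(labels)
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN Taxa;\n")
        fh.write(f"DIMENSIONS ntax={ntax};\nTAXLABELS\n")
        for i, lab in enumerate(labels, 1):
            fh.write(f"[{i}] '{lab}'\n")
        fh.write(";\nEND;\n\nBEGIN Splits;\n")
        fh.write(f"DIMENSIONS ntax={ntax} nsplits={len(splits.splits)};\n")
        fh.write("FORMAT labels=no weights=yes confidences=no intervals=no;\n")
        fh.write("MATRIX\n")
        for j, s in enumerate(splits.splits, 1):
            side = s.side_a if labels[0] in s.side_a else s.side_b
            idx = sorted(labels.index(lab) + 1 for lab in side)
            fh.write(f"[{j}, size={len(idx)}]\t{s.weight:.12g}\t")
            fh.write(" ".join(str(i) for i in idx) + ",\n")
        fh.write(";\nEND;\n")


def read_nexus_splits(path) -> SplitSystem:
    """Read back a NEXUS Splits block written by :func:`write_nexus_splits`."""
    with open(path) as fh:
        text = fh.read()
    if not text.lstrip().upper().startswith("#NEXUS"):
        raise ValueError("not a NEXUS file")
    tax_match = re.search(r"TAXLABELS\s*(.*?);", text, re.S | re.I)
    if not tax_match:
        raise ValueError("no TAXLABELS found")
    labels = re.findall(r"\[\d+\]\s*'([^']*)'", tax_match.group(1))
    if not labels:
        raise ValueError("no taxon labels parsed")
    splits_match = re.search(r"BEGIN Splits;.*?MATRIX\s*(.*?);\s*END;", text, re.S | re.I)
    if not splits_match:
        raise ValueError("no Splits block found")
    all_taxa = frozenset(labels)
    splits: list[Split] = []
    for line in splits_match.group(1).strip().splitlines():
        line = line.strip().rstrip(",")
        if not line:
            continue
        m = re.match(r"\[[^\]]*\]\s+(\S+)\s+(.*)", line)
        if not m:
            raise ValueError(f"malformed splits row: {line!r}")
        weight = float(m.group(1))
        side = frozenset(labels[int(i) - 1] for i in m.group(2).split())
        splits.append(Split(side, all_taxa - side, weight))
    return SplitSystem(labels, splits)
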