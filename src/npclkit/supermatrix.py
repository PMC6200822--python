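"""Supermatrix concatenation, neighbor-joining trees with bootstrap support,
and PCR validation-matrix summaries.

The concatenated matrix is partitioned by locus (RAxML-style partition
table); taxa missing a locus are padded with gaps. Tree building is
Saitou-Nei neighbor joining with a documented deterministic tie-break
(lowest-index pair on equal Q); on additive distance matrices NJ recovers
the generating tree exactly. Maximum-likelihood inference is deliberately
delegated: the module writes a RAxML-ready relaxed PHYLIP alignment plus
partition file instead of running it.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    FAILURE,
    NOT_ATTEMPTED,
    SUCCESS,
    SequenceSet,
    ValidationMatrix,
    write_phylip,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# concatenation
# ---------------------------------------------------------------------------

@dataclass
class SuperMatrix:
    taxa: list[str]
    partitions: list[tuple[str, tuple[int, int]]]  # (locus_id, 0-based half-open span)
    rows: dict[str, str]

    @property
    def n_columns(self) -> int:
        return sum(e - s for _, (s, e) in self.partitions)

    def missing_fraction(self, taxon: str) -> float:
        row = self.rows[taxon]
        return row.count("-") / len(row)

    def as_sequence_set(self) -> SequenceSet:
        return SequenceSet(records=[(t, self.rows[t]) for t in self.taxa])

    def gap_stripped_length(self) -> int:
        """Number of columns containing no gaps in any taxon."""
        mat = np.frombuffer(
            "".join(self.rows[t] for t in self.taxa).encode("ascii"), dtype="S1"
        ).reshape(len(self.taxa), self.n_columns)
        return int((mat != b"-").all(axis=0).sum())


def concatenate(loci: list[tuple[str, SequenceSet]]) -> SuperMatrix:
    """Concatenate per-locus alignments into a partitioned supermatrix.

    Taxa are the union over loci in order of first appearance; a taxon
    missing a locus is padded with '-'. A duplicate taxon id within one
    locus is an error.
    """
    loci = [
        (lid, aln if isinstance(aln, SequenceSet) else list(aln)) for lid, aln in loci
    ]

    def _records(aln):
        return aln.records if isinstance(aln, SequenceSet) else aln

    taxa: list[str] = []
    for locus_id, aln in loci:
        seen: set[str] = set()
        for tid, _ in _records(aln):
            if tid in seen:
                raise ValueError(f"locus {locus_id}: duplicate taxon id {tid!r}")
            seen.add(tid)
            if tid not in taxa:
                taxa.append(tid)
    partitions: list[tuple[str, tuple[int, int]]] = []
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    offset = 0
    for locus_id, aln in loci:
        lengths = {len(s) for _, s in _records(aln)}
        if len(lengths) != 1:
            raise ValueError(f"locus {locus_id}: rows are not equal-length")
        L = lengths.pop()
        partitions.append((locus_id, (offset, offset + L)))
        present = dict(_records(aln))
        for t in taxa:
            chunks[t].append(present.get(t, "-" * L))
        offset += L
    rows = {t: "".join(chunks[t]) for t in taxa}
    return SuperMatrix(taxa=taxa, partitions=partitions, rows=rows)


def split_by_partition(sm: SuperMatrix) -> list[tuple[str, SequenceSet]]:
    """Invert :func:`concatenate`: recover each locus alignment.

    Taxa whose block is entirely gap (absent from the locus) are dropped.
    """
    out = []
    for locus_id, (s, e) in sm.partitions:
        records = []
        for t in sm.taxa:
            block = sm.rows[t][s:e]
            if block.count("-") == len(block):
                continue
            records.append((t, block))
        out.append((locus_id, SequenceSet(records=records)))
    return out


def write_raxml_inputs(sm: SuperMatrix, phylip_path, partition_path) -> None:
    """Write the relaxed PHYLIP alignment and RAxML partition file."""
    write_phylip(sm.as_sequence_set(), phylip_path)
    with open(partition_path, "w") as fh:
        for locus_id, (s, e) in sm.partitions:
            fh.write(f"DNA, {locus_id} = {s + 1}-{e}\n")


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("label", "children", "lengths")

    def __init__(self, label=None):
        self.label = label
        self.children: list[_Node] = []
        self.lengths: list[float] = []

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(
            f"{child.newick()}:{length:.10f}"
            for child, length in zip(self.children, self.lengths)
        )
        return f"({inner})"


def nj_tree(dist: np.ndarray, labels: list[str]) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted Newick string.

    Requires a symmetric zero-diagonal matrix over >= 3 taxa. Deterministic:
    on equal Q the lowest-index pair is joined. Branch lengths may be
    negative on non-additive inputs (not clamped, preserving additive-case
    exactness).
    """
    d = np.array(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix shape must match the label count")
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")

    nodes: list[_Node] = [_Node(lbl) for lbl in labels]
    active = list(range(n))
    D = d.copy()

    while len(active) > 3:
        m = len(active)
        sums = {i: sum(D[i][j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (m - 2) * D[i][j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        dij = D[i][j]
        li = 0.5 * dij + (sums[i] - sums[j]) / (2.0 * (m - 2))
        lj = dij - li
        parent = _Node()
        parent.children = [nodes[i], nodes[j]]
        parent.lengths = [li, lj]
        # reuse slot i for the new node
        new_row = np.zeros(D.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i][k] + D[j][k] - dij)
        D[i, :] = new_row
        D[:, i] = new_row
        D[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    i, j, k = active
    # three-point formulas for the final star
    li = 0.5 * (D[i][j] + D[i][k] - D[j][k])
    lj = 0.5 * (D[i][j] + D[j][k] - D[i][k])
    lk = 0.5 * (D[i][k] + D[j][k] - D[i][j])
    root = _Node()
    root.children = [nodes[i], nodes[j], nodes[k]]
    root.lengths = [li, lj, lk]
    return root.newick() + ";"


def distance_matrix(alignment: SequenceSet, model: str = "p") -> tuple[np.ndarray, list[str]]:
    """Pairwise distance matrix over an alignment (pairwise deletion)."""
    from .distances import pairwise_distance

    labels = alignment.ids
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_distance(
                alignment.records[i][1], alignment.records[j][1], model
            )
    return d, labels


def tree_splits(newick: str, taxa: list[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, each given as the side
    not containing the first taxon."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.encode_bipartitions()
    ref = taxa[0]
    full = frozenset(taxa)
    splits: set[frozenset[str]] = set()
    for edge in tree.preorder_edge_iter():
        if edge.bipartition is None or edge.head_node is None:
            continue
        side = frozenset(
            leaf.taxon.label for leaf in edge.head_node.leaf_iter()
        )
        if len(side) <= 1 or len(side) >= len(taxa) - 1:
            continue
        if ref in side:
            side = full - side
        splits.add(side)
    return splits


@dataclass
class SupportedTree:
    newick: str
    support: dict[frozenset[str], float]  # split -> percent of replicates
    strong_threshold: float = 70.0

    def strong_splits(self) -> list[frozenset[str]]:
        return [s for s, v in self.support.items() if v >= self.strong_threshold]


def bootstrap_support(
    sm: SuperMatrix,
    reps: int = 1000,
    seed: int | None = None,
    model: str = "p",
) -> SupportedTree:
    """Column-bootstrap support for the NJ tree of a supermatrix.

    Each replicate resamples supermatrix columns with replacement, rebuilds
    the NJ tree, and support for each split of the full-data tree is the
    percentage of replicate trees containing it. Splits at or above 70% are
    flagged strong (metadata, not a filter).
    """
    if reps < 1:
        raise ValueError("bootstrap requires at least 1 replicate")
    aln = sm.as_sequence_set()
    d, labels = distance_matrix(aln, model)
    main_newick = nj_tree(d, labels)
    main_splits = tree_splits(main_newick, labels)

    mat = np.frombuffer(
        "".join(sm.rows[t] for t in sm.taxa).encode("ascii"), dtype="S1"
    ).reshape(len(sm.taxa), sm.n_columns)
    rng = np.random.default_rng(seed)
    counts = {s: 0 for s in main_splits}
    for _ in range(reps):
        cols = rng.integers(0, mat.shape[1], size=mat.shape[1])
        resampled = mat[:, cols]
        records = [
            (t, resampled[i].tobytes().decode("ascii")) for i, t in enumerate(sm.taxa)
        ]
        rd, rlabels = distance_matrix(SequenceSet(records=records), model)
        rsplits = tree_splits(nj_tree(rd, rlabels), rlabels)
        for s in main_splits:
            if s in rsplits:
                counts[s] += 1
    support = {s: 100.0 * c / reps for s, c in counts.items()}
    return SupportedTree(newick=main_newick, support=support)


# ---------------------------------------------------------------------------
# validation-matrix summary
# ---------------------------------------------------------------------------

@dataclass
class MarkerPanel:
    overall_psr: float
    per_marker_psr: dict[str, float]
    per_order_psr: dict[str, float]
    universal: list[str]
    excluded: list[str]  # markers with no attempted reactions
    threshold: float


def summarize_validation(vm: ValidationMatrix, threshold: float = 0.80) -> MarkerPanel:
    """PCR success rates from a validation matrix.

    Overall PSR = successes / attempted reactions (not-attempted cells are
    excluded from the denominator); per-marker and per-order PSR likewise.
    The universal panel keeps markers with PSR >= threshold. Markers with no
    attempted reactions have undefined PSR and are excluded with a warning.
    """
    attempted = vm.cells != NOT_ATTEMPTED
    successes = vm.cells == SUCCESS
    total_attempted = int(attempted.sum())
    if total_attempted == 0:
        raise ValueError("validation matrix has no attempted reactions")
    overall = successes.sum() / total_attempted

    per_marker: dict[str, float] = {}
    excluded: list[str] = []
    for idx, marker in enumerate(vm.markers):
        n_att = int(attempted[idx].sum())
        if n_att == 0:
            logger.warning("marker %s: no attempted reactions; PSR undefined", marker)
            excluded.append(marker)
            continue
        per_marker[marker] = successes[idx].sum() / n_att

    per_order: dict[str, float] = {}
    orders = [order for _, order in vm.taxa]
    for order in dict.fromkeys(orders):
        cols = [i for i, o in enumerate(orders) if o == order]
        n_att = int(attempted[:, cols].sum())
        if n_att:
            per_order[order] = successes[:, cols].sum() / n_att

    universal = [m for m, psr in per_marker.items() if psr >= threshold]
    return MarkerPanel(
        overall_psr=float(overall),
        per_marker_psr=per_marker,
        per_order_psr=per_order,
        universal=universal,
        excluded=excluded,
        threshold=threshold,
    )


def panel_table(panel: MarkerPanel, chromosomes: dict[str, str] | None = None) -> pd.DataFrame:
    rows = [
        {
            "marker": m,
            "chromosome": (chromosomes or {}).get(m, ""),
            "psr": round(psr, 6),
            "universal": m in set(panel.universal),
        }
        for m, psr in panel.per_marker_psr.items()
    ]
    return pd.DataFrame(rows)
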