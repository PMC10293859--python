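"""Patristic-distance resampling test for in-situ gene duplication, plus the
alignment-column QC filter applied before tree building.

Tandem (dual) TniQ-TnsD gene pairs may arise either by repeated independent
in-situ duplication (each pair then sits close together on the gene tree) or
by a single ancestral duplication (pair members fall into two deep clades).
The test compares the within-pair patristic distances against a null of
random leaf couples drawn from the non-pair leaves, via a two-sample t-test.
A significantly smaller observed mean (negative t statistic) supports
independent in-situ duplications.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from scipy import stats

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class LeafPair:
    leaf_a: str
    leaf_b: str

    def __post_init__(self) -> None:
        if self.leaf_a == self.leaf_b:
            raise ValueError(f"pair members must differ (got {self.leaf_a!r} twice)")


@dataclass
class DupTestResult:
    observed_distances: list[float]
    null_distances: list[float]
    n_null: int
    t_statistic: float
    p_value: float
    seed: int

    @property
    def pairs_closer(self) -> bool:
        """True when observed pairs are on average closer than random couples."""
        return self.t_statistic < 0


def _as_tree(tree: dendropy.Tree | str) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=tree, schema="newick")


class _TreeIndex:
    """Array view of a tree for fast batched patristic distances.

    Distances use root-path depths: d(a, b) = depth(a) + depth(b) -
    2 * depth(mrca), with the MRCA depth found as the deepest node on both
    root paths.
    """

    def __init__(self, tree: dendropy.Tree):
        nodes = list(tree.preorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        n = len(nodes)
        depth = np.zeros(n)
        self.ancestors = np.zeros((n, n), dtype=bool)
        self.leaf_index: dict[str, int] = {}
        for i, node in enumerate(nodes):
            elen = node.edge.length
            if node.parent_node is None:
                elen = elen or 0.0
            elif elen is None:
                raise ValueError("missing branch length in tree")
            if elen < 0:
                raise ValueError(f"negative branch length {elen}")
            if node.parent_node is not None:
                p = index[id(node.parent_node)]
                depth[i] = depth[p] + elen
                self.ancestors[i] = self.ancestors[p]
            else:
                depth[i] = elen
            self.ancestors[i, i] = True
            if node.is_leaf():
                label = node.taxon.label if node.taxon else None
                if label is None:
                    raise ValueError("unlabeled leaf in tree")
                self.leaf_index[label] = i
        self.depth = depth

    def distances(self, a_idx: np.ndarray, b_idx: np.ndarray) -> np.ndarray:
        shared = self.ancestors[a_idx] & self.ancestors[b_idx]
        mrca_depth = np.where(shared, self.depth[None, :], -np.inf).max(axis=1)
        return self.depth[a_idx] + self.depth[b_idx] - 2.0 * mrca_depth

    def leaf_ids(self, labels: Iterable[str]) -> np.ndarray:
        out = []
        for lab in labels:
            if lab not in self.leaf_index:
                raise KeyError(f"unknown leaf {lab!r}")
            out.append(self.leaf_index[lab])
        return np.asarray(out, dtype=np.int64)


def patristic_distance(
    tree: dendropy.Tree | str, leaf_a: str, leaf_b: str
) -> float:
    """Sum of branch lengths on the unique path between two leaves."""
    idx = _TreeIndex(_as_tree(tree))
    if leaf_a == leaf_b:
        idx.leaf_ids([leaf_a])  # still validates the label
        return 0.0
    a, b = idx.leaf_ids([leaf_a, leaf_b])
    return float(idx.distances(np.array([a]), np.array([b]))[0])


def dual_pair_duplication_test(
    tree: dendropy.Tree | str,
    pairs: Sequence[LeafPair | tuple[str, str]],
    n_null: int = 1000,
    seed: int = 0,
    equal_var: bool = False,
) -> DupTestResult:
    """Compare within-pair distances to ``n_null`` random couple distances.

    Null couples are drawn uniformly from the leaves outside the pair-member
    set, two distinct leaves per couple (couples may repeat across draws).
    The two-sample t-test is Welch's by default; set ``equal_var=True`` for
    the pooled-variance variant.  The p-value is two-sided; directionality
    (pairs closer) is carried by the sign of the t statistic.
    """
    pairs = [p if isinstance(p, LeafPair) else LeafPair(*p) for p in pairs]
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    idx = _TreeIndex(_as_tree(tree))
    pair_leaves = {p.leaf_a for p in pairs} | {p.leaf_b for p in pairs}
    non_pair = sorted(set(idx.leaf_index) - pair_leaves)
    if len(non_pair) < 2:
        raise ValueError("too few non-pair leaves to sample a null")

    a_idx = idx.leaf_ids([p.leaf_a for p in pairs])
    b_idx = idx.leaf_ids([p.leaf_b for p in pairs])
    observed = idx.distances(a_idx, b_idx)

    rng = np.random.default_rng(seed)
    m = len(non_pair)
    na = rng.integers(0, m, size=n_null)
    nb = rng.integers(0, m - 1, size=n_null)
    nb = nb + (nb >= na)  # distinct members within a couple
    non_pair_idx = idx.leaf_ids(non_pair)
    null = idx.distances(non_pair_idx[na], non_pair_idx[nb])

    t_stat, p_value = stats.ttest_ind(observed, null, equal_var=equal_var)
    return DupTestResult(
        observed_distances=observed.tolist(),
        null_distances=null.tolist(),
        n_null=n_null,
        t_statistic=float(t_stat),
        p_value=float(p_value),
        seed=seed,
    )


def motif_gap_filter(
    alignment: Mapping[str, str] | Sequence[tuple[str, str]],
    anchor_columns: Sequence[int],
) -> list[str]:
    """Retain sequences with a residue (non-gap) at every anchor column.

    Used to discard sequences whose conserved motif (e.g. the first CxxC of
    the TniQ zinc finger, or the Walker A/B of TnsC) is not aligned at the
    expected columns.  ``alignment`` is a rectangular id -> row mapping or a
    sequence of (id, row) tuples; columns are 0-based.
    """
    items = list(alignment.items()) if isinstance(alignment, Mapping) else list(alignment)
    if not items:
        return []
    width = len(items[0][1])
    if any(len(row) != width for _, row in items):
        raise ValueError("alignment is not rectangular")
    for col in anchor_columns:
        if not 0 <= col < width:
            raise IndexError(f"anchor column {col} out of range (width {width})")
    return [
        sid
        for sid, row in items
        if all(row[col] not in GAP_CHARS for col in anchor_columns)
    ]
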