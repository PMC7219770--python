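"""Tree comparison and phylogenetic-signal diagnostics.

Provides newick I/O (via dendropy), percent bipartition overlap between
unrooted trees, minimum-change (Fitch) parsimony lengths for binary
characters, the retention index with a leaf-label permutation null, and
a distance-saturation profile against a reference tree.

Parsimony lengths are computed with a two-state Sankoff dynamic program
(unit change cost), which equals the Fitch length on bifurcating trees
and stays exact on polytomies; '?' cells are treated as fully ambiguous
{0, 1} and are excluded from the counts that define the maximum and
minimum possible steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from codonpairing.parsimony_matrix import MISSING, CharacterMatrix
from codonpairing.profiles_af import DistanceMatrix

# --- newick I/O -------------------------------------------------------------


def read_tree(path: str | Path) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    tree.is_rooted = False
    return tree


def tree_from_newick(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick")


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


# --- bipartition overlap ----------------------------------------------------


@dataclass
class EdgeOverlap:
    """Shared non-trivial bipartitions between two unrooted trees.

    Directional percentages are NaN when the corresponding tree has no
    non-trivial bipartition (e.g. a star); ``mean_pct`` averages the
    defined directions.
    """

    shared_bipartitions: int
    n_source: int
    n_reference: int
    pct_source_in_ref: float
    pct_ref_in_source: float
    mean_pct: float


def _nontrivial_bipartitions(tree: dendropy.Tree, leaves: set[str]) -> set[frozenset]:
    """Bipartitions as frozensets of the side not containing the anchor leaf."""
    anchor = min(leaves)
    n = len(leaves)
    out: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = frozenset(leaves - side)
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def _restricted_copy(tree: dendropy.Tree, keep: set[str]) -> dendropy.Tree:
    clone = tree.clone(depth=1)
    clone.retain_taxa_with_labels(sorted(keep))
    clone.is_rooted = False
    # collapse a degree-2 basal node left by a rooted representation
    clone.deroot()
    return clone


def edge_overlap(source: dendropy.Tree, reference: dendropy.Tree) -> EdgeOverlap:
    """Percent of non-trivial bipartitions shared between two trees.

    Both trees are pruned to their shared leaf set first; polytomies
    contribute only the bipartitions they actually resolve.
    """
    shared_leaves = leaf_labels(source) & leaf_labels(reference)
    if len(shared_leaves) < 4:
        raise ValueError(f"need >= 4 shared leaves, got {len(shared_leaves)}")
    bp_s = _nontrivial_bipartitions(_restricted_copy(source, shared_leaves), shared_leaves)
    bp_r = _nontrivial_bipartitions(_restricted_copy(reference, shared_leaves), shared_leaves)
    shared = len(bp_s & bp_r)
    pct_s = 100.0 * shared / len(bp_s) if bp_s else float("nan")
    pct_r = 100.0 * shared / len(bp_r) if bp_r else float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = float(np.nanmean([pct_s, pct_r]))
    return EdgeOverlap(
        shared_bipartitions=shared,
        n_source=len(bp_s),
        n_reference=len(bp_r),
        pct_source_in_ref=pct_s,
        pct_ref_in_source=pct_r,
        mean_pct=mean,
    )


def average_edge_overlap(
    sources: Iterable[dendropy.Tree], reference: dendropy.Tree
) -> float:
    """Mean of ``mean_pct`` across several equally good source trees."""
    pcts = [edge_overlap(s, reference).mean_pct for s in sources]
    if not pcts:
        raise ValueError("no source trees given")
    return float(np.mean(pcts))


# --- parsimony length -------------------------------------------------------


class _TreeDP:
    """Postorder scaffold for vectorized two-state parsimony on one tree."""

    def __init__(self, tree: dendropy.Tree):
        nodes = list(tree.postorder_node_iter())
        self.index = {id(n): i for i, n in enumerate(nodes)}
        self.children = [
            [self.index[id(c)] for c in n.child_nodes()] for n in nodes
        ]
        self.leaf_label = [
            n.taxon.label if n.is_leaf() else None for n in nodes
        ]
        self.n_nodes = len(nodes)

    def lengths(self, states: dict[str, np.ndarray], ncols: int) -> np.ndarray:
        """Min steps per column; ``states[label]`` is an int array over
        columns with values 0, 1 or MISSING."""
        big = np.float64(1e9)
        cost = np.zeros((self.n_nodes, 2, ncols))
        for i in range(self.n_nodes):
            kids = self.children[i]
            if not kids:
                label = self.leaf_label[i]
                st = states.get(label)
                if st is None:
                    continue  # unscored leaf: cost 0 for both states
                c = cost[i]
                c[0][st == 1] = big
                c[1][st == 0] = big
            else:
                acc0 = np.zeros(ncols)
                acc1 = np.zeros(ncols)
                for k in kids:
                    c0, c1 = cost[k]
                    acc0 += np.minimum(c0, c1 + 1)
                    acc1 += np.minimum(c1, c0 + 1)
                cost[i, 0] = acc0
                cost[i, 1] = acc1
        root = cost[self.n_nodes - 1]
        return np.minimum(root[0], root[1])


def fitch_length(tree: dendropy.Tree, column: dict[str, int]) -> int:
    """Minimum state changes for one binary character on the tree.

    ``column`` maps leaf labels to 0, 1 or :data:`MISSING` ('?', treated
    as the ambiguous set {0, 1}); leaves absent from ``column`` are also
    ambiguous.  An all-ambiguous column costs 0 steps.
    """
    dp = _TreeDP(tree)
    states = {
        label: np.array([state], dtype=np.int8)
        for label, state in column.items()
    }
    return int(dp.lengths(states, 1)[0])


# --- retention index --------------------------------------------------------


@dataclass
class RIReport:
    """Retention indices of a character matrix on a tree.

    ``per_character`` holds one RI per column (NaN where undefined, i.e.
    the character cannot exhibit homoplasy); ``ensemble_ri`` pools steps
    across characters; ``mean_ri`` averages defined per-character values.
    """

    per_character: np.ndarray
    ensemble_ri: float
    mean_ri: float
    n_skipped: int


def _ri_components(m: CharacterMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(g, m_min) per column from scored-taxon state counts."""
    ones = (m.cells == 1).sum(axis=0)
    zeros = (m.cells == 0).sum(axis=0)
    g = np.minimum(ones, zeros).astype(float)
    m_min = ((ones > 0) & (zeros > 0)).astype(float)
    return g, m_min


def _matrix_states(m: CharacterMatrix) -> dict[str, np.ndarray]:
    return {
        sid: m.cells[i, :].astype(np.int8)
        for i, sid in enumerate(m.species_ids)
    }


def retention_index(tree: dendropy.Tree, m: CharacterMatrix) -> RIReport:
    """Retention index RI = (g - s) / (g - m) per character and pooled.

    s is the parsimony length on ``tree``, m the minimum possible steps
    (1 when both states occur, else 0) and g the maximum (min of the two
    state counts among scored taxa, attained on a star tree).  Characters
    with g == m have no room for homoplasy and are skipped.
    """
    if m.n_characters == 0:
        raise ValueError("empty character matrix")
    missing = set(m.species_ids) - leaf_labels(tree)
    if missing:
        raise ValueError(f"species not on tree: {sorted(missing)}")
    dp = _TreeDP(tree)
    s = dp.lengths(_matrix_states(m), m.n_characters)
    g, m_min = _ri_components(m)
    defined = g > m_min
    per = np.full(m.n_characters, np.nan)
    per[defined] = (g[defined] - s[defined]) / (g[defined] - m_min[defined])
    denom = g.sum() - m_min.sum()
    ensemble = float((g.sum() - s.sum()) / denom) if denom > 0 else float("nan")
    mean = float(np.nanmean(per)) if defined.any() else float("nan")
    return RIReport(
        per_character=per,
        ensemble_ri=ensemble,
        mean_ri=mean,
        n_skipped=int((~defined).sum()),
    )


@dataclass
class PermutationResult:
    observed_mean_ri: float
    null_mean_ri: np.ndarray
    p_value: float
    n_perm: int
    seed: int


def ri_permutation_test(
    tree: dendropy.Tree,
    m: CharacterMatrix,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation null for the mean retention index.

    Each permutation shuffles species placement on the fixed reference
    topology (equivalently, permutes matrix rows among the species) and
    recomputes the mean per-character RI.  The empirical p-value uses the
    add-one estimator p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = retention_index(tree, m)
    dp = _TreeDP(tree)
    g, m_min = _ri_components(m)
    defined = g > m_min
    rng = np.random.default_rng(seed)
    ids = list(m.species_ids)
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(len(ids))
        states = {
            ids[perm[i]]: m.cells[i, :].astype(np.int8)
            for i in range(len(ids))
        }
        s = dp.lengths(states, m.n_characters)
        ri = (g[defined] - s[defined]) / (g[defined] - m_min[defined])
        null[k] = ri.mean()
    p = (1 + int((null >= observed.mean_ri).sum())) / (1 + n_perm)
    return PermutationResult(
        observed_mean_ri=observed.mean_ri,
        null_mean_ri=null,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
    )


# --- saturation -------------------------------------------------------------


@dataclass
class SaturationResult:
    """Computed vs. taxonomic distance for every species pair.

    ``table`` has one row per pair with the topological path length on
    the reference tree (edge count) and the profile distance; pairs at
    the distance ceiling 1.0 are fully saturated.
    """

    table: pd.DataFrame
    saturation_fraction: float
    excluded_species: list[str]


def saturation_profile(dm: DistanceMatrix, reference: dendropy.Tree) -> SaturationResult:
    """Pair computed distances with topological distances on the reference."""
    ref_leaves = leaf_labels(reference)
    included = [s for s in dm.ids if s in ref_leaves]
    excluded = [s for s in dm.ids if s not in ref_leaves]
    if excluded:
        warnings.warn(f"species absent from reference tree: {excluded}")
    if len(included) < 2:
        raise ValueError("need >= 2 species present on the reference tree")
    ref = _restricted_copy(reference, set(included))
    pdm = ref.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in pdm.taxon_iter()}
    rows = []
    for i, a in enumerate(included):
        for b in included[i + 1 :]:
            rows.append(
                {
                    "species_a": a,
                    "species_b": b,
                    "taxonomic_distance": pdm.path_edge_count(taxa[a], taxa[b]),
                    "computed_distance": dm[a, b],
                }
            )
    table = pd.DataFrame(rows)
    sat = float((table["computed_distance"] >= 1.0).mean())
    return SaturationResult(table=table, saturation_fraction=sat, excluded_species=excluded)
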