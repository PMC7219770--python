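"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately take the *opposite* algorithmic route from the
implementation: pairing is found by enumerating every contiguous window
and counting symbol occurrences inside it; parsimony length is found by
exhaustive enumeration of internal-node state assignments.
"""

from __future__ import annotations

import itertools
from collections import Counter

ACGT = set("ACGT")


def _pairable(codon, code):
    return set(codon) <= ACGT and codon not in code.stop_codons


def brute_force_pairing(codons, mode, w, code):
    """Union over all contiguous w-codon windows of within-window pairings."""
    n = len(codons)
    out = set()
    starts = range(n - w + 1) if n >= w else [0]
    for start in starts:
        window = [c for c in codons[start : start + w] if _pairable(c, code)]
        if mode == "identical":
            counts = Counter(window)
            out.update(c for c, k in counts.items() if k >= 2)
        else:
            by_residue = {}
            for c in window:
                by_residue.setdefault(code.codon_to_aa[c], []).append(c)
            for aa, group in by_residue.items():
                if mode == "cotrna":
                    if len(set(group)) >= 2:
                        out.add(aa)
                else:  # combined
                    if len(group) >= 2:
                        out.add(aa)
    return out


def brute_force_fitch(tree, column):
    """Min changes by exhaustive enumeration of free node states.

    ``column`` maps leaf labels to 0, 1 or -1 ('?'); '?' leaves and all
    internal nodes are free.  Exponential — tiny trees only.
    """
    nodes = list(tree.postorder_node_iter())
    free = []
    fixed = {}
    for node in nodes:
        if node.is_leaf():
            state = column.get(node.taxon.label, -1)
            if state in (0, 1):
                fixed[id(node)] = state
            else:
                free.append(node)
        else:
            free.append(node)
    best = None
    for assignment in itertools.product((0, 1), repeat=len(free)):
        states = dict(fixed)
        for node, st in zip(free, assignment):
            states[id(node)] = st
        changes = 0
        for node in nodes:
            if node.parent_node is not None:
                changes += states[id(node)] != states[id(node.parent_node)]
        if best is None or changes < best:
            best = changes
    return best


def random_codon_gene(rng, length, code):
    """Random sense-codon list of the given length."""
    sense = sorted(code.sense_codons)
    return [sense[i] for i in rng.integers(0, len(sense), size=length)]
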