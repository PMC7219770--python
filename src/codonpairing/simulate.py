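"""Synthetic datasets with phylogenetically conserved pairing signal.

The generator evolves binary pairing states — one per (ortholog, symbol)
character — along a known tree under a symmetric two-state Markov chain
(flip probability ``1 - exp(-flip_rate * branch_length)`` per edge), then
*realizes* every species' states as coding sequences whose pairing sets,
under the configured mode and window, equal the simulated states exactly.
The per-edge flip probability is the exact two-state continuous-time
transition probability ``(1 - exp(-2 * flip_rate * t)) / 2``, so states
decorrelate toward 50% disagreement as path length grows.

Realization uses block construction: each target symbol becomes a pair of
adjacent codons that pairs by design, and filler codons rotate through
``w`` distinct codon/residue families so that no unintended pairing can
arise within the window.  Biological realism of the filler sequence is
explicitly not a goal; exact invertibility is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from codonpairing.pairing_core import PairingMode
from codonpairing.seqio_genetics import (
    GeneRecord,
    GeneticCode,
    SpeciesGeneSet,
    write_species_fasta,
)


def random_tree(
    n_leaves: int,
    seed: int,
    bl_low: float = 0.1,
    bl_high: float = 1.0,
) -> dendropy.Tree:
    """Random binary tree by sequential pair joining, U(bl_low, bl_high)
    branch lengths.  Leaf labels are ``sp01``, ``sp02``, ..."""
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    rng = np.random.default_rng(seed)
    labels = [f"sp{i:02d}" for i in range(1, n_leaves + 1)]
    taxa = dendropy.TaxonNamespace(labels)
    nodes = []
    for label in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = dendropy.Node()
        parent.add_child(left)
        parent.add_child(right)
        left.edge.length = float(rng.uniform(bl_low, bl_high))
        right.edge.length = float(rng.uniform(bl_low, bl_high))
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[0]
    return tree


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``flip_rate`` scales the per-unit-branch-length probability of a
    pairing state flipping; with the default branch lengths (~0.1-1.0)
    the default rate yields moderate divergence well below saturation.
    """

    tree: dendropy.Tree
    n_orthologs: int = 200
    symbols_per_ortholog: int = 8
    root_pairing_prob: float = 0.5
    flip_rate: float = 0.1
    window: int = 9
    mode: PairingMode = PairingMode.COMBINED
    gene_length: int = 300  # codons
    missingness: float = 0.0
    seed: int = 0
    table_id: int = 1

    def __post_init__(self) -> None:
        for name in ("root_pairing_prob", "missingness"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_orthologs < 1:
            raise ValueError("n_orthologs must be >= 1")
        self.mode = PairingMode(self.mode)


@dataclass
class ProfileStateTable:
    """Simulated truth: per species, per ortholog, the set of symbols
    that pair ('on' states); orthologs absent from a species are listed
    nowhere and realize as missing genes."""

    species_ids: list[str]
    ortholog_symbols: dict[str, tuple[str, ...]]
    states: dict[str, dict[str, frozenset[str]]]  # species -> og -> on symbols
    present: dict[str, list[str]] = field(default_factory=dict)  # species -> ogs


def _symbol_pool(mode: PairingMode, code: GeneticCode) -> list[str]:
    if mode is PairingMode.IDENTICAL:
        return sorted(code.sense_codons)
    synonyms: dict[str, list[str]] = {}
    for codon in sorted(code.sense_codons):
        synonyms.setdefault(code.codon_to_aa[codon], []).append(codon)
    if mode is PairingMode.COTRNA:
        # co-tRNA pairing needs two distinct synonymous codons
        return sorted(aa for aa, cods in synonyms.items() if len(cods) >= 2)
    return sorted(synonyms)


def _synonym_table(code: GeneticCode) -> dict[str, list[str]]:
    table: dict[str, list[str]] = {}
    for codon in sorted(code.sense_codons):
        table.setdefault(code.codon_to_aa[codon], []).append(codon)
    return table


def evolve_states(cfg: SimulationConfig) -> ProfileStateTable:
    """Evolve binary pairing states for every (ortholog, symbol) character
    down the tree; seeded and reproducible."""
    code = GeneticCode.from_table_id(cfg.table_id)
    rng = np.random.default_rng(cfg.seed)
    pool = _symbol_pool(cfg.mode, code)
    k = min(cfg.symbols_per_ortholog, len(pool))
    ogs = [f"og{i + 1:04d}" for i in range(cfg.n_orthologs)]
    ortholog_symbols = {
        og: tuple(sorted(rng.choice(pool, size=k, replace=False))) for og in ogs
    }
    ncols = cfg.n_orthologs * k

    for edge in cfg.tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None and edge.length is None:
            raise ValueError("simulation tree must have branch lengths")

    node_states: dict[int, np.ndarray] = {}
    root = cfg.tree.seed_node
    node_states[id(root)] = rng.random(ncols) < cfg.root_pairing_prob
    leaves: dict[str, np.ndarray] = {}
    for node in cfg.tree.preorder_node_iter():
        if node is root:
            parent_state = node_states[id(root)]
        else:
            parent_state = node_states[id(node.parent_node)]
            # symmetric two-state CTMC transition probability: tends to
            # 1/2 (stationary disagreement) as rate * length grows
            p_flip = 0.5 * (1.0 - np.exp(-2.0 * cfg.flip_rate * node.edge.length))
            flips = rng.random(ncols) < p_flip
            node_states[id(node)] = parent_state ^ flips
        if node.is_leaf():
            leaves[node.taxon.label] = node_states[id(node)]

    species_ids = sorted(leaves)
    states: dict[str, dict[str, frozenset[str]]] = {}
    present: dict[str, list[str]] = {}
    for sid in species_ids:
        vec = leaves[sid]
        kept = [og for og in ogs if not (cfg.missingness and rng.random() < cfg.missingness)]
        per: dict[str, frozenset[str]] = {}
        for idx, og in enumerate(ogs):
            if og not in kept:
                continue
            symbols = ortholog_symbols[og]
            on = frozenset(
                sym for j, sym in enumerate(symbols) if vec[idx * k + j]
            )
            per[og] = on
        states[sid] = per
        present[sid] = kept
    return ProfileStateTable(
        species_ids=species_ids,
        ortholog_symbols=ortholog_symbols,
        states=states,
        present=present,
    )


def _build_cds(
    target: tuple[str, ...],
    mode: PairingMode,
    w: int,
    gene_length: int,
    code: GeneticCode,
) -> str:
    """A CDS whose pairing set under (mode, w) is exactly ``target``."""
    synonyms = _synonym_table(code)
    blocks: list[str] = []
    for sym in sorted(target):
        if mode is PairingMode.IDENTICAL:
            blocks += [sym, sym]
        elif mode is PairingMode.COTRNA:
            c1, c2 = synonyms[sym][:2]
            blocks += [c1, c2]
        else:
            codon = synonyms[sym][0]
            blocks += [codon, codon]

    # filler families rotate with period w so the same family never recurs
    # within w-1 positions; families overlapping the target are harmless
    # (any pairing they cause is of a symbol already in the target set)
    if mode is PairingMode.IDENTICAL:
        families = [c for c in sorted(code.sense_codons) if c not in target]
        fillers = [c for c in families[:w]]
        if len(fillers) < w:
            fillers += sorted(target)[: w - len(fillers)]
    else:
        residues = [aa for aa in sorted(synonyms) if aa not in target]
        fillers = [synonyms[aa][0] for aa in residues[:w]]
        if len(fillers) < w:
            fillers += [synonyms[aa][0] for aa in sorted(target)[: w - len(fillers)]]

    length = gene_length
    if len(blocks) > length:
        warnings.warn(
            f"target of {len(target)} symbols needs {len(blocks)} codons; "
            f"extending gene beyond {gene_length}"
        )
        length = len(blocks)
    codons = list(blocks)
    i = 0
    while len(codons) < length:
        codons.append(fillers[i % len(fillers)])
        i += 1
    return "".join(codons) + "TAA"


def realize_sequences(
    states: ProfileStateTable,
    cfg: SimulationConfig,
) -> dict[str, SpeciesGeneSet]:
    """Turn simulated states into per-species gene sets (invertible)."""
    code = GeneticCode.from_table_id(cfg.table_id)
    out: dict[str, SpeciesGeneSet] = {}
    for sid in states.species_ids:
        genes = []
        for og in states.present.get(sid, sorted(states.states[sid])):
            target = tuple(sorted(states.states[sid][og]))
            cds = _build_cds(target, cfg.mode, cfg.window, cfg.gene_length, code)
            # strip the terminal stop the loader would remove, keeping the
            # in-memory record consistent with a load round trip
            genes.append(GeneRecord(species_id=sid, ortholog_key=og, cds=cds[:-3]))
        out[sid] = SpeciesGeneSet(species_id=sid, genes=genes)
    return out


def simulate_dataset(cfg: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write one FASTA per species plus the true tree, the true state
    table and a replay manifest.  Returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    states = evolve_states(cfg)
    gene_sets = realize_sequences(states, cfg)

    paths: dict[str, Path] = {}
    for sid, gs in gene_sets.items():
        p = out_dir / f"{sid}.fasta"
        write_species_fasta(gs, p)
        paths[sid] = p

    tree_path = out_dir / "true_tree.nwk"
    cfg.tree.write(path=str(tree_path), schema="newick")
    paths["true_tree"] = tree_path

    states_path = out_dir / "true_states.tsv"
    with open(states_path, "w") as fh:
        fh.write("species_id\tortholog\ton_symbols\n")
        for sid in states.species_ids:
            for og in sorted(states.states[sid]):
                fh.write(f"{sid}\t{og}\t{','.join(sorted(states.states[sid][og]))}\n")
    paths["true_states"] = states_path

    manifest_path = out_dir / "manifest.txt"
    with open(manifest_path, "w") as fh:
        fh.write(f"seed={cfg.seed}\n")
        fh.write(f"n_orthologs={cfg.n_orthologs}\n")
        fh.write(f"symbols_per_ortholog={cfg.symbols_per_ortholog}\n")
        fh.write(f"root_pairing_prob={cfg.root_pairing_prob}\n")
        fh.write(f"flip_rate={cfg.flip_rate}\n")
        fh.write(f"window={cfg.window}\n")
        fh.write(f"mode={cfg.mode.value}\n")
        fh.write(f"gene_length={cfg.gene_length}\n")
        fh.write(f"missingness={cfg.missingness}\n")
        fh.write(f"table_id={cfg.table_id}\n")
        fh.write(f"n_species={len(states.species_ids)}\n")
    paths["manifest"] = manifest_path
    return paths
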