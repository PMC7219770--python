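"""Alignment-free pipeline: species motif profiles, set-overlap distances,
and neighbor-joining.

A species profile is the set of distinct gene pairing motifs across all
its genes.  The pairwise distance between species A and B with profiles
``a`` and ``b`` is

    Dist(A, B) = 1 - |a ∩ b| / min(|a|, |b|)

normalized by the smaller profile so that a small genome fully contained
in a large one scores distance 0.  To limit small-genome bias, pairs whose
profile-size ratio min/max does not exceed 5% are snapped to the maximum
distance 1.0.  Note the distance is containment-normalized and is not a
metric (no triangle inequality).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import skbio
import dendropy

from codonpairing.pairing_core import PairingMode, gene_motif
from codonpairing.seqio_genetics import GeneticCode, SpeciesGeneSet

DEFAULT_RATIO_FLOOR = 0.05

Motif = tuple[str, ...]


@dataclass
class SpeciesProfile:
    species_id: str
    motifs: set[Motif] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.motifs)


@dataclass
class DistanceMatrix:
    """Symmetric species-by-species distance matrix with values in [0, 1]."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate species ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix not symmetric")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return float(self.values[i, j])

    def to_skbio(self) -> skbio.DistanceMatrix:
        return skbio.DistanceMatrix(self.values, ids=self.ids)

    def write_phylip(self, path: str | Path) -> None:
        """Square PHYLIP distance format, %.6f entries."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for sid, row in zip(self.ids, self.values):
                fh.write(sid + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def read_phylip(cls, path: str | Path) -> "DistanceMatrix":
        with open(path) as fh:
            n = int(fh.readline().split()[0])
            ids, rows = [], []
            for _ in range(n):
                parts = fh.readline().split()
                ids.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        return cls(ids=ids, values=np.array(rows))


def build_profile(
    genes: SpeciesGeneSet,
    mode: PairingMode,
    w: int,
    code: GeneticCode,
) -> SpeciesProfile:
    """Collect the species' set of distinct nonempty gene motifs."""
    motifs = set()
    for gene in genes:
        motif = gene_motif(gene, mode, w, code)
        if motif:
            motifs.add(motif)
    return SpeciesProfile(species_id=genes.species_id, motifs=motifs)


def pair_distance(
    a: SpeciesProfile,
    b: SpeciesProfile,
    ratio_floor: float = DEFAULT_RATIO_FLOOR,
) -> float:
    """Containment-normalized profile distance with the small-profile guard.

    Returns 1.0 when either profile is empty or when the profile-size
    ratio min/max does not exceed ``ratio_floor`` (inclusive snap).
    """
    na, nb = len(a.motifs), len(b.motifs)
    lo, hi = min(na, nb), max(na, nb)
    if lo == 0 or lo / hi <= ratio_floor:
        return 1.0
    return 1.0 - len(a.motifs & b.motifs) / lo


def distance_matrix(
    profiles: list[SpeciesProfile],
    ratio_floor: float = DEFAULT_RATIO_FLOOR,
) -> DistanceMatrix:
    ids = [p.species_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate species ids in profiles")
    n = len(profiles)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pair_distance(profiles[i], profiles[j], ratio_floor)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids=ids, values=values)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; negative branch lengths clamped to 0.

    Returns an unrooted binary tree over all species ids.
    """
    if len(dm.ids) < 3:
        raise ValueError("neighbor joining requires at least 3 species")
    nj_tree = skbio.tree.nj(dm.to_skbio(), neg_as_zero=True)
    buf = io.StringIO()
    nj_tree.write(buf)
    tree = dendropy.Tree.get(data=buf.getvalue(), schema="newick")
    tree.is_rooted = False
    return tree
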