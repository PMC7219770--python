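"""Descriptive statistics of pairing motifs.

Answers the census questions one asks of a motif catalogue: how often is
the same motif found in more than one species, how many symbols do motifs
contain, what fraction of genes pair each codon, and whether pairing is
merely a gene-length artifact (total pairing events scale with length;
the number of *distinct* paired symbols should not).
"""

from __future__ import annotations

import csv
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy import stats

from codonpairing.pairing_core import (
    PairingMode,
    gene_motif,
    gene_pairing_set,
    pairing_event_count,
)
from codonpairing.seqio_genetics import GeneticCode, SpeciesGeneSet

Motif = tuple[str, ...]

#: sentinel for statistics that are undefined on degenerate input
UNDEFINED = float("nan")


@dataclass
class MotifCensus:
    """Catalogue of motifs: which species use each, and how often overall."""

    species_of: dict[Motif, set[str]] = field(default_factory=lambda: defaultdict(set))
    occurrences: Counter = field(default_factory=Counter)

    def add(self, species_id: str, motif: Motif) -> None:
        if not motif:
            return
        self.species_of[motif].add(species_id)
        self.occurrences[motif] += 1

    def __len__(self) -> int:
        return len(self.species_of)


def build_census(
    species: Iterable[SpeciesGeneSet],
    mode: PairingMode,
    w: int,
    code: GeneticCode,
) -> MotifCensus:
    census = MotifCensus()
    for sp in species:
        for gene in sp:
            census.add(sp.species_id, gene_motif(gene, mode, w, code))
    return census


def shared_motif_fraction(census: MotifCensus) -> float:
    """Fraction of distinct motifs found in two or more species."""
    if len(census) == 0:
        raise ValueError("empty motif census")
    shared = sum(1 for spp in census.species_of.values() if len(spp) >= 2)
    return shared / len(census)


def motif_size_distribution(census: MotifCensus) -> Counter:
    """Counts of distinct motifs by cardinality (1..61 codons, 1..20 residues)."""
    return Counter(len(m) for m in census.species_of)


def repeat_frequency_distribution(census: MotifCensus) -> Counter:
    """Histogram of how many times each distinct motif occurs across genes."""
    return Counter(census.occurrences.values())


def codon_pairing_frequency(
    species: SpeciesGeneSet,
    mode: PairingMode,
    w: int,
    code: GeneticCode,
) -> dict[str, float]:
    """Per-symbol fraction of the species' genes whose pairing set has it."""
    if len(species) == 0:
        raise ValueError("empty gene set")
    counts: Counter = Counter()
    for gene in species:
        counts.update(gene_pairing_set(gene, mode, w, code))
    return {sym: c / len(species) for sym, c in sorted(counts.items())}


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return UNDEFINED
    return float(stats.linregress(x, y).rvalue ** 2)


def length_correlations(
    species: SpeciesGeneSet,
    mode: PairingMode,
    w: int,
    code: GeneticCode,
) -> tuple[float, float]:
    """OLS R-squared of pairing against gene length (in codons).

    Returns ``(r2_events, r2_distinct)``: the fit of the total number of
    pairing events, and of the number of distinct paired symbols, against
    gene length.  NaN where the regression is degenerate.
    """
    if len(species) < 3:
        raise ValueError("need >= 3 genes for a length regression")
    lengths = np.array([g.n_codons for g in species], dtype=float)
    events = np.array(
        [pairing_event_count(g, mode, w, code) for g in species], dtype=float
    )
    distinct = np.array(
        [len(gene_pairing_set(g, mode, w, code)) for g in species], dtype=float
    )
    return _r_squared(lengths, events), _r_squared(lengths, distinct)


def write_census_tsv(census: MotifCensus, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["motif", "n_species", "n_occurrences"])
        for motif in sorted(census.species_of):
            writer.writerow(
                [",".join(motif), len(census.species_of[motif]), census.occurrences[motif]]
            )
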