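"""Sliding-window codon pairing detection.

A translating ribosome covers roughly 2-15 codons of mRNA; when the same
tRNA (or a synonymous one) is needed twice inside that footprint, it can
be reused before diffusing away.  We model the footprint as a window of
``w`` codons and record, per gene, which symbols pair within it:

* IDENTICAL — the same codon occurs twice within the window; the symbol
  recorded is the codon itself.
* COTRNA — two *different* codons encoding the same amino acid occur
  within the window; the symbol recorded is the one-letter residue.
* COMBINED — any two codons encoding the same amino acid (identical or
  not); residue symbols.

Encoding is binary: a symbol is in the gene's pairing set once no matter
how many times it pairs.  Two codon positions ``i < j`` are "within a
window of w codons" iff ``j - i <= w - 1``, which is equivalent to
scanning every contiguous w-codon window.
"""

from __future__ import annotations

import csv
from enum import Enum
from pathlib import Path
from typing import Iterable

from codonpairing.seqio_genetics import GeneRecord, GeneticCode, SpeciesGeneSet, _ACGT

MIN_WINDOW = 2
MAX_WINDOW = 15


class PairingMode(str, Enum):
    IDENTICAL = "identical"
    COTRNA = "cotrna"
    COMBINED = "combined"

    @property
    def emits_residues(self) -> bool:
        return self is not PairingMode.IDENTICAL


def _check_window(w: int) -> None:
    if not (MIN_WINDOW <= w <= MAX_WINDOW):
        raise ValueError(f"window must be in [{MIN_WINDOW}, {MAX_WINDOW}], got {w}")


def _pairable_codon(codon: str, code: GeneticCode) -> bool:
    # Stop codons and codons with ambiguity letters never pair; their
    # positions still count toward pairwise distance.
    return set(codon) <= _ACGT and codon not in code.stop_codons


def gene_pairing_set(
    gene: GeneRecord,
    mode: PairingMode,
    w: int,
    code: GeneticCode,
) -> set[str]:
    """Symbols (codons or residues) that pair within a w-codon window.

    O(n * w): each codon is compared with the at most ``w - 1`` codons
    preceding it.  Genes shorter than ``w`` are handled naturally.
    """
    _check_window(w)
    mode = PairingMode(mode)
    codons = gene.codons
    out: set[str] = set()
    for j, cj in enumerate(codons):
        if not _pairable_codon(cj, code):
            continue
        aa_j = code.codon_to_aa[cj]
        for i in range(max(0, j - (w - 1)), j):
            ci = codons[i]
            if not _pairable_codon(ci, code):
                continue
            if mode is PairingMode.IDENTICAL:
                if ci == cj:
                    out.add(cj)
            elif mode is PairingMode.COTRNA:
                if ci != cj and code.codon_to_aa[ci] == aa_j:
                    out.add(aa_j)
            else:  # COMBINED
                if code.codon_to_aa[ci] == aa_j:
                    out.add(aa_j)
    return out


def gene_motif(
    gene: GeneRecord,
    mode: PairingMode,
    w: int,
    code: GeneticCode,
) -> tuple[str, ...]:
    """The gene's pairing motif: its pairing set as a sorted tuple.

    Sorting makes the motif independent of the order pairings are found;
    an empty tuple means no pairing (excluded from species profiles).
    """
    return tuple(sorted(gene_pairing_set(gene, mode, w, code)))


def pairing_event_count(
    gene: GeneRecord,
    mode: PairingMode,
    w: int,
    code: GeneticCode,
) -> int:
    """Number of unordered codon-position pairs (i<j, j-i<=w-1) that pair.

    Unlike :func:`gene_pairing_set` this counts multiplicity, which is the
    quantity expected to scale linearly with gene length.
    """
    _check_window(w)
    mode = PairingMode(mode)
    codons = gene.codons
    n = 0
    for j, cj in enumerate(codons):
        if not _pairable_codon(cj, code):
            continue
        aa_j = code.codon_to_aa[cj]
        for i in range(max(0, j - (w - 1)), j):
            ci = codons[i]
            if not _pairable_codon(ci, code):
                continue
            if mode is PairingMode.IDENTICAL:
                n += ci == cj
            elif mode is PairingMode.COTRNA:
                n += ci != cj and code.codon_to_aa[ci] == aa_j
            else:
                n += code.codon_to_aa[ci] == aa_j
    return n


def write_pairing_report(
    species: Iterable[SpeciesGeneSet],
    mode: PairingMode,
    w: int,
    code: GeneticCode,
    path: str | Path,
) -> None:
    """Per-gene pairing motifs as TSV: species, ortholog, mode, w, motif."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["species_id", "ortholog_key", "mode", "window", "motif"])
        for sp in species:
            for gene in sp.genes:
                motif = gene_motif(gene, mode, w, code)
                writer.writerow(
                    [sp.species_id, gene.ortholog_key, PairingMode(mode).value, w, ",".join(motif)]
                )
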