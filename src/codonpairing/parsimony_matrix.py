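"""Binary parsimony character matrix over (ortholog, symbol) columns.

Each column records whether a given codon (or residue, depending on
pairing mode) pairs within the ribosome window of a given ortholog: '1'
if it pairs in that species, '0' if it does not, '?' if the species lacks
the ortholog.  Columns are filtered to the informative set (ortholog in
at least four species; both states observed), species with too few scored
cells are removed, and the result is exported as a TNT ``xread`` block
plus an ordered key file.

Filtering is a single linear pass: informative-column filter, then
species-coverage filter, then the group-viability check.  Columns are not
re-filtered after species removal unless ``refilter`` is requested.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from codonpairing.pairing_core import PairingMode, gene_pairing_set
from codonpairing.seqio_genetics import GeneticCode, SpeciesGeneSet

MISSING = -1  # internal encoding of '?'

DEFAULT_MIN_CHAR_FRAC = 0.05
DEFAULT_MIN_SPECIES_FRAC = 0.05
MIN_ORTHOLOG_SPECIES = 4


class EmptyMatrixError(ValueError):
    """No column survived filtering."""


class GroupNotAnalyzableError(RuntimeError):
    """Too few species passed the coverage filter; the group is skipped.

    Distinct from I/O failure: the inputs were valid but the dataset does
    not meet the minimum-coverage design of the analysis.
    """

    def __init__(self, surviving: int, total: int, min_frac: float):
        self.surviving = surviving
        self.total = total
        self.min_frac = min_frac
        super().__init__(
            f"only {surviving}/{total} species passed the coverage filter "
            f"(< {min_frac:.0%}); group skipped"
        )


@dataclass
class CharacterMatrix:
    """Species x (ortholog, symbol) grid over {0, 1, ?}.

    ``cells`` is int8 with 0/1 and -1 for '?'; row order matches
    ``species_ids`` and column order matches ``characters``.
    """

    species_ids: list[str]
    characters: list[tuple[str, str]]  # (ortholog_key, symbol) in column order
    cells: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.cells.shape != (len(self.species_ids), len(self.characters)):
            raise ValueError("cell grid shape mismatch")
        if len(set(self.characters)) != len(self.characters):
            raise ValueError("duplicate (ortholog, symbol) characters")

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def column(self, j: int) -> dict[str, int]:
        """Column j as species -> state (MISSING for '?')."""
        return {s: int(v) for s, v in zip(self.species_ids, self.cells[:, j])}

    def to_strings(self) -> dict[str, str]:
        """Per-species contiguous 0/1/? strings (TNT row payload)."""
        lut = {0: "0", 1: "1", MISSING: "?"}
        return {
            s: "".join(lut[int(v)] for v in row)
            for s, row in zip(self.species_ids, self.cells)
        }


def assemble_raw_matrix(
    species: list[SpeciesGeneSet],
    mode: PairingMode,
    w: int,
    code: GeneticCode,
) -> CharacterMatrix:
    """Build the unfiltered matrix from per-species gene sets.

    Emits one column per (ortholog, symbol) where the symbol pairs in at
    least one species carrying the ortholog; species lacking the ortholog
    get '?' in all its columns.  Columns are ordered by (ortholog, symbol).
    """
    if len(species) < MIN_ORTHOLOG_SPECIES:
        raise ValueError(f"need at least {MIN_ORTHOLOG_SPECIES} species")
    ids = [s.species_id for s in species]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate species ids")

    # pairing sets per species per ortholog
    pairing: dict[str, dict[str, set[str]]] = {}
    orthologs: set[str] = set()
    for sp in species:
        per = {}
        for gene in sp:
            per[gene.ortholog_key] = gene_pairing_set(gene, mode, w, code)
        pairing[sp.species_id] = per
        orthologs.update(per)

    characters: list[tuple[str, str]] = []
    columns: list[np.ndarray] = []
    for og in sorted(orthologs):
        symbols = sorted(set().union(*(pairing[s].get(og, set()) for s in ids)))
        for sym in symbols:
            col = np.full(len(ids), MISSING, dtype=np.int8)
            for i, sid in enumerate(ids):
                sets = pairing[sid]
                if og in sets:
                    col[i] = 1 if sym in sets[og] else 0
            characters.append((og, sym))
            columns.append(col)
    cells = (
        np.column_stack(columns) if columns else np.zeros((len(ids), 0), dtype=np.int8)
    )
    return CharacterMatrix(species_ids=ids, characters=characters, cells=cells)


def filter_informative(
    m: CharacterMatrix,
    *,
    strict: bool = False,
) -> CharacterMatrix:
    """Keep columns whose ortholog spans >= 4 species and that show both states.

    ``strict`` additionally requires each state in >= 2 taxa (the textbook
    parsimony-informative definition, which excludes autapomorphies).
    Column order is preserved.
    """
    keep = []
    for j in range(m.n_characters):
        col = m.cells[:, j]
        scored = col != MISSING
        if scored.sum() < MIN_ORTHOLOG_SPECIES:
            continue
        ones = int((col == 1).sum())
        zeros = int((col == 0).sum())
        need = 2 if strict else 1
        if ones >= need and zeros >= need:
            keep.append(j)
    if not keep:
        raise EmptyMatrixError("no informative columns survive filtering")
    return CharacterMatrix(
        species_ids=list(m.species_ids),
        characters=[m.characters[j] for j in keep],
        cells=m.cells[:, keep],
    )


def filter_species_coverage(
    m: CharacterMatrix,
    min_char_frac: float = DEFAULT_MIN_CHAR_FRAC,
    min_species_frac: float = DEFAULT_MIN_SPECIES_FRAC,
) -> CharacterMatrix:
    """Drop species scoring (non-'?') fewer than ``min_char_frac`` of columns.

    If fewer than ``min_species_frac`` of the input species survive, the
    whole group is not analyzable and :class:`GroupNotAnalyzableError` is
    raised.
    """
    n_total = m.n_species
    scored_frac = (m.cells != MISSING).mean(axis=1)
    keep = [i for i in range(n_total) if scored_frac[i] >= min_char_frac]
    if len(keep) < min_species_frac * n_total:
        raise GroupNotAnalyzableError(len(keep), n_total, min_species_frac)
    return CharacterMatrix(
        species_ids=[m.species_ids[i] for i in keep],
        characters=list(m.characters),
        cells=m.cells[keep, :],
    )


def build_matrix(
    species: list[SpeciesGeneSet],
    mode: PairingMode,
    w: int,
    code: GeneticCode,
    *,
    min_char_frac: float = DEFAULT_MIN_CHAR_FRAC,
    min_species_frac: float = DEFAULT_MIN_SPECIES_FRAC,
    strict: bool = False,
    refilter: bool = False,
) -> CharacterMatrix:
    """Full pipeline: assemble, informative filter, coverage filter."""
    m = assemble_raw_matrix(species, mode, w, code)
    m = filter_informative(m, strict=strict)
    m = filter_species_coverage(m, min_char_frac, min_species_frac)
    if refilter:
        m = filter_informative(m, strict=strict)
    return m


# --- TNT serialization ------------------------------------------------------

_SANITIZE_RE = re.compile(r"[^A-Za-z0-9_.]")
MAX_TAXON_NAME = 32


def sanitize_taxon(name: str) -> str:
    return _SANITIZE_RE.sub("_", name.replace(" ", "_"))[:MAX_TAXON_NAME]


def write_tnt(
    m: CharacterMatrix,
    matrix_path: str | Path,
    key_path: str | Path,
    name_map_path: str | Path | None = None,
) -> None:
    """Write a TNT ``xread`` block plus the ordered character key file.

    Key file line ``i`` is ``ortholog<TAB>symbol`` for matrix column ``i``.
    Taxon names are sanitized for TNT; a sidecar name map guarantees
    reversibility when requested.
    """
    if m.n_characters == 0:
        raise EmptyMatrixError("refusing to write an empty matrix")
    sanitized = {}
    used = set()
    for sid in m.species_ids:
        base = sanitize_taxon(sid)
        name = base
        k = 1
        while name in used:
            name = f"{base}_{k}"
            k += 1
        used.add(name)
        sanitized[sid] = name

    rows = m.to_strings()
    with open(matrix_path, "w") as fh:
        fh.write("xread\n")
        fh.write(f"{m.n_characters} {m.n_species}\n")
        for sid in m.species_ids:
            fh.write(f"{sanitized[sid]} {rows[sid]}\n")
        fh.write(";\n")

    with open(key_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        for og, sym in m.characters:
            writer.writerow([og, sym])

    if name_map_path is not None:
        with open(name_map_path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            for sid in m.species_ids:
                writer.writerow([sanitized[sid], sid])


def read_tnt(
    matrix_path: str | Path,
    key_path: str | Path,
    name_map_path: str | Path | None = None,
) -> CharacterMatrix:
    """Reread a TNT xread matrix + key file written by :func:`write_tnt`."""
    with open(key_path) as fh:
        characters = [tuple(line.rstrip("\n").split("\t")) for line in fh if line.strip()]

    name_map = {}
    if name_map_path is not None:
        with open(name_map_path) as fh:
            for line in fh:
                if line.strip():
                    tnt_name, original = line.rstrip("\n").split("\t")
                    name_map[tnt_name] = original

    lut = {"0": 0, "1": 1, "?": MISSING}
    species_ids: list[str] = []
    rows: list[list[int]] = []
    with open(matrix_path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    assert lines[0].strip() == "xread", "not an xread file"
    nchar, ntax = map(int, lines[1].split())
    for ln in lines[2 : 2 + ntax]:
        name, payload = ln.split(maxsplit=1)
        species_ids.append(name_map.get(name, name))
        rows.append([lut[c] for c in payload.strip()])
    cells = np.array(rows, dtype=np.int8)
    if cells.shape != (ntax, nchar):
        raise ValueError("xread dimensions do not match payload")
    return CharacterMatrix(
        species_ids=species_ids, characters=[tuple(c) for c in characters], cells=cells
    )
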