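"""Reading per-species CDS FASTA files into validated gene records.

One FASTA file holds all coding sequences of one species, one record per
gene.  Records are validated (length divisible by three, terminal stop
stripped, internal-stop policy applied), collapsed to the longest isoform
per ortholog key, and wrapped with an NCBI genetic-code table for
downstream translation.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STOP = "*"
AMBIGUOUS = "X"
_ACGT = frozenset("ACGT")

# Default keyword list used to drop genes whose annotation flags a known
# translation problem (e.g. "transl_except=..." or "partial" CDS tags).
DEFAULT_DROP_KEYWORDS = ("exception", "partial")


class EmptySpeciesError(ValueError):
    """A FASTA file yielded zero valid gene records."""


@dataclass(frozen=True)
class GeneticCode:
    """An NCBI translation table restricted to what pairing needs.

    ``codon_to_aa`` maps all 64 trinucleotides to a one-letter residue,
    with stop codons mapped to ``"*"``.
    """

    table_id: int
    codon_to_aa: dict[str, str]
    stop_codons: frozenset[str]

    @classmethod
    def from_table_id(cls, table_id: int = 1) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = STOP
        if len(mapping) != 64:
            raise ValueError(f"table {table_id} does not map all 64 codons")
        return cls(table_id=table_id, codon_to_aa=mapping, stop_codons=frozenset(table.stop_codons))

    def residue(self, codon: str) -> str:
        """One-letter residue for a codon; ``X`` for non-ACGT codons."""
        aa = self.codon_to_aa.get(codon)
        return aa if aa is not None else AMBIGUOUS

    @property
    def sense_codons(self) -> frozenset[str]:
        return frozenset(c for c in self.codon_to_aa if c not in self.stop_codons)


@dataclass(frozen=True)
class GeneRecord:
    """One gene's CDS with its species and ortholog identifiers.

    ``cds`` is uppercase, has length divisible by 3 and no terminal stop
    codon (stripped at load time).
    """

    species_id: str
    ortholog_key: str
    cds: str

    @property
    def codons(self) -> tuple[str, ...]:
        return tuple(self.cds[i : i + 3] for i in range(0, len(self.cds), 3))

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3


@dataclass
class SpeciesGeneSet:
    """All validated genes of one species, keyed uniquely by ortholog."""

    species_id: str
    genes: list[GeneRecord] = field(default_factory=list)
    drop_counts: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        keys = [g.ortholog_key for g in self.genes]
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate ortholog keys in species {self.species_id}")
        for g in self.genes:
            if g.species_id != self.species_id:
                raise ValueError("gene species_id does not match set species_id")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    @property
    def ortholog_keys(self) -> set[str]:
        return {g.ortholog_key for g in self.genes}

    def get(self, ortholog_key: str) -> Optional[GeneRecord]:
        for g in self.genes:
            if g.ortholog_key == ortholog_key:
                return g
        return None


# --- header rules -----------------------------------------------------------

_GENE_TAG_RE = re.compile(r"\[?gene=([^\]\s]+)\]?")


def default_header_rule(header: str) -> str:
    """Extract an ortholog key from a FASTA header.

    Looks for a ``gene=``/``[gene=...]`` tag first (the NCBI CDS-from-genomic
    dialect), then falls back to the first whitespace-delimited token.
    Returns an empty string when nothing usable is present.
    """
    match = _GENE_TAG_RE.search(header)
    if match:
        return match.group(1)
    tokens = header.split()
    return tokens[0] if tokens else ""


HeaderRule = Callable[[str], str]


def _validate_cds(
    raw_seq: str,
    code: GeneticCode,
    internal_stop_policy: str,
) -> tuple[Optional[str], Optional[str]]:
    """Validate and normalize a raw CDS.

    Returns ``(cds, None)`` on success or ``(None, reason)`` when the record
    must be dropped.  Terminal stop codons are stripped; internal stops
    follow ``internal_stop_policy`` ("drop" removes the gene, "keep"
    retains it — pairing later skips the stop positions).
    """
    seq = raw_seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        return None, "length_not_multiple_of_3"
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in code.stop_codons:
        codons = codons[:-1]
    if any(c in code.stop_codons for c in codons):
        if internal_stop_policy == "drop":
            return None, "internal_stop"
        if internal_stop_policy != "keep":
            raise ValueError(f"unknown internal_stop_policy {internal_stop_policy!r}")
    return "".join(codons), None


def load_species_fasta(
    path: str | Path,
    *,
    species_id: Optional[str] = None,
    header_rule: HeaderRule = default_header_rule,
    code: Optional[GeneticCode] = None,
    internal_stop_policy: str = "drop",
    drop_keywords: Iterable[str] = DEFAULT_DROP_KEYWORDS,
) -> SpeciesGeneSet:
    """Load one species' CDS FASTA into a validated :class:`SpeciesGeneSet`.

    Records failing validation are dropped and tallied in ``drop_counts``.
    Among records sharing an ortholog key only the longest CDS is retained
    (ties keep the record appearing first in file order).

    Raises :class:`EmptySpeciesError` when no valid record survives.
    """
    path = Path(path)
    if code is None:
        code = GeneticCode.from_table_id(1)
    if species_id is None:
        species_id = path.stem
    keywords = tuple(k.lower() for k in drop_keywords)

    drops: Counter = Counter()
    best: dict[str, GeneRecord] = {}
    order: dict[str, int] = {}
    for i, record in enumerate(SeqIO.parse(str(path), "fasta")):
        header = f"{record.id} {record.description}".strip()
        if any(k in header.lower() for k in keywords):
            drops["annotation_keyword"] += 1
            continue
        key = header_rule(record.description or record.id)
        if not key:
            drops["no_ortholog_key"] += 1
            continue
        cds, reason = _validate_cds(str(record.seq), code, internal_stop_policy)
        if cds is None:
            drops[reason] += 1
            continue
        gene = GeneRecord(species_id=species_id, ortholog_key=key, cds=cds)
        if key not in best or len(gene.cds) > len(best[key].cds):
            if key in best:
                drops["shorter_isoform"] += 1
            else:
                order[key] = i
            best[key] = gene
        else:
            drops["shorter_isoform"] += 1

    if not best:
        raise EmptySpeciesError(f"no valid gene records in {path}")
    genes = [best[k] for k in sorted(best, key=order.__getitem__)]
    return SpeciesGeneSet(species_id=species_id, genes=genes, drop_counts=drops)


def write_species_fasta(genes: SpeciesGeneSet, path: str | Path) -> None:
    """Write a gene set back to FASTA (header = ortholog key)."""
    records = [
        SeqRecord(Seq(g.cds), id=g.ortholog_key, description="") for g in genes.genes
    ]
    SeqIO.write(records, str(path), "fasta")


def write_qc_report(species: Iterable[SpeciesGeneSet], path: str | Path) -> None:
    """TSV per-species QC summary: gene counts and drop reasons."""
    rows = []
    reasons: set[str] = set()
    for s in species:
        reasons.update(s.drop_counts)
        rows.append(s)
    reason_cols = sorted(reasons)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["species_id", "n_genes", "n_dropped", *reason_cols])
        for s in rows:
            writer.writerow(
                [s.species_id, len(s.genes), sum(s.drop_counts.values())]
                + [s.drop_counts.get(r, 0) for r in reason_cols]
            )


def translate(cds: str, code: GeneticCode) -> str:
    """Translate a CDS to one residue per sense codon.

    A terminal stop yields no residue; internal stops translate to ``*``
    and codons containing non-ACGT letters to ``X``.
    """
    seq = cds.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in code.stop_codons:
        codons = codons[:-1]
    return "".join(code.residue(c) for c in codons)
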