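"""Reference-database input/output and taxonomic group assignment.

A reference database is a FASTA file of rDNA sequences plus a flat taxonomy
TSV (``id<TAB>taxid<TAB>lineage``, lineage semicolon-joined root→leaf).
Lineages are mapped onto the four study groups — ascomycetes,
basidiomycetes, 'non-dikarya' fungi (a polyphyletic remainder including
e.g. Blastocladiomycota, Chytridiomycota, Glomeromycota and Zygomycota)
and plants — by clade *name*, so synthetic databases need no canonical
taxids. A minimal EMBL flat-file reader (ID / OC / SQ lines) is provided
for small fixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from ._iupac import validate_iupac

logger = logging.getLogger(__name__)

#: columns of the amplicon report TSV, in order
AMPLICON_COLUMNS = [
    "record_id",
    "taxid",
    "group",
    "strand",
    "fwd_start",
    "rev_end",
    "insert_length",
    "total_length",
    "fwd_mismatches",
    "rev_mismatches",
    "fwd_tm",
    "rev_tm",
]


class Group(str, Enum):
    """Taxonomic group labels used throughout the bias statistics."""

    ASCOMYCETE = "ascomycete"
    BASIDIOMYCETE = "basidiomycete"
    NON_DIKARYA = "non_dikarya"
    PLANT = "plant"
    OTHER = "other"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def classify_group(lineage: Sequence[str]) -> Group:
    """Map a root→leaf lineage onto the study's group labels.

    Matching is on clade names, case-insensitively: Ascomycota →
    ascomycete, Basidiomycota → basidiomycete, any other lineage
    containing Fungi → non_dikarya, Viridiplantae → plant, otherwise
    other. Total and deterministic; the five labels partition all inputs.
    """
    if not lineage:
        raise ValueError("lineage must be non-empty")
    ranks = {r.strip().lower() for r in lineage}
    if "ascomycota" in ranks:
        return Group.ASCOMYCETE
    if "basidiomycota" in ranks:
        return Group.BASIDIOMYCETE
    if "fungi" in ranks:
        return Group.NON_DIKARYA
    if "viridiplantae" in ranks:
        return Group.PLANT
    return Group.OTHER


@dataclass(frozen=True)
class ReferenceRecord:
    """One database entry: uppercase IUPAC DNA plus resolved taxonomy."""

    id: str
    sequence: str
    taxid: int
    lineage: tuple[str, ...]
    group: Group

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id}: empty sequence")
        if not self.sequence.isupper():
            object.__setattr__(self, "sequence", self.sequence.upper())
        if not validate_iupac(self.sequence):
            bad = sorted(set(self.sequence) - set("ACGTRYSWKMBDHVN"))
            raise ValueError(f"record {self.id}: non-IUPAC characters {bad}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceDB:
    """An ordered collection of reference records with unique ids."""

    records: list[ReferenceRecord]
    label: str = "db"
    dropped: int = 0  # records discarded at load (unresolvable taxid)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids in database: {dup[:5]}")
        self._index = {r.id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, record_id: str) -> ReferenceRecord:
        return self._index[record_id]

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._index

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


@dataclass
class TaxonomyTable:
    """Hierarchical taxonomy: taxid → (name, rank, parent taxid).

    Optional adapter for users with a real taxonomy dump; the flat
    per-record TSV is the primary carrier of lineage information.
    """

    nodes: dict[int, tuple[str, str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for taxid in self.nodes:
            self.lineage(taxid)  # raises on cycles / dangling parents

    def lineage(self, taxid: int) -> list[str]:
        """Root→leaf list of node names; raises on cyclic parent chains."""
        names: list[str] = []
        seen: set[int] = set()
        node = taxid
        while True:
            if node in seen:
                raise ValueError(f"cyclic parent chain at taxid {node}")
            seen.add(node)
            if node not in self.nodes:
                raise KeyError(f"unknown taxid {node}")
            name, _rank, parent = self.nodes[node]
            names.append(name)
            if parent == node:  # root convention: parent of root is itself
                break
            node = parent
        return names[::-1]


def read_taxonomy_tsv(path: str | Path) -> dict[str, tuple[int, tuple[str, ...]]]:
    """Read the flat taxonomy TSV: record id → (taxid, lineage tuple)."""
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                        names=["id", "taxid", "lineage"], header=0)
    out: dict[str, tuple[int, tuple[str, ...]]] = {}
    for row in table.itertuples(index=False):
        out[row.id] = (int(row.taxid), tuple(p.strip() for p in row.lineage.split(";")))
    return out


def write_taxonomy_tsv(db: ReferenceDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\ttaxid\tlineage\n")
        for rec in db:
            fh.write(f"{rec.id}\t{rec.taxid}\t{';'.join(rec.lineage)}\n")


def read_reference_db(fasta_path: str | Path, taxonomy_path: str | Path,
                      label: str | None = None) -> ReferenceDB:
    """Load FASTA + taxonomy TSV into a ReferenceDB.

    Sequences are uppercased (soft-masking has no meaning for primer
    matching). Records whose id is absent from the taxonomy table are
    dropped and counted in ``db.dropped``; records with non-IUPAC
    characters are rejected with an error naming the offending id.
    """
    taxonomy = read_taxonomy_tsv(taxonomy_path)
    records: list[ReferenceRecord] = []
    dropped = 0
    for seqrec in SeqIO.parse(str(fasta_path), "fasta"):
        if seqrec.id not in taxonomy:
            dropped += 1
            continue
        taxid, lineage = taxonomy[seqrec.id]
        records.append(ReferenceRecord(
            id=seqrec.id,
            sequence=str(seqrec.seq).upper(),
            taxid=taxid,
            lineage=lineage,
            group=classify_group(lineage),
        ))
    if dropped:
        logger.warning("%d record(s) dropped: id absent from taxonomy table", dropped)
    return ReferenceDB(records, label=label or Path(fasta_path).stem, dropped=dropped)


def write_reference_db(db: ReferenceDB, fasta_path: str | Path,
                       taxonomy_path: str | Path) -> None:
    """Write FASTA + taxonomy TSV (inverse of :func:`read_reference_db`)."""
    with open(fasta_path, "w") as fh:
        for rec in db:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i:i + 70] + "\n")
    write_taxonomy_tsv(db, taxonomy_path)


def read_embl_db(path: str | Path, label: str | None = None) -> ReferenceDB:
    """Minimal EMBL flat-file reader (ID, OC, optional taxon xref, SQ block).

    Sufficient for small fixtures; full EMBL ingestion is out of scope.
    """
    records: list[ReferenceRecord] = []
    rec_id = None
    lineage_parts: list[str] = []
    taxid = 0
    seq_lines: list[str] = []
    in_seq = False
    with open(path) as fh:
        for line in fh:
            code, _, rest = line.rstrip("\n").partition("   ")
            if line.startswith("ID"):
                rec_id = rest.split(";")[0].strip()
                lineage_parts, seq_lines, taxid, in_seq = [], [], 0, False
            elif line.startswith("OC"):
                lineage_parts.append(rest.strip().rstrip(".;"))
            elif 'db_xref="taxon:' in line:
                taxid = int(line.split('taxon:')[1].split('"')[0])
            elif line.startswith("SQ"):
                in_seq = True
            elif line.startswith("//"):
                if rec_id is None:
                    raise ValueError("EMBL record terminator before ID line")
                lineage = tuple(
                    p.strip() for chunk in lineage_parts for p in chunk.split(";") if p.strip()
                )
                seq = "".join(seq_lines).upper()
                records.append(ReferenceRecord(
                    id=rec_id, sequence=seq, taxid=taxid, lineage=lineage,
                    group=classify_group(lineage) if lineage else Group.OTHER,
                ))
                rec_id, in_seq = None, False
            elif in_seq:
                seq_lines.append("".join(c for c in line if c.isalpha()))
    return ReferenceDB(records, label=label or Path(path).stem)


def write_amplicon_table(amplicons: Iterable, path: str | Path) -> None:
    """Write amplicons as a TSV with the fixed column set.

    Rows are sorted by (record id, span start); coordinates are 0-based
    half-open on the stored (plus) strand; temperatures are rounded to
    2 decimals in the file (full precision is kept in memory).
    """
    rows = [a.as_row() if hasattr(a, "as_row") else dict(a) for a in amplicons]
    table = pd.DataFrame(rows, columns=AMPLICON_COLUMNS)
    table = table.sort_values(["record_id", "fwd_start"], kind="mergesort")
    for col in ("fwd_tm", "rev_tm"):
        table[col] = pd.to_numeric(table[col], errors="coerce").round(2)
    table.to_csv(path, sep="\t", index=False)


def read_amplicon_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"record_id": str, "group": str, "strand": str})
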