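"""Reading and writing the formats the toolkit touches.

FASTA and aligned FASTA go through Biopython's SeqIO; this module adds the
validation the downstream contracts rely on: unique ids, a restricted
alphabet, U->T normalization (rRNA *gene* context), and equal row lengths
for alignments. The taxon table is a three-column-plus-id TSV mapping each
sequence to a phylum, a class, and a role in the primer-design problem
(``target`` = clades the primers must amplify, ``excluded`` = clades they
must reject, ``outgroup`` = rooting convenience).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from . import iupac
from .errors import (
    AlignmentShapeError,
    DuplicateIdError,
    EmptyFileError,
    GappedTemplateError,
    MissingFileError,
    TaxonTableError,
)

log = logging.getLogger(__name__)

ROLES = frozenset({"target", "excluded", "outgroup"})


@dataclass(frozen=True)
class SequenceRecord:
    """One sequence with its FASTA header split into id and description."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise ValueError(f"invalid record id: {self.id!r}")
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Alignment:
    """An ordered list of equal-length rows (gaps '-' allowed)."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentShapeError("alignment has no rows")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise AlignmentShapeError(f"ragged rows: lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def row(self, seq_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class TaxonEntry:
    phylum: str
    klass: str  # 'class' is reserved; reports print it as "class"
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise TaxonTableError(
                f"unknown role {self.role!r}; expected one of {sorted(ROLES)}"
            )


@dataclass
class TaxonMap:
    """Sequence id -> (phylum, class, role); grouping key defaults to class."""

    entries: dict[str, TaxonEntry] = field(default_factory=dict)

    def __getitem__(self, seq_id: str) -> TaxonEntry:
        return self.entries[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def ids_with_role(self, role: str) -> list[str]:
        return [i for i, e in self.entries.items() if e.role == role]

    def group_of(self, seq_id: str, key: str = "class") -> str:
        e = self.entries[seq_id]
        return e.klass if key == "class" else e.phylum

    def groups(self, key: str = "class") -> dict[str, list[str]]:
        """Group name -> member ids, insertion-ordered."""
        out: dict[str, list[str]] = {}
        for seq_id in self.entries:
            out.setdefault(self.group_of(seq_id, key), []).append(seq_id)
        return out


def _normalize(raw: str, *, allow_gaps: bool, where: str) -> str:
    seq = raw.upper()
    n_u = seq.count("U")
    if n_u:
        seq = seq.replace("U", "T")
        log.info("normalized %d U->T in %s", n_u, where)
    if not allow_gaps and "-" in seq:
        raise GappedTemplateError(f"gap character in unaligned record {where}")
    iupac.validate_sequence(seq, allow_gaps=allow_gaps)
    return seq


def _read_records(path: str | Path, *, allow_gaps: bool) -> list[SequenceRecord]:
    p = Path(path)
    if not p.exists():
        raise MissingFileError(str(p))
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(p), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate id {rec.id!r} in {p}")
        seen.add(rec.id)
        seq = _normalize(str(rec.seq), allow_gaps=allow_gaps, where=rec.id)
        desc = rec.description[len(rec.id):].strip()
        records.append(SequenceRecord(id=rec.id, sequence=seq, description=desc))
    if not records:
        raise EmptyFileError(f"no FASTA records in {p}")
    return records


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read unaligned FASTA. Upper-cases, normalizes U->T, rejects gaps."""
    return _read_records(path, allow_gaps=False)


def read_alignment(path: str | Path) -> Alignment:
    """Read aligned FASTA; all rows must have equal length."""
    return Alignment(tuple(_read_records(path, allow_gaps=True)))


def write_fasta(
    records: Iterable[SequenceRecord] | Alignment, path: str | Path, width: int = 80
) -> None:
    """Write FASTA wrapped at `width` columns (readers accept any wrapping)."""
    if isinstance(records, Alignment):
        records = records.records
    bio = [
        _BioRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(bio)


def read_taxon_table(path: str | Path, known_ids: Iterable[str] | None = None) -> TaxonMap:
    """Read the id/phylum/class/role TSV.

    `known_ids`, when given, triggers a warning (not an error) for table
    rows whose id is absent from the companion FASTA.
    """
    p = Path(path)
    if not p.exists():
        raise MissingFileError(str(p))
    tm = TaxonMap()
    with open(p, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"id", "phylum", "class", "role"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            missing = required - set(reader.fieldnames or [])
            raise TaxonTableError(f"missing column(s): {sorted(missing)}")
        for row in reader:
            seq_id = row["id"].strip()
            if seq_id in tm:
                raise TaxonTableError(f"duplicate id {seq_id!r} in taxon table")
            tm.entries[seq_id] = TaxonEntry(
                phylum=row["phylum"].strip(),
                klass=(row["class"] or "").strip(),
                role=row["role"].strip(),
            )
    if known_ids is not None:
        known = set(known_ids)
        for seq_id in tm.entries:
            if seq_id not in known:
                log.warning("taxon table id %r absent from companion FASTA", seq_id)
    return tm


def write_taxon_table(taxa: TaxonMap, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "phylum", "class", "role"])
        for seq_id, e in taxa.entries.items():
            w.writerow([seq_id, e.phylum, e.klass, e.role])
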