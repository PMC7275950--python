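"""FASTA I/O for UNITE-style fungal ITS reference sequences.

UNITE releases carry, in each FASTA header, an accession, a species-hypothesis
(SH) code — the species-level OTU that serves as the classification unit — and
a seven-rank taxonomy string (``k__Fungi;p__...;s__...``). The exact field
layout drifts between releases, so header parsing goes through a registry of
named dialects rather than a single hard-coded format.

Sequences are normalized on read: uppercased, RNA-style ``U`` mapped to ``T``
(k-mer tokens must be case- and alphabet-stable), IUPAC ambiguity letters kept
verbatim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import FastaError, HeaderFormatError

logger = logging.getLogger(__name__)

RANKS = ("kingdom", "phylum", "class_", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

# uppercase normalization table; U -> T so RNA-style archive entries share the
# DNA token space
_NORMALIZE = str.maketrans(
    "abcdefghijklmnopqrstuvwxyzU", "ABCDEFGHIJKLMNOPQRSTTVWXYZT"
)


@dataclass(frozen=True)
class TaxonomyLineage:
    """A seven-rank taxonomy, kingdom through species, prefixes stripped.

    Empty strings denote missing ranks.
    """

    kingdom: str = ""
    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""

    @property
    def ranks(self) -> tuple[str, ...]:
        return (
            self.kingdom, self.phylum, self.class_, self.order,
            self.family, self.genus, self.species,
        )

    @classmethod
    def parse(cls, text: str) -> "TaxonomyLineage":
        """Parse a semicolon-delimited lineage string.

        Rank prefixes (``k__`` ... ``s__``) are stripped positionally; a string
        with fewer than seven fields parses with trailing ranks empty.
        """
        parts = [p.strip() for p in text.split(";")] if text.strip() else []
        if len(parts) > len(RANKS):
            raise HeaderFormatError(
                f"lineage has {len(parts)} fields, expected at most {len(RANKS)}: {text!r}"
            )
        values = []
        for i, prefix in enumerate(RANK_PREFIXES):
            part = parts[i] if i < len(parts) else ""
            if part.startswith(prefix):
                part = part[len(prefix):]
            values.append(part)
        return cls(*values)

    def format(self) -> str:
        """Canonical form: all seven ranks, prefixed, semicolon-joined."""
        return ";".join(p + r for p, r in zip(RANK_PREFIXES, self.ranks))


@dataclass(frozen=True)
class SequenceRecord:
    """One barcode sequence with its accession, SH code, and taxonomy."""

    accession: str
    sh_code: str
    lineage: TaxonomyLineage
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


def normalize_sequence(sequence: str) -> str:
    """Uppercase and map U->T. Idempotent; IUPAC ambiguity letters pass through."""
    return sequence.translate(_NORMALIZE)


@dataclass(frozen=True)
class Dialect:
    """A pipe-delimited header layout: which field holds what.

    ``filler`` supplies constant values for fields (e.g. a reference-count
    column) that the record model does not carry, so headers can be
    regenerated on write.
    """

    name: str
    n_fields: int
    accession_field: int = 0
    sh_field: int = 1
    lineage_field: int = 2
    filler: tuple[tuple[int, str], ...] = field(default=())

    def parse(self, header: str) -> tuple[str, str, TaxonomyLineage]:
        parts = header.split("|")
        if len(parts) != self.n_fields:
            raise HeaderFormatError(
                f"header has {len(parts)} '|'-delimited fields, dialect "
                f"{self.name!r} expects {self.n_fields}: {header!r}"
            )
        return (
            parts[self.accession_field].strip(),
            parts[self.sh_field].strip(),
            TaxonomyLineage.parse(parts[self.lineage_field]),
        )

    def format(self, record: SequenceRecord) -> str:
        parts = [""] * self.n_fields
        parts[self.accession_field] = record.accession
        parts[self.sh_field] = record.sh_code
        parts[self.lineage_field] = record.lineage.format()
        for i, value in self.filler:
            parts[i] = value
        return "|".join(parts)


#: Registered header dialects. "unite" (accession|SH|lineage) is the default;
#: "sh-general" mimics the four-field layout of UNITE sh_general releases
#: (accession|SH|refcount|lineage) with the reference count discarded on parse.
DIALECTS: dict[str, Dialect] = {}


def register_dialect(dialect: Dialect) -> None:
    DIALECTS[dialect.name] = dialect


register_dialect(Dialect("unite", n_fields=3))
register_dialect(
    Dialect("sh-general", n_fields=4, sh_field=1, lineage_field=3,
            filler=((2, "reps"),))
)

DEFAULT_DIALECT = "unite"


def get_dialect(name: str) -> Dialect:
    try:
        return DIALECTS[name]
    except KeyError:
        raise HeaderFormatError(
            f"unknown header dialect {name!r}; registered: {sorted(DIALECTS)}"
        ) from None


def parse_unite_header(
    header: str, dialect: str | Dialect = DEFAULT_DIALECT
) -> tuple[str, str, TaxonomyLineage]:
    """Split a header (without leading '>') into accession, SH code, lineage."""
    if isinstance(dialect, str):
        dialect = get_dialect(dialect)
    return dialect.parse(header)


def format_unite_header(
    record: SequenceRecord, dialect: str | Dialect = DEFAULT_DIALECT
) -> str:
    if isinstance(dialect, str):
        dialect = get_dialect(dialect)
    return dialect.format(record)


def _line_of_header(path: Path, header: str) -> int | None:
    """1-based line number of the FASTA header line, for error messages."""
    needle = ">" + header
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.rstrip("\n") == needle:
                return lineno
    return None


def read_fasta(
    path: str | Path,
    dialect: str | Dialect = DEFAULT_DIALECT,
    on_error: Literal["raise", "skip"] = "raise",
) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, preserving file order.

    Parameters
    ----------
    path:
        FASTA file; multi-line sequences are concatenated.
    dialect:
        Registered header dialect name (or a Dialect instance).
    on_error:
        ``"raise"`` aborts on the first malformed header or empty sequence,
        reporting the offending line; ``"skip"`` drops the record with a
        logged warning.
    """
    path = Path(path)
    if isinstance(dialect, str):
        dialect = get_dialect(dialect)
    records: list[SequenceRecord] = []
    with open(path) as handle:
        for header, raw_seq in SimpleFastaParser(handle):
            try:
                accession, sh_code, lineage = dialect.parse(header)
                sequence = normalize_sequence(raw_seq.replace(" ", ""))
                if not sequence:
                    raise FastaError(f"empty sequence for header {header!r}")
            except (HeaderFormatError, FastaError) as exc:
                lineno = _line_of_header(path, header)
                where = f"line {lineno}" if lineno is not None else "unknown line"
                if on_error == "skip":
                    logger.warning("skipping record at %s: %s", where, exc)
                    continue
                raise type(exc)(f"{path}:{where}: {exc}") from None
            records.append(
                SequenceRecord(accession=accession, sh_code=sh_code,
                               lineage=lineage, sequence=sequence)
            )
    return records


def write_fasta(
    records: Iterable[SequenceRecord],
    path: str | Path,
    line_width: int = 60,
    dialect: str | Dialect = DEFAULT_DIALECT,
) -> None:
    """Write records as FASTA, regenerating headers in the chosen dialect."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    if isinstance(dialect, str):
        dialect = get_dialect(dialect)
    with open(path, "w") as handle:
        for record in records:
            handle.write(">" + dialect.format(record) + "\n")
            seq = record.sequence
            for start in range(0, len(seq), line_width):
                handle.write(seq[start:start + line_width] + "\n")
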