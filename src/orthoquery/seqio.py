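"""FASTA input/output and pipe-delimited protein header parsing.

Proteome dumps from genome portals label each protein with a compact,
pipe-delimited header such as ``jgi|ChlNC64A|41714|8``: a source tag for the
hosting database, a short species identification code, a numeric protein
identifier (unique only within a species) and, optionally, an ortholog-group
number. Two positional conventions for the last two fields occur in the wild,
so the field order is configuration (see :data:`FIELD_ORDERS`), not code.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

#: Amino-acid alphabet; ambiguity codes X/B/Z and selenocysteine U tolerated.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
TOLERATED = set(AMINO_ACIDS) | set("XBZU*")

#: Named presets for the positional meaning of pipe-separated header fields.
#: ``species_protein_group`` is the default: tag|species|protein|group.
FIELD_ORDERS = {
    "species_protein_group": ("source_tag", "species_code", "protein_id", "group_id"),
    "species_group_protein": ("source_tag", "species_code", "group_id", "protein_id"),
}
DEFAULT_FIELD_ORDER = "species_protein_group"


class FastaFormatError(ValueError):
    """Raised when a FASTA file violates the format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence plus its parsed header fields.

    ``raw_header`` is kept verbatim so that writing the record back to FASTA
    is byte-identical to the input. The structured fields are best-effort:
    headers that do not follow the pipe convention leave them all ``None``.
    """

    raw_header: str
    sequence: str
    source_tag: str | None = None
    species_code: str | None = None
    protein_id: str | None = None
    group_id: str | None = None
    origin_file: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FastaFormatError(f"record {self.raw_header!r} has an empty sequence")
        if "-" in self.sequence:
            raise FastaFormatError(f"record {self.raw_header!r} contains gap characters")

    @property
    def key(self) -> tuple[str | None, str | None]:
        """(species_code, protein_id) pair used to join against group tables."""
        return (self.species_code, self.protein_id)

    def with_header(self, header: str, field_order: str = DEFAULT_FIELD_ORDER) -> "ProteinRecord":
        tag, sp, pid, gid = parse_label(header, field_order=field_order)
        return replace(self, raw_header=header, source_tag=tag, species_code=sp,
                       protein_id=pid, group_id=gid)


def parse_label(header: str, field_order: str = DEFAULT_FIELD_ORDER
                ) -> tuple[str | None, str | None, str | None, str | None]:
    """Split a pipe-delimited header into (source_tag, species_code, protein_id, group_id).

    Lenient: fields are whitespace-stripped; headers without a pipe separator
    yield all-``None`` (the raw header is still usable as a label). Missing
    trailing fields (e.g. no group number) are ``None``.
    """
    order = FIELD_ORDERS[field_order]
    parts = [p.strip() for p in header.split("|")]
    if len(parts) < 2:  # no pipe separator: not the convention
        return (None, None, None, None)
    out: dict[str, str | None] = {k: None for k in ("source_tag", "species_code", "protein_id", "group_id")}
    for name, value in zip(order, parts):
        out[name] = value if value != "" else None
    return (out["source_tag"], out["species_code"], out["protein_id"], out["group_id"])


def render_label(source_tag: str | None, species_code: str | None, protein_id: str | None,
                 group_id: str | None, field_order: str = DEFAULT_FIELD_ORDER) -> str:
    """Inverse of :func:`parse_label` for headers that matched the convention."""
    order = FIELD_ORDERS[field_order]
    values = {"source_tag": source_tag, "species_code": species_code,
              "protein_id": protein_id, "group_id": group_id}
    parts = [values[name] for name in order]
    while parts and parts[-1] is None:
        parts.pop()
    return "|".join("" if p is None else p for p in parts)


def _make_record(header: str, seq: str, origin: str, field_order: str) -> ProteinRecord:
    seq = seq.upper()
    if seq.endswith("*"):  # trailing stop codon marker, common in proteome dumps
        seq = seq[:-1]
    if not seq:
        raise FastaFormatError(f"record {header!r} has an empty sequence")
    bad = set(seq) - TOLERATED
    if bad:
        logger.warning("record %r contains non-standard residues %s (kept)", header, sorted(bad))
    tag, sp, pid, gid = parse_label(header, field_order=field_order)
    return ProteinRecord(raw_header=header, sequence=seq, source_tag=tag,
                         species_code=sp, protein_id=pid, group_id=gid, origin_file=origin)


def read_fasta(path: str | Path, field_order: str = DEFAULT_FIELD_ORDER) -> list[ProteinRecord]:
    """Read a protein FASTA file into an ordered list of :class:`ProteinRecord`.

    Sequences are uppercased and a single trailing ``*`` is stripped; duplicate
    headers within one file are kept but logged. An empty file (or one with no
    ``>`` lines) raises :class:`FastaFormatError`.
    """
    path = Path(path)
    origin = path.name
    with open(path) as fh:
        first = fh.read(1)
        if first not in ("", ">", ";") and first.strip():
            raise FastaFormatError(f"{path}: sequence data before any '>' header line")
        fh.seek(0)
        records = [_make_record(title, seq, origin, field_order)
                   for title, seq in SimpleFastaParser(fh)]
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.raw_header] = seen.get(rec.raw_header, 0) + 1
    for header, n in seen.items():
        if n > 1:
            logger.warning("%s: header %r occurs %d times", path, header, n)
    return records


def read_fasta_dir(directory: str | Path, pattern: str = "*.fa*",
                   field_order: str = DEFAULT_FIELD_ORDER) -> dict[str, list[ProteinRecord]]:
    """Read every proteome FASTA in a directory, keyed by file stem (species code)."""
    directory = Path(directory)
    files = sorted(directory.glob(pattern)) or sorted(
        p for p in directory.iterdir() if p.is_file())
    proteomes: dict[str, list[ProteinRecord]] = {}
    for path in files:
        proteomes[path.stem] = read_fasta(path, field_order=field_order)
    if not proteomes:
        raise FastaFormatError(f"{directory}: no proteome files found")
    return proteomes


def write_fasta(records: Sequence[ProteinRecord], path: str | Path, wrap: int = 60) -> Path:
    """Write records to FASTA; ``read_fasta(write_fasta(r))`` round-trips exactly."""
    if not records:
        raise ValueError("cannot write an empty record collection")
    if wrap < 1:
        raise ValueError("wrap must be a positive integer")
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.raw_header}\n")
            for i in range(0, len(rec.sequence), wrap):
                fh.write(rec.sequence[i:i + wrap] + "\n")
    return path


def unique_keys(records: Iterable[ProteinRecord]) -> dict[tuple[str, str], ProteinRecord]:
    """Index records by (species_code, protein_id); duplicates get '#n' suffixes."""
    index: dict[tuple[str, str], ProteinRecord] = {}
    counts: dict[tuple[str, str], int] = {}
    for rec in records:
        sp = rec.species_code if rec.species_code is not None else rec.origin_file
        pid = rec.protein_id if rec.protein_id is not None else rec.raw_header
        k = (sp, pid)
        n = counts.get(k, 0)
        counts[k] = n + 1
        if n:
            logger.warning("duplicate key %s disambiguated with suffix #%d", k, n)
            k = (sp, f"{pid}#{n}")
        index[k] = rec
    return index
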