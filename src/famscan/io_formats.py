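"""Readers and writers for the external formats the pipeline touches.

Sequence data travels as :class:`SequenceRecord`, gene coordinates as
:class:`GeneModel` and domain-table rows as :class:`DomainHit`.  Genomic
coordinates are converted to 0-based half-open at the parser boundary and
back to 1-based inclusive on writing (GFF3) — no other module performs
coordinate arithmetic across conventions.  Protein coordinates in
:class:`DomainHit` stay 1-based inclusive, as printed by HMMER.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, TextIO

import yaml

logger = logging.getLogger("famscan")

# "-" is admitted so aligned FASTA (MSA input) parses under the same rules
NUCLEOTIDE_ALPHABET = frozenset("ACGTUN-")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*-")

_ALPHABETS = {
    "nucleotide": NUCLEOTIDE_ALPHABET,
    "protein": PROTEIN_ALPHABET,
}


class FormatError(ValueError):
    """Malformed input in one of the supported text formats."""


@dataclass
class SequenceRecord:
    """One FASTA entry: whitespace-free id, free-text description, residues."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid sequence id {self.id!r}")
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A gene locus. ``start``/``end`` are 0-based half-open on ``seq_id``."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: bad interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


@dataclass
class DomainHit:
    """One domain match on a protein (coordinates 1-based inclusive)."""

    protein_id: str
    domain_name: str
    evalue: float
    ali_start: int
    ali_end: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"{self.protein_id}: negative E-value")
        if self.ali_start > self.ali_end:
            raise ValueError(
                f"{self.protein_id}: ali_start {self.ali_start} > ali_end {self.ali_end}"
            )


def _as_lines(stream: str | TextIO) -> list[str]:
    if isinstance(stream, str):
        return stream.splitlines()
    return stream.read().splitlines()


# ---------------------------------------------------------------------------
# FASTA


def parse_fasta(
    stream: str | TextIO,
    alphabet: str = "protein",
    strict: bool = True,
) -> list[SequenceRecord]:
    """Parse FASTA text into records, preserving input order.

    ``alphabet`` is ``"protein"`` or ``"nucleotide"``; in strict mode an
    illegal residue is an error naming the record and 1-based position, and
    duplicate ids are an error.  In lax mode duplicates are disambiguated by
    suffixing ``_2``, ``_3`` ... (redundancy is then detected downstream).
    """
    if alphabet not in _ALPHABETS:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    allowed = _ALPHABETS[alphabet]
    lines = _as_lines(stream)
    if not any(line.strip() for line in lines):
        raise FormatError("empty FASTA stream")

    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"record {header.split()[0]!r} has an empty sequence")
        ident, _, desc = header.partition(" ")
        if ident in seen:
            if strict:
                raise FormatError(f"duplicate FASTA id {ident!r}")
            seen[ident] += 1
            ident = f"{ident}_{seen[ident]}"
            seen.setdefault(ident, 1)
        else:
            seen[ident] = 1
        if strict:
            for pos, c in enumerate(seq, start=1):
                if c not in allowed:
                    raise FormatError(
                        f"illegal {alphabet} residue {c!r} in record "
                        f"{ident!r} at position {pos}"
                    )
        records.append(SequenceRecord(ident, seq, desc.strip()))
        header, chunks = None, []

    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            if not header:
                raise FormatError("FASTA header with no id")
        else:
            if header is None:
                raise FormatError("sequence line before any FASTA header")
            chunks.append(line.upper())
    flush()
    return records


def write_fasta(
    records: Iterable[SequenceRecord], handle: TextIO | None = None, wrap: int = 60
) -> str:
    """Write records as FASTA (fixed 60-column wrap); returns the text."""
    out = io.StringIO()
    for rec in records:
        head = f">{rec.id} {rec.description}".rstrip()
        out.write(head + "\n")
        for i in range(0, len(rec.sequence), wrap):
            out.write(rec.sequence[i : i + wrap] + "\n")
    text = out.getvalue()
    if handle is not None:
        handle.write(text)
    return text


# ---------------------------------------------------------------------------
# GFF3


def parse_gff3(stream: str | TextIO) -> list[GeneModel]:
    """Parse GFF3, keeping rows of type ``gene`` (ID attribute required)."""
    models: list[GeneModel] = []
    for lineno, line in enumerate(_as_lines(stream), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise FormatError(f"GFF3 line {lineno}: expected 9 columns, got {len(cols)}")
        seq_id, _, ftype, start_s, end_s, _, strand, _, attrs = cols
        if ftype != "gene":
            continue
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise FormatError(f"GFF3 line {lineno}: non-integer coordinates") from None
        if start > end:
            raise FormatError(f"GFF3 line {lineno}: start {start} > end {end}")
        gene_id = None
        for item in attrs.split(";"):
            key, _, value = item.strip().partition("=")
            if key == "ID" and value:
                gene_id = value
                break
        if gene_id is None:
            raise FormatError(f"GFF3 line {lineno}: gene row lacks an ID attribute")
        # 1-based inclusive -> 0-based half-open.
        models.append(GeneModel(gene_id, seq_id, start - 1, end, strand))
    return models


def write_gff3(models: Iterable[GeneModel], handle: TextIO | None = None) -> str:
    """Write gene models as GFF3 (coordinates back to 1-based inclusive)."""
    out = io.StringIO()
    out.write("##gff-version 3\n")
    for m in models:
        out.write(
            "\t".join(
                [
                    m.seq_id,
                    "famscan",
                    "gene",
                    str(m.start + 1),
                    str(m.end),
                    ".",
                    m.strand,
                    ".",
                    f"ID={m.gene_id}",
                ]
            )
            + "\n"
        )
    text = out.getvalue()
    if handle is not None:
        handle.write(text)
    return text


def write_bed(models: Iterable[GeneModel], handle: TextIO | None = None) -> str:
    """BED6 export; BED is natively 0-based half-open so no conversion."""
    out = io.StringIO()
    for m in models:
        out.write(
            f"{m.seq_id}\t{m.start}\t{m.end}\t{m.gene_id}\t0\t{m.strand}\n"
        )
    text = out.getvalue()
    if handle is not None:
        handle.write(text)
    return text


# ---------------------------------------------------------------------------
# HMMER domain tables


def default_domain_map() -> dict[str, str]:
    """Packaged Pfam accession -> {NBD, TMD} normalization table."""
    with resources.files("famscan.data").joinpath("pfam_domain_map.yaml").open() as fh:
        return dict(yaml.safe_load(fh))


def parse_domtblout(
    stream: str | TextIO, accession_map: Mapping[str, str] | None = None
) -> list[DomainHit]:
    """Parse a HMMER3 ``--domtblout`` table (or the condensed 5-column form).

    Full 23+-column rows are read as hmmsearch output (target = protein,
    query accession = Pfam model, i-Evalue, ali coordinates).  Rows with
    exactly 5 whitespace-separated fields are read as
    ``protein accession evalue ali_start ali_end``.  Accessions are mapped to
    {NBD, TMD}; rows with unmapped accessions are dropped (count logged).
    """
    if accession_map is None:
        accession_map = default_domain_map()
    hits: list[DomainHit] = []
    dropped = 0
    for lineno, line in enumerate(_as_lines(stream), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tok = line.split()
        if len(tok) >= 23:
            protein, acc, ev_s, start_s, end_s = tok[0], tok[4], tok[12], tok[17], tok[18]
        elif len(tok) == 5:
            protein, acc, ev_s, start_s, end_s = tok
        else:
            raise FormatError(
                f"domain table line {lineno}: expected 5 or >=23 fields, got {len(tok)}"
            )
        acc = acc.split(".")[0]  # strip Pfam version suffix
        try:
            evalue = float(ev_s)
        except ValueError:
            raise FormatError(
                f"domain table line {lineno}: non-numeric E-value {ev_s!r}"
            ) from None
        if evalue < 0:
            raise FormatError(f"domain table line {lineno}: negative E-value")
        try:
            ali_start, ali_end = int(start_s), int(end_s)
        except ValueError:
            raise FormatError(
                f"domain table line {lineno}: non-integer alignment coordinates"
            ) from None
        domain = accession_map.get(acc)
        if domain is None:
            dropped += 1
            continue
        hits.append(DomainHit(protein, domain, evalue, ali_start, ali_end))
    if dropped:
        logger.info("parse_domtblout: dropped %d rows with unmapped accessions", dropped)
    return hits


def write_domtblout(hits: Iterable[DomainHit], handle: TextIO | None = None) -> str:
    """Write hits in the condensed 5-column form parse_domtblout accepts."""
    inverse = {"NBD": "PF00005", "TMD": "PF00664"}
    out = io.StringIO()
    for h in hits:
        out.write(
            f"{h.protein_id}\t{inverse.get(h.domain_name, h.domain_name)}\t"
            f"{h.evalue:.3g}\t{h.ali_start}\t{h.ali_end}\n"
        )
    text = out.getvalue()
    if handle is not None:
        handle.write(text)
    return text
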