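"""Promoter extraction and degenerate cis-element scanning.

Promoters are the 1,500 bp (configurable) upstream of the translation
start, reported 5'→3' relative to the gene: for minus-strand genes the
downstream flank is reverse-complemented.  Scanning uses IUPAC degenerate
patterns (R = A/G, W = A/T, ...) from a packaged 23-element catalog of
signals shared by all family promoters; every overlapping occurrence on
the requested strands is reported, minus-strand hits with forward
coordinates.  An N in the scanned sequence is matched only by a pattern N.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import GeneModel, SequenceRecord

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifDefinition:
    name: str
    signal: str
    site_id: str = ""
    annotation: str = ""

    def __post_init__(self) -> None:
        if not self.signal:
            raise ValueError(f"motif {self.name!r} has an empty signal")
        for c in self.signal:
            if c not in IUPAC:
                raise ValueError(f"motif {self.name!r}: illegal IUPAC letter {c!r}")


@dataclass
class MotifHit:
    motif: str
    promoter_id: str
    start: int  # 1-based, forward orientation of the promoter
    strand: str
    match: str  # forward-orientation substring


@dataclass
class Promoter:
    """An extracted upstream region, 5'→3' relative to its gene."""

    id: str
    sequence: str
    truncated: bool = False


@dataclass
class PromoterConfig:
    upstream_length: int = 1500

    def __post_init__(self) -> None:
        if self.upstream_length <= 0:
            raise ValueError("upstream_length must be positive")


def load_catalog(path=None) -> list[MotifDefinition]:
    """The packaged cis-element catalog (or a user TSV in the same schema)."""
    if path is None:
        src = resources.files("famscan.data").joinpath("cis_element_catalog.tsv")
        with src.open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return [
        MotifDefinition(r["name"], r["signal"], r.get("site_id", ""), r.get("annotation", ""))
        for _, r in df.iterrows()
    ]


def compile_iupac(signal: str) -> re.Pattern:
    """Overlap-reporting regex for an IUPAC pattern.

    Each pattern letter becomes the character class of its A/C/G/T
    expansion; pattern N additionally admits a literal N in the sequence.
    """
    classes = []
    for c in signal.upper():
        if c not in IUPAC:
            raise ValueError(f"illegal IUPAC letter {c!r} in pattern {signal!r}")
        expansion = IUPAC[c] + ("N" if c == "N" else "")
        classes.append(f"[{expansion}]")
    return re.compile(r"(?=(" + "".join(classes) + r"))")


def scan_promoters(
    promoters: Iterable[Promoter | SequenceRecord],
    catalog: Sequence[MotifDefinition],
    strands: str = "both",
) -> list[MotifHit]:
    """Every occurrence of every catalog signal, overlapping allowed.

    ``strands`` is ``"+"``, ``"-"`` or ``"both"``.  Minus-strand hits are
    found by scanning the reverse-complemented pattern on the forward
    sequence, so their coordinates and matched substrings are reported in
    forward orientation.
    """
    if strands not in ("+", "-", "both"):
        raise ValueError("strands must be '+', '-' or 'both'")
    want = ("+", "-") if strands == "both" else (strands,)
    compiled = []
    for motif in catalog:
        fwd = compile_iupac(motif.signal)
        rev = compile_iupac(reverse_complement(motif.signal))
        compiled.append((motif.name, fwd, rev))
    hits: list[MotifHit] = []
    for prom in promoters:
        seq = prom.sequence.upper()
        for name, fwd, rev in compiled:
            if "+" in want:
                for m in fwd.finditer(seq):
                    hits.append(MotifHit(name, prom.id, m.start() + 1, "+", m.group(1)))
            if "-" in want:
                for m in rev.finditer(seq):
                    hits.append(MotifHit(name, prom.id, m.start() + 1, "-", m.group(1)))
    hits.sort(key=lambda h: (h.promoter_id, h.start, h.motif))
    return hits


def extract_promoter(
    gene: GeneModel,
    genome: Mapping[str, SequenceRecord],
    cfg: PromoterConfig | None = None,
) -> Promoter:
    """Upstream region of one gene, truncated at contig bounds if needed."""
    cfg = cfg or PromoterConfig()
    if gene.seq_id not in genome:
        raise KeyError(f"gene {gene.gene_id}: contig {gene.seq_id!r} not in genome")
    contig = genome[gene.seq_id].sequence
    length = cfg.upstream_length
    if gene.strand == "+":
        lo = max(0, gene.start - length)
        seq = contig[lo : gene.start]
        truncated = gene.start < length
    else:
        seq = reverse_complement(contig[gene.end : gene.end + length])
        truncated = len(contig) - gene.end < length
    if not seq:
        raise ValueError(f"gene {gene.gene_id}: zero upstream bases at contig edge")
    return Promoter(f"{gene.gene_id}_promoter", seq, truncated)


def extract_promoters(
    genes: Iterable[GeneModel],
    genome_records: Iterable[SequenceRecord],
    cfg: PromoterConfig | None = None,
) -> list[Promoter]:
    genome = {rec.id: rec for rec in genome_records}
    return [extract_promoter(g, genome, cfg) for g in genes]


def common_elements(
    hits: Iterable[MotifHit], groups: Mapping[str, Sequence[str]]
) -> set[str]:
    """Motif names present (>= 1 hit) in every promoter of every group."""
    if not groups:
        raise ValueError("no promoter groups supplied")
    present: dict[str, set[str]] = {}
    for hit in hits:
        present.setdefault(hit.promoter_id, set()).add(hit.motif)
    result: set[str] | None = None
    for group, promoter_ids in groups.items():
        if not promoter_ids:
            raise ValueError(f"group {group!r} is empty")
        for pid in promoter_ids:
            names = present.get(pid, set())
            result = names.copy() if result is None else (result & names)
    return result or set()
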