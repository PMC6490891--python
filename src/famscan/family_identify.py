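"""Family membership filtering, subfamily assignment and systematic naming.

Candidates are proteins carrying at least one nucleotide-binding-domain
(NBD) hit at E-value <= 1e-5 (the threshold is inclusive: the exclusion
rule drops hits *above* the cutoff).  Redundant entries — identical
sequences, or isoforms of one locus — are collapsed to a single survivor.
Subfamilies (A–G, I) are assigned by the best-scoring global alignment
against a labeled reference set, and gene symbols
``<prefix>ABC<subfamily><index>`` are numbered along the chromosomes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .io_formats import DomainHit, GeneModel, SequenceRecord
from .pairwise_align import AlignParams, global_align

logger = logging.getLogger("famscan")

SUBFAMILY_LETTERS = frozenset("ABCDEFGI")
DEFAULT_EVALUE_MAX = 1e-5

_LABEL_RE = re.compile(r"subfamily=([A-GI])\b")


@dataclass
class FamilyMember:
    protein_id: str
    species_prefix: str
    evidence: list[DomainHit] = field(default_factory=list)
    subfamily: str | None = None
    symbol: str | None = None

    @property
    def n_nbd(self) -> int:
        return sum(1 for h in self.evidence if h.domain_name == "NBD")

    @property
    def n_tmd(self) -> int:
        return sum(1 for h in self.evidence if h.domain_name == "TMD")

    @property
    def best_evalue(self) -> float:
        return min(h.evalue for h in self.evidence)


@dataclass
class ReferenceSet:
    """Labeled reference proteins, one subfamily letter per record."""

    records: list[tuple[SequenceRecord, str]]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("reference set is empty")
        for _, label in self.records:
            if label not in SUBFAMILY_LETTERS:
                raise ValueError(f"unknown subfamily label {label!r}")

    @classmethod
    def from_fasta(cls, records: list[SequenceRecord]) -> "ReferenceSet":
        """Labels read from a ``subfamily=X`` token in each description."""
        labeled = []
        for rec in records:
            m = _LABEL_RE.search(rec.description)
            if not m:
                raise ValueError(f"reference {rec.id!r} lacks a subfamily=X label")
            labeled.append((rec, m.group(1)))
        return cls(labeled)


def locus_id(protein_id: str) -> str:
    """Locus identifier with any trailing isoform suffix ``.N`` removed."""
    return re.sub(r"\.\d+$", "", protein_id)


def filter_candidates(
    hits: list[DomainHit],
    proteins: list[SequenceRecord],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    species_prefix: str | None = None,
) -> list[FamilyMember]:
    """Keep proteins with an NBD hit at E <= ``evalue_max``; drop redundancy.

    Redundancy: proteins sharing a locus id, or with byte-identical
    sequences, are collapsed keeping the longest (ties: lexicographically
    smallest id).  Output is sorted by protein id, so the result is
    invariant to input order.
    """
    seq_by_id = {rec.id: rec for rec in proteins}
    by_protein: dict[str, list[DomainHit]] = {}
    for hit in hits:
        if hit.protein_id not in seq_by_id:
            raise KeyError(
                f"domain hit references protein {hit.protein_id!r} absent from the FASTA"
            )
        by_protein.setdefault(hit.protein_id, []).append(hit)

    kept = {
        pid: phits
        for pid, phits in by_protein.items()
        if any(h.domain_name == "NBD" and h.evalue <= evalue_max for h in phits)
    }

    def survivor(ids: list[str]) -> str:
        return min(ids, key=lambda i: (-len(seq_by_id[i].sequence), i))

    # collapse isoforms of one locus, then exact-duplicate sequences
    by_locus: dict[str, list[str]] = {}
    for pid in kept:
        by_locus.setdefault(locus_id(pid), []).append(pid)
    stage1 = {survivor(ids) for ids in by_locus.values()}
    by_seq: dict[str, list[str]] = {}
    for pid in stage1:
        by_seq.setdefault(seq_by_id[pid].sequence, []).append(pid)
    survivors = sorted(survivor(ids) for ids in by_seq.values())

    members = []
    for pid in survivors:
        prefix = species_prefix if species_prefix is not None else pid[:2]
        members.append(
            FamilyMember(pid, prefix, sorted(kept[pid], key=lambda h: h.ali_start))
        )
    return members


def assign_subfamily(
    query: SequenceRecord, refs: ReferenceSet, params: AlignParams | None = None
) -> tuple[str, float]:
    """Label of the best-scoring reference; score ties go to the smallest id."""
    if not query.sequence:
        raise ValueError("empty query sequence")
    best: tuple[float, str, str] | None = None
    for rec, label in sorted(refs.records, key=lambda r: r[0].id):
        score = global_align(query, rec, params).score
        if best is None or score > best[0]:
            best = (score, rec.id, label)
    assert best is not None
    return best[2], best[0]


def classify_members(
    members: list[FamilyMember],
    proteins: list[SequenceRecord],
    refs: ReferenceSet,
    params: AlignParams | None = None,
) -> list[FamilyMember]:
    """Set ``subfamily`` on every member by nearest labeled reference."""
    seq_by_id = {rec.id: rec for rec in proteins}
    for m in members:
        m.subfamily, _ = assign_subfamily(seq_by_id[m.protein_id], refs, params)
    return members


def assign_names(
    members: list[FamilyMember],
    gene_models: list[GeneModel],
    anchored_pattern: str = r"(?i)^chr",
) -> list[FamilyMember]:
    """Assign ``<prefix>ABC<subfamily><i>`` symbols in chromosomal order.

    Within each (species, subfamily) group, genes on anchored sequences
    (``seq_id`` matching ``anchored_pattern``) are numbered first by
    (chromosome, start), then genes on unanchored scaffolds, then members
    without a gene model (warning logged).  Coordinate ties break by
    protein id.
    """
    anchored = re.compile(anchored_pattern)
    model_by_gene = {g.gene_id: g for g in gene_models}

    def sort_key(m: FamilyMember):
        g = model_by_gene.get(m.protein_id) or model_by_gene.get(locus_id(m.protein_id))
        if g is None:
            logger.warning("member %s has no gene model; numbered last", m.protein_id)
            return (2, "", 0, m.protein_id)
        tier = 0 if anchored.search(g.seq_id) else 1
        return (tier, g.seq_id, g.start, m.protein_id)

    groups: dict[tuple[str, str], list[FamilyMember]] = {}
    for m in members:
        if m.subfamily is None:
            raise ValueError(f"member {m.protein_id} has no subfamily; classify first")
        groups.setdefault((m.species_prefix, m.subfamily), []).append(m)
    for (prefix, sub), group in groups.items():
        for idx, m in enumerate(sorted(group, key=sort_key), start=1):
            m.symbol = f"{prefix}ABC{sub}{idx}"
    return members
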