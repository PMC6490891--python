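"""Global pairwise alignment with affine gaps, plus codon-level alignment.

Protein alignments use a BLOSUM62 substitution matrix with gap-open /
gap-extension penalties of 10 and 0.1 (a gap of length k costs
``open + (k-1)*extend``); nucleotide alignments use match/mismatch +2/-3
with the same gap model.  Identity is computed over both-non-gap columns
and coverage against the shorter input sequence — the denominators behind
the ortholog (identity >= 98, coverage >= 70) and paralog (> 70 / > 70)
criteria used elsewhere in the package.

Coding sequences are aligned by translating, aligning the proteins and
expanding each aligned residue back to its codon, so gaps always come in
whole-codon units and the reading frame is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .io_formats import SequenceRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass
class AlignParams:
    """Scoring parameters for global alignment."""

    matrix: str = "BLOSUM62"  # "NUC" selects match/mismatch scoring
    gap_open: float = 10.0
    gap_extend: float = 0.1
    match: float = 2.0
    mismatch: float = -3.0

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    coverage_pct: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")


@dataclass
class CodonAlignment:
    """Gapped CDS pair; gaps in whole-codon units, frame preserved."""

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    identity_pct: float
    coverage_pct: float

    def codons(self) -> list[tuple[str, str]]:
        return [
            (self.aligned_a[i : i + 3], self.aligned_b[i : i + 3])
            for i in range(0, len(self.aligned_a), 3)
        ]


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float,
             match: float, mismatch: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if matrix == "NUC":
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    else:
        aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def _stats(row_a: str, row_b: str, len_a: int, len_b: int) -> tuple[float, float]:
    aligned = matches = 0
    for ca, cb in zip(row_a, row_b):
        if ca != "-" and cb != "-":
            aligned += 1
            if ca == cb:
                matches += 1
    if aligned == 0:
        raise ValueError("alignment has zero both-non-gap columns; identity undefined")
    return 100.0 * matches / aligned, 100.0 * aligned / min(len_a, len_b)


def global_align(
    a: SequenceRecord, b: SequenceRecord, params: AlignParams | None = None
) -> PairwiseAlignment:
    """Optimal affine-gap global alignment of two same-alphabet records.

    Among co-optimal alignments the aligner's first traceback is returned;
    this choice is deterministic for fixed inputs.
    """
    params = params or AlignParams()
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align an empty sequence")
    aligner = _aligner(
        params.matrix, params.gap_open, params.gap_extend, params.match, params.mismatch
    )
    try:
        aln = aligner.align(a.sequence, b.sequence)[0]
    except ValueError as exc:  # letter absent from the substitution matrix
        raise ValueError(
            f"alphabet mismatch aligning {a.id!r} vs {b.id!r}: {exc}"
        ) from exc
    row_a, row_b = str(aln[0]), str(aln[1])
    try:
        identity, coverage = _stats(row_a, row_b, len(a.sequence), len(b.sequence))
    except ValueError:  # optimum aligns nothing: no homology signal at all
        identity = coverage = 0.0
    return PairwiseAlignment(row_a, row_b, float(aln.score), identity, coverage)


def homology_stats(aln: PairwiseAlignment | CodonAlignment) -> tuple[float, float]:
    """(identity %, coverage %) recomputed from the aligned rows."""
    len_a = len(aln.aligned_a.replace("-", ""))
    len_b = len(aln.aligned_b.replace("-", ""))
    return _stats(aln.aligned_a, aln.aligned_b, len_a, len_b)


def _prepare_cds(rec: SequenceRecord) -> tuple[str, str]:
    """Trim one trailing stop, validate frame/stops; return (cds, protein)."""
    seq = rec.sequence.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"{rec.id}: CDS length {len(seq)} is not a multiple of 3")
    if seq[-3:] in STOP_CODONS:
        seq = seq[:-3]
        if not seq:
            raise ValueError(f"{rec.id}: CDS is a lone stop codon")
    protein = str(Seq(seq).translate())
    if "*" in protein:
        pos = protein.index("*")
        raise ValueError(
            f"{rec.id}: internal stop codon at codon {pos + 1} "
            f"(nucleotide {3 * pos + 1})"
        )
    return seq, protein


def codon_align(
    cds_a: SequenceRecord, cds_b: SequenceRecord, params: AlignParams | None = None
) -> CodonAlignment:
    """Protein-guided codon alignment of two coding sequences."""
    seq_a, prot_a = _prepare_cds(cds_a)
    seq_b, prot_b = _prepare_cds(cds_b)
    paln = global_align(
        SequenceRecord(cds_a.id, prot_a), SequenceRecord(cds_b.id, prot_b), params
    )

    def expand(row: str, cds: str) -> str:
        out, i = [], 0
        for c in row:
            if c == "-":
                out.append("---")
            else:
                out.append(cds[i : i + 3])
                i += 3
        return "".join(out)

    row_a = expand(paln.aligned_a, seq_a)
    row_b = expand(paln.aligned_b, seq_b)
    identity, coverage = _stats(row_a, row_b, len(seq_a), len(seq_b))
    return CodonAlignment(cds_a.id, cds_b.id, row_a, row_b, identity, coverage)
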