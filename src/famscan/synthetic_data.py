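"""Seeded synthetic-data generators with machine-readable ground truth.

Each generator emulates the statistical structure one pipeline stage
assumes — proteomes with planted domain architectures, codon pairs diverged
at controlled ω and Ks, promoters with planted cis-elements on motif-free
background, count matrices with known RPKM, and gene models on both strands
for promoter round-trips.  All outputs are byte-identical under a fixed
seed, and every generator returns the truth alongside the data so tests can
compare pipeline output against what was planted.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .architecture_props import TopologyClass
from .cis_regulation import (
    IUPAC,
    MotifDefinition,
    Promoter,
    reverse_complement,
    scan_promoters,
)
from .expression import CountMatrix
from .family_identify import ReferenceSet, SUBFAMILY_LETTERS
from .io_formats import DomainHit, GeneModel, SequenceRecord
from .selection_dating import _SYN_SITES, _aa

_AA = "ACDEFGHIKLMNPQRSTVWY"
_BASES = "ACGT"
_NON_STOP_CODONS = sorted(_SYN_SITES)

_CLASS_DOMAINS = {
    TopologyClass.FULL_FORWARD: ("TMD", "NBD", "TMD", "NBD"),
    TopologyClass.FULL_REVERSE: ("NBD", "TMD", "NBD", "TMD"),
    TopologyClass.HALF_FORWARD: ("TMD", "NBD"),
    TopologyClass.HALF_REVERSE: ("NBD", "TMD"),
    TopologyClass.QUARTER_NBD: ("NBD",),
    TopologyClass.QUARTER_TMD: ("TMD",),
    TopologyClass.ABC2_NBD_NBD: ("NBD", "NBD"),
    TopologyClass.TMD_TMD: ("TMD", "TMD"),
    TopologyClass.UNIQUE: ("NBD", "TMD", "NBD"),
}

_ACCESSION = {"NBD": "PF00005", "TMD": "PF00664"}


@dataclass
class SimSpec:
    """Seed plus per-generator parameters; same spec → identical outputs."""

    seed: int
    params: dict = field(default_factory=dict)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA), size=length))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


# ---------------------------------------------------------------------------
# proteomes with planted architectures


@dataclass
class SimProteome:
    proteins: list[SequenceRecord]
    hits: list[DomainHit]
    gene_models: list[GeneModel]
    truth: pd.DataFrame  # protein_id, planted_class, is_decoy


def gen_proteome(
    class_counts: Mapping[TopologyClass | str, int],
    decoys: int = 0,
    seed: int = 0,
    nbd_len: int = 150,
    tmd_len: int = 120,
    linker_len: int = 25,
) -> SimProteome:
    """Proteome with planted NBD/TMD architectures plus NBD-free decoys.

    Planted proteins get one domain-table row per segment (E-values
    log-uniform in [1e-50, 1e-10]); decoys carry no NBD hit (every second
    decoy gets a TMD-only hit so the NBD requirement, not hit presence, is
    what rejects them).  Genes are placed non-overlapping on two synthetic
    chromosomes, alternating strands.
    """
    rng = np.random.default_rng(seed)
    seg_len = {"NBD": nbd_len, "TMD": tmd_len}
    proteins: list[SequenceRecord] = []
    hits: list[DomainHit] = []
    rows = []

    def evalue() -> float:
        return float(10.0 ** rng.uniform(-50, -10))

    counter = itertools.count(1)
    for cls, count in sorted(class_counts.items(), key=lambda kv: str(kv[0])):
        cls = TopologyClass(cls)
        domains = _CLASS_DOMAINS[cls]
        for _ in range(count):
            pid = f"SYN{next(counter):04d}"
            pos = linker_len
            parts = [_random_protein(rng, linker_len)]
            for dom in domains:
                length = seg_len[dom]
                parts.append(_random_protein(rng, length))
                hits.append(DomainHit(pid, dom, evalue(), pos + 1, pos + length))
                pos += length
                parts.append(_random_protein(rng, linker_len))
                pos += linker_len
            proteins.append(SequenceRecord(pid, "".join(parts)))
            rows.append({"protein_id": pid, "planted_class": cls.value, "is_decoy": False})
    for k in range(decoys):
        pid = f"SYN{next(counter):04d}"
        seq = _random_protein(rng, tmd_len + 2 * linker_len)
        proteins.append(SequenceRecord(pid, seq))
        if k % 2 == 0:
            hits.append(DomainHit(pid, "TMD", evalue(), linker_len + 1, linker_len + tmd_len))
        rows.append({"protein_id": pid, "planted_class": None, "is_decoy": True})

    gene_models = []
    cursors = {"chr01": 5000, "chr02": 5000}
    for i, rec in enumerate(proteins):
        chrom = "chr01" if i % 2 == 0 else "chr02"
        strand = "+" if (i // 2) % 2 == 0 else "-"
        start = cursors[chrom]
        end = start + 3 * len(rec.sequence)
        gene_models.append(GeneModel(rec.id, chrom, start, end, strand))
        cursors[chrom] = end + 2000
    return SimProteome(proteins, hits, gene_models, pd.DataFrame(rows))


def gen_reference_set(
    seed: int = 0, length: int = 300, letters: str = "ABCDEFGI"
) -> ReferenceSet:
    """One random reference protein per subfamily letter."""
    rng = np.random.default_rng(seed)
    records = []
    for letter in letters:
        if letter not in SUBFAMILY_LETTERS:
            raise ValueError(f"unknown subfamily letter {letter!r}")
        rec = SequenceRecord(
            f"REF_{letter}", _random_protein(rng, length), f"subfamily={letter}"
        )
        records.append((rec, letter))
    return ReferenceSet(records)


def mutate_protein(sequence: str, rate: float, seed: int = 0) -> str:
    """Substitute a ``rate`` fraction of residues with different ones."""
    rng = np.random.default_rng(seed)
    chars = list(sequence)
    n_mut = int(round(rate * len(chars)))
    for pos in rng.choice(len(chars), size=n_mut, replace=False):
        chars[pos] = rng.choice([a for a in _AA if a != chars[pos]])
    return "".join(chars)


# ---------------------------------------------------------------------------
# diverged codon pairs


def _evolve_branch(
    codons: list[str], target_syn: float, omega: float, rng: np.random.Generator
) -> tuple[list[str], int, int]:
    """Apply substitutions until ``target_syn`` synonymous events accrued.

    Single-base proposals are uniform over positions and alternative bases;
    stop-creating changes are rejected; synonymous changes are accepted at
    relative rate 1 and non-synonymous at rate ``omega``.
    """
    codons = list(codons)
    syn_events = nonsyn_events = 0
    p_syn = min(1.0, 1.0 / omega) if omega > 0 else 1.0
    p_non = min(1.0, omega)
    max_proposals = int(5000 * (target_syn + 1)) + 20000
    proposals = 0
    while syn_events < target_syn:
        proposals += 1
        if proposals > max_proposals:
            raise RuntimeError(
                "branch evolution did not reach the requested Ks "
                "(saturation); lower ks_true or raise n_codons"
            )
        ci = int(rng.integers(len(codons)))
        pos = int(rng.integers(3))
        codon = codons[ci]
        base = _BASES[int(rng.integers(4))]
        if base == codon[pos]:
            continue
        alt = codon[:pos] + base + codon[pos + 1 :]
        if _aa(alt) == "*":
            continue
        if _aa(alt) == _aa(codon):
            if rng.random() < p_syn:
                codons[ci] = alt
                syn_events += 1
        else:
            if rng.random() < p_non:
                codons[ci] = alt
                nonsyn_events += 1
    return codons, syn_events, nonsyn_events


def gen_diverged_pair(
    n_codons: int, omega_true: float, ks_true: float, seed: int = 0
) -> tuple[SequenceRecord, SequenceRecord, dict]:
    """A CDS pair diverged from a common ancestor at controlled ω and Ks.

    The ancestor evolves along two branches; branch lengths are set so the
    realized synonymous events per synonymous site total ≈ ``ks_true``.
    """
    if n_codons < 50:
        raise ValueError("n_codons must be >= 50")
    if ks_true < 0 or omega_true < 0:
        raise ValueError("omega_true and ks_true must be non-negative")
    rng = np.random.default_rng(seed)
    ancestor = [ _NON_STOP_CODONS[i] for i in rng.integers(len(_NON_STOP_CODONS), size=n_codons) ]
    s_sites = sum(_SYN_SITES[c] for c in ancestor)
    truth = {"omega_true": omega_true, "ks_true": ks_true, "s_sites_ancestor": s_sites}
    if ks_true == 0:
        seq = "".join(ancestor)
        return (
            SequenceRecord("sim_a", seq),
            SequenceRecord("sim_b", seq),
            truth | {"syn_events": 0, "nonsyn_events": 0},
        )
    target = 0.5 * ks_true * s_sites
    codons_a, syn_a, non_a = _evolve_branch(ancestor, target, omega_true, rng)
    codons_b, syn_b, non_b = _evolve_branch(ancestor, target, omega_true, rng)
    truth |= {"syn_events": syn_a + syn_b, "nonsyn_events": non_a + non_b}
    return (
        SequenceRecord("sim_a", "".join(codons_a)),
        SequenceRecord("sim_b", "".join(codons_b)),
        truth,
    )


# ---------------------------------------------------------------------------
# promoters with planted motifs


def _instantiate(signal: str, rng: np.random.Generator) -> str:
    return "".join(IUPAC[c][int(rng.integers(len(IUPAC[c])))] for c in signal)


def _motif_free_background(
    length: int,
    catalog: Sequence[MotifDefinition],
    rng: np.random.Generator,
    max_rounds: int = 500,
) -> str:
    seq = _random_dna(rng, length)
    for _ in range(max_rounds):
        hits = scan_promoters([Promoter("bg", seq)], catalog, strands="both")
        if not hits:
            return seq
        chars = list(seq)
        for hit in hits:
            lo = hit.start - 1
            for k in range(lo, lo + len(hit.match)):
                chars[k] = _BASES[int(rng.integers(4))]
        seq = "".join(chars)
    raise RuntimeError(
        "could not build a motif-free background; use a longer sequence "
        "or a looser catalog"
    )


def gen_promoters(
    n: int,
    length: int,
    catalog: Sequence[MotifDefinition],
    plant: Sequence[str] | str | None = "all",
    seed: int = 0,
) -> tuple[list[Promoter], pd.DataFrame]:
    """Promoters on catalog-free background with planted motif instances.

    ``plant`` names the motifs inserted into *every* promoter ("all" for the
    whole catalog, None for background only).  Degenerate letters are
    instantiated uniformly; strands are random; planted windows do not
    overlap.  Returns the promoters and a truth table
    (promoter, motif, start 1-based forward, strand, match).
    """
    rng = np.random.default_rng(seed)
    by_name = {m.name: m for m in catalog}
    if plant == "all":
        names = [m.name for m in catalog]
    else:
        names = list(plant or [])
        for nm in names:
            if nm not in by_name:
                raise KeyError(f"motif {nm!r} not in catalog")
    need = sum(len(by_name[nm].signal) for nm in names)
    if need > length:
        raise ValueError("planted motifs do not fit in the promoter length")

    promoters: list[Promoter] = []
    rows = []
    for i in range(n):
        pid = f"prom{i + 1:03d}"
        seq = list(_motif_free_background(length, catalog, rng))
        occupied: list[tuple[int, int]] = []
        for nm in names:
            width = len(by_name[nm].signal)
            for _ in range(10000):
                start = int(rng.integers(0, length - width + 1))
                if all(start + width <= lo or start >= hi for lo, hi in occupied):
                    break
            else:
                raise RuntimeError("could not place motifs without overlap")
            occupied.append((start, start + width))
            strand = "+" if rng.random() < 0.5 else "-"
            instance = _instantiate(by_name[nm].signal, rng)
            forward = instance if strand == "+" else reverse_complement(instance)
            seq[start : start + width] = forward
            rows.append(
                {
                    "promoter": pid,
                    "motif": nm,
                    "start": start + 1,
                    "strand": strand,
                    "match": forward,
                }
            )
        promoters.append(Promoter(pid, "".join(seq)))
    return promoters, pd.DataFrame(rows, columns=["promoter", "motif", "start", "strand", "match"])


# ---------------------------------------------------------------------------
# count matrices with known RPKM


def gen_counts(
    rpkm_truth: pd.DataFrame,
    libsizes: pd.Series,
    lengths: pd.Series,
    seed: int = 0,
    mode: str = "deterministic",
) -> CountMatrix:
    """Counts whose RPKM is (up to rounding / Poisson noise) the given truth.

    ``deterministic`` rounds the expected count exactly; ``poisson`` draws
    around it with the given seed.
    """
    if (rpkm_truth.to_numpy() < 0).any():
        raise ValueError("negative RPKM truth")
    expected = rpkm_truth.mul(libsizes, axis=1).mul(lengths, axis=0) / 1e9
    if mode == "deterministic":
        counts = expected.round().astype(int)
    elif mode == "poisson":
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(
            rng.poisson(expected.to_numpy()),
            index=expected.index,
            columns=expected.columns,
        )
    else:
        raise ValueError("mode must be 'deterministic' or 'poisson'")
    return CountMatrix(counts, lengths, libsizes)


# ---------------------------------------------------------------------------
# gene models on both strands for promoter round-trips


@dataclass
class SimGenome:
    genome: list[SequenceRecord]
    gene_models: list[GeneModel]
    upstream_truth: dict[str, str]  # gene_id -> planted promoter (gene 5'→3')


def gen_gene_models(
    n_genes: int, seed: int = 0, upstream: int = 1500, body: int = 600
) -> SimGenome:
    """A synthetic contig with alternating-strand genes and known upstream
    sequences, for promoter-extraction round-trips."""
    rng = np.random.default_rng(seed)
    chunks: list[str] = []
    cursor = 0
    models = []
    truth = {}
    for i in range(n_genes):
        gid = f"gene{i + 1:03d}"
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            up = _random_dna(rng, upstream)
            chunks += [up, _random_dna(rng, body)]
            models.append(GeneModel(gid, "chrS", cursor + upstream, cursor + upstream + body, "+"))
            truth[gid] = up
            cursor += upstream + body
        else:
            down = _random_dna(rng, upstream)
            chunks += [_random_dna(rng, body), down]
            models.append(GeneModel(gid, "chrS", cursor, cursor + body, "-"))
            truth[gid] = reverse_complement(down)
            cursor += body + upstream
        spacer = _random_dna(rng, 100)
        chunks.append(spacer)
        cursor += 100
    genome = [SequenceRecord("chrS", "".join(chunks))]
    return SimGenome(genome, models, truth)
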