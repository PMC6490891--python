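"""Domain-architecture topology classes and protein physicochemical properties.

ABC proteins fall into full-sized ((TMD-NBD)x2 in either orientation),
half-sized (one TMD + one NBD), quarter-sized (a single domain), the
two-NBD "ABC2" arrangement, a rare TMD-TMD arrangement, and a catch-all
UNIQUE class for anything else (e.g. NBD-TMD-NBD).  "Forward" means the
transmembrane domain precedes the nucleotide-binding domain.  Proteins with
no TMD at all are flagged soluble.

Molecular weight uses average residue masses plus one water; the
theoretical pI is the root of the Henderson–Hasselbalch net-charge curve
under the packaged EMBOSS pKa set, found by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from importlib import resources

import yaml
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from scipy.optimize import bisect

from .io_formats import DomainHit


class TopologyClass(str, Enum):
    FULL_FORWARD = "FULL_FORWARD"      # TMD-NBD-TMD-NBD
    FULL_REVERSE = "FULL_REVERSE"      # NBD-TMD-NBD-TMD
    HALF_FORWARD = "HALF_FORWARD"      # TMD-NBD
    HALF_REVERSE = "HALF_REVERSE"      # NBD-TMD
    QUARTER_NBD = "QUARTER_NBD"
    QUARTER_TMD = "QUARTER_TMD"
    ABC2_NBD_NBD = "ABC2_NBD_NBD"
    TMD_TMD = "TMD_TMD"
    UNIQUE = "UNIQUE"


_CANONICAL = {
    ("TMD", "NBD", "TMD", "NBD"): TopologyClass.FULL_FORWARD,
    ("NBD", "TMD", "NBD", "TMD"): TopologyClass.FULL_REVERSE,
    ("TMD", "NBD"): TopologyClass.HALF_FORWARD,
    ("NBD", "TMD"): TopologyClass.HALF_REVERSE,
    ("NBD",): TopologyClass.QUARTER_NBD,
    ("TMD",): TopologyClass.QUARTER_TMD,
    ("NBD", "NBD"): TopologyClass.ABC2_NBD_NBD,
    ("TMD", "TMD"): TopologyClass.TMD_TMD,
}


@dataclass
class Architecture:
    protein_id: str
    domain_string: tuple[str, ...]
    topology_class: TopologyClass
    soluble: bool


@dataclass
class ProteinProps:
    length: int
    mw: float
    pi: float


def classify_topology(domain_string: list[str] | tuple[str, ...]) -> TopologyClass:
    """Map an N→C ordered NBD/TMD string to its topology class."""
    if not domain_string:
        raise ValueError("empty domain string")
    for d in domain_string:
        if d not in ("NBD", "TMD"):
            raise ValueError(f"unknown domain token {d!r}")
    return _CANONICAL.get(tuple(domain_string), TopologyClass.UNIQUE)


def merge_hits(hits: list[DomainHit], overlap_frac: float = 0.5) -> list[DomainHit]:
    """Merge same-type hits overlapping by more than ``overlap_frac`` of the
    shorter hit; output ordered by alignment start."""
    merged: list[DomainHit] = []
    for hit in sorted(hits, key=lambda h: (h.ali_start, h.ali_end)):
        last = merged[-1] if merged else None
        if last is not None and last.domain_name == hit.domain_name:
            overlap = min(last.ali_end, hit.ali_end) - max(last.ali_start, hit.ali_start) + 1
            shorter = min(last.ali_end - last.ali_start, hit.ali_end - hit.ali_start) + 1
            if overlap > overlap_frac * shorter:
                merged[-1] = DomainHit(
                    last.protein_id,
                    last.domain_name,
                    min(last.evalue, hit.evalue),
                    last.ali_start,
                    max(last.ali_end, hit.ali_end),
                )
                continue
        merged.append(hit)
    return merged


def build_architecture(protein_id: str, hits: list[DomainHit]) -> Architecture:
    """Order a protein's merged hits N→C and classify the topology."""
    own = [h for h in hits if h.protein_id == protein_id]
    if not own:
        raise ValueError(f"no domain hits for protein {protein_id!r}")
    domains = tuple(h.domain_name for h in merge_hits(own))
    return Architecture(
        protein_id, domains, classify_topology(domains), "TMD" not in domains
    )


def summarize_topology(architectures: list[Architecture]) -> dict[str, int]:
    """Counts per topology class plus full/half/quarter rollups."""
    if not architectures:
        raise ValueError("no architectures to summarize")
    counts = {cls.value: 0 for cls in TopologyClass}
    for arch in architectures:
        counts[arch.topology_class.value] += 1
    counts["full"] = counts["FULL_FORWARD"] + counts["FULL_REVERSE"]
    counts["half"] = counts["HALF_FORWARD"] + counts["HALF_REVERSE"]
    counts["quarter"] = counts["QUARTER_NBD"] + counts["QUARTER_TMD"]
    counts["soluble"] = sum(1 for a in architectures if a.soluble)
    counts["n"] = len(architectures)
    return counts


# ---------------------------------------------------------------------------
# physicochemical properties

_MW_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")


def compute_mw(sequence: str) -> float:
    """Average molecular weight in Daltons (residue masses + one water)."""
    if not sequence:
        raise ValueError("empty sequence")
    for c in sequence:
        if c not in _MW_ALPHABET:
            raise ValueError(f"unknown amino acid {c!r}")
    return float(ProteinAnalysis(sequence).molecular_weight())


@lru_cache(maxsize=1)
def load_pka_set() -> dict:
    with resources.files("famscan.data").joinpath("pka_emboss.yaml").open() as fh:
        return yaml.safe_load(fh)


def net_charge(sequence: str, ph: float, pka: dict | None = None) -> float:
    """Net protein charge at ``ph`` (termini + D,E,C,Y,H,K,R side chains)."""
    pka = pka or load_pka_set()
    charge = 1.0 / (1.0 + 10 ** (ph - pka["n_terminus"]))
    charge -= 1.0 / (1.0 + 10 ** (pka["c_terminus"] - ph))
    for aa, k in pka["positive"].items():
        charge += sequence.count(aa) / (1.0 + 10 ** (ph - k))
    for aa, k in pka["negative"].items():
        charge -= sequence.count(aa) / (1.0 + 10 ** (k - ph))
    return charge


def compute_pi(sequence: str, pka: dict | None = None, xtol: float = 1e-6) -> float:
    """Theoretical isoelectric point: pH where net charge crosses zero.

    The charge curve is strictly decreasing in pH, so the root on [0, 14]
    is unique; bisection converges unconditionally.
    """
    if not sequence:
        raise ValueError("empty sequence")
    pka = pka or load_pka_set()
    return float(bisect(lambda ph: net_charge(sequence, ph, pka), 0.0, 14.0, xtol=xtol))


def compute_props(sequence: str) -> ProteinProps:
    return ProteinProps(len(sequence), compute_mw(sequence), compute_pi(sequence))
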