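"""Nei–Gojobori (1986) Ka/Ks estimation, selection calls and Ks-clock dating.

Synonymous site counts are fractional: at each codon position the fraction
of the three possible single-base changes that are synonymous (changes
creating a stop codon are excluded from both numerator and denominator)
contributes to S; N = 3 - S per codon, and sites are averaged over the two
sequences.  Differences between codons differing at k positions are
averaged over all k! minimal mutational pathways, excluding pathways that
pass through a stop codon (if every pathway is blocked, all are used).
Proportions p = d/sites are corrected for multiple hits with the
Jukes–Cantor transform d = -(3/4) ln(1 - (4/3) p); p >= 3/4 saturates and
the corresponding rate is reported as +inf with a flag.

ω = Ka/Ks classifies selection (ω > 1 positive, ω < 1 purifying) and the
synonymous clock dates duplications as T = Ks / (2λ) with
λ = 6.96e-9 synonymous substitutions per site per year by default.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources

import networkx as nx
import pandas as pd
from Bio.Data import CodonTable

from .io_formats import SequenceRecord
from .pairwise_align import AlignParams, CodonAlignment, codon_align

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_BASES = "ACGT"


def _aa(codon: str) -> str:
    return "*" if codon in _TABLE.stop_codons else _TABLE.forward_table[codon]


def _syn_sites(codon: str) -> float:
    """Fractional number of synonymous sites in one (non-stop) codon."""
    total = 0.0
    aa0 = _aa(codon)
    for pos in range(3):
        syn = valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if _aa(alt) == "*":
                continue
            valid += 1
            if _aa(alt) == aa0:
                syn += 1
        if valid:
            total += syn / valid
    return total


_SYN_SITES = {
    "".join(c): _syn_sites("".join(c))
    for c in itertools.product(_BASES, repeat=3)
    if _aa("".join(c)) != "*"
}


def _pathway_counts(ca: str, cb: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    over minimal mutational pathways that avoid stop codons."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    results = []
    blocked = []
    for order in itertools.permutations(diff):
        cur, syn, non, ok = ca, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if _aa(nxt) == "*":
                ok = False
            if _aa(nxt) == _aa(cur):
                syn += 1
            else:
                non += 1
            cur = nxt
        (results if ok else blocked).append((syn, non))
    use = results or blocked
    sd = sum(s for s, _ in use) / len(use)
    nd = sum(n for _, n in use) / len(use)
    return sd, nd


_PATHWAYS: dict[tuple[str, str], tuple[float, float]] = {}


class SaturationError(ValueError):
    """Observed proportion of differences exceeds the Jukes–Cantor domain."""


class SelectionCall(str, Enum):
    POSITIVE = "positive"
    PURIFYING = "purifying"
    NEUTRAL = "neutral"
    UNDEFINED = "undefined"


@dataclass
class SiteCounts:
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    compared_codons: int


@dataclass
class SelectionEstimate:
    ka: float
    ks: float
    omega: float | None
    call: SelectionCall
    saturated: bool = False


@dataclass
class DatingParams:
    """Synonymous molecular-clock rate, substitutions per site per year."""

    lambda_: float = 6.96e-9

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ValueError("lambda must be positive")


@dataclass
class HomologyCriteria:
    min_identity: float = 70.0
    min_coverage: float = 70.0
    inclusive: bool = False  # paralog criteria are strict (>), ortholog inclusive


@dataclass
class ParalogPair:
    gene_a: str
    gene_b: str
    identity_pct: float
    coverage_pct: float
    sites: SiteCounts
    estimate: SelectionEstimate
    t_mya: float
    component_size: int = 0
    strongly_connected: bool = False


def _jc_correct(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return math.inf, True
    if p == 0.0:
        return 0.0, False
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p), False


def ng86(
    aln: CodonAlignment, eps: float = 0.0
) -> tuple[SiteCounts, SelectionEstimate]:
    """NG86 site/difference counts and Jukes–Cantor-corrected Ka, Ks, ω.

    Codons containing a gap, a non-ACGT base or a stop in either row are
    skipped entirely (neither sites nor differences counted).
    """
    s_sites = sd = nd = 0.0
    n_codons = 0
    for ca, cb in aln.codons():
        if ca not in _SYN_SITES or cb not in _SYN_SITES:
            continue
        n_codons += 1
        s_sites += 0.5 * (_SYN_SITES[ca] + _SYN_SITES[cb])
        if ca != cb:
            key = (ca, cb) if ca <= cb else (cb, ca)
            if key not in _PATHWAYS:
                _PATHWAYS[key] = _pathway_counts(*key)
            d_s, d_n = _PATHWAYS[key]
            sd += d_s
            nd += d_n
    if n_codons == 0:
        raise ValueError("no comparable codons in the alignment")
    n_sites = 3.0 * n_codons - s_sites
    counts = SiteCounts(s_sites, n_sites, sd, nd, n_codons)

    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks, sat_s = _jc_correct(ps)
    ka, sat_n = _jc_correct(pn)
    omega = ka / ks if (math.isfinite(ka) and math.isfinite(ks) and ks > 0) else None
    est = SelectionEstimate(ka, ks, omega, SelectionCall.UNDEFINED, sat_s or sat_n)
    est.call = classify_selection(est, eps)
    return counts, est


def classify_selection(est: SelectionEstimate, eps: float = 0.0) -> SelectionCall:
    """ω > 1+eps positive; ω < 1-eps purifying; within eps neutral."""
    if est.omega is None or not math.isfinite(est.omega):
        return SelectionCall.UNDEFINED
    if est.omega > 1.0 + eps:
        return SelectionCall.POSITIVE
    if est.omega < 1.0 - eps:
        return SelectionCall.PURIFYING
    return SelectionCall.NEUTRAL


def duplication_time(ks: float, params: DatingParams | None = None) -> float:
    """Ks-clock duplication age in million years: T = Ks / (2λ)."""
    params = params or DatingParams()
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    if not math.isfinite(ks):
        return math.inf
    return ks / (2.0 * params.lambda_) / 1e6


def find_paralog_pairs(
    cds: list[SequenceRecord],
    criteria: HomologyCriteria | None = None,
    align_params: AlignParams | None = None,
    dating: DatingParams | None = None,
    require_strong: bool = False,
) -> list[ParalogPair]:
    """All-vs-all codon alignment; retain pairs passing the coverage and
    identity thresholds (strictly, by default), annotated with Ka/Ks,
    duplication time, and their duplication-graph component.

    A component is "strongly connected" here when it contains at least two
    retained duplication events (edges).
    """
    if len(cds) < 2:
        raise ValueError("need at least two sequences")
    criteria = criteria or HomologyCriteria()
    cmp = (lambda v, t: v >= t) if criteria.inclusive else (lambda v, t: v > t)
    graph = nx.Graph()
    graph.add_nodes_from(rec.id for rec in cds)
    pairs: list[ParalogPair] = []
    for rec_a, rec_b in itertools.combinations(sorted(cds, key=lambda r: r.id), 2):
        aln = codon_align(rec_a, rec_b, align_params)
        if not (
            cmp(aln.identity_pct, criteria.min_identity)
            and cmp(aln.coverage_pct, criteria.min_coverage)
        ):
            continue
        counts, est = ng86(aln)
        pairs.append(
            ParalogPair(
                rec_a.id,
                rec_b.id,
                aln.identity_pct,
                aln.coverage_pct,
                counts,
                est,
                duplication_time(est.ks, dating),
            )
        )
        graph.add_edge(rec_a.id, rec_b.id)
    for comp in nx.connected_components(graph):
        n_edges = graph.subgraph(comp).number_of_edges()
        for pair in pairs:
            if pair.gene_a in comp:
                pair.component_size = len(comp)
                pair.strongly_connected = n_edges >= 2
    pairs.sort(key=lambda p: (p.gene_a, p.gene_b))
    if require_strong:
        pairs = [p for p in pairs if p.strongly_connected]
    return pairs


def pairs_to_frame(pairs: list[ParalogPair]) -> pd.DataFrame:
    rows = [
        {
            "gene_a": p.gene_a,
            "gene_b": p.gene_b,
            "identity_pct": p.identity_pct,
            "coverage_pct": p.coverage_pct,
            "s_sites": p.sites.s_sites,
            "n_sites": p.sites.n_sites,
            "ka": p.estimate.ka,
            "ks": p.estimate.ks,
            "omega": p.estimate.omega,
            "selection": p.estimate.call.value,
            "t_mya": p.t_mya,
            "component_size": p.component_size,
            "strongly_connected": p.strongly_connected,
        }
        for p in pairs
    ]
    return pd.DataFrame(rows)


def load_reference_pairs() -> pd.DataFrame:
    """Packaged 14-row syntenic-paralog reference table (Ka/Ks/ω/T columns)."""
    path = resources.files("famscan.data").joinpath("paralog_pairs.tsv")
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t")


def species_prefix(symbol: str) -> str:
    return symbol[:2]


def summarize_pairs(pairs: pd.DataFrame, eps: float = 0.0) -> dict[str, float]:
    """Column-level summary of a paralog-pair table.

    Expects columns ``gene_a``, ``gene_b``, ``omega``, ``t_mya``.  Selection
    counts are recomputed from ω (not from any label column).  Values are
    returned unrounded.
    """
    if pairs.empty:
        raise ValueError("empty paralog-pair table")
    omega = pairs["omega"].astype(float)
    n = len(pairs)
    n_pos = int((omega > 1.0 + eps).sum())
    n_pur = int((omega < 1.0 - eps).sum())
    same = pairs.apply(
        lambda r: species_prefix(r["gene_a"]) == species_prefix(r["gene_b"]), axis=1
    )
    return {
        "n_pairs": n,
        "mean_omega": float(omega.mean()),
        "min_omega": float(omega.min()),
        "max_omega": float(omega.max()),
        "n_purifying": n_pur,
        "n_positive": n_pos,
        "pct_positive": 100.0 * n_pos / n,
        "mean_t_mya": float(pairs["t_mya"].astype(float).mean()),
        "n_intraspecies": int(same.sum()),
    }
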