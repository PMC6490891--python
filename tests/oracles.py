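"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written naively and directly from the definitions —
explicit enumeration, dense grids, position-by-position scans — and shares
no code with the package internals it checks.
"""

from __future__ import annotations

import itertools
import math

from Bio.Data import CodonTable

_CODE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_CODE.stop_codons)
_BASES = "ACGT"

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T", "N"},
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
         "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
         "B": "V", "V": "B", "D": "H", "H": "D"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def translate_codon(codon: str) -> str:
    return "*" if codon in _STOPS else _CODE.forward_table[codon]


# ---------------------------------------------------------------------------
# NG86 by explicit enumeration


def syn_sites_codon(codon: str) -> float:
    """Fraction-of-changes-synonymous site count for one codon, with
    stop-creating changes excluded from numerator and denominator."""
    aa = translate_codon(codon)
    total = 0.0
    for pos in range(3):
        syn, possible = 0, 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if translate_codon(mutant) == "*":
                continue
            possible += 1
            if translate_codon(mutant) == aa:
                syn += 1
        if possible:
            total += syn / possible
    return total


def pathway_differences(ca: str, cb: str) -> tuple[float, float]:
    """(Sd, Nd) between two codons, averaged over minimal pathways; pathways
    through stop codons are dropped unless all are blocked."""
    positions = [i for i in range(3) if ca[i] != cb[i]]
    clean, blocked = [], []
    for order in itertools.permutations(positions):
        codon, syn, non, through_stop = ca, 0, 0, False
        for pos in order:
            nxt = codon[:pos] + cb[pos] + codon[pos + 1 :]
            if translate_codon(nxt) == "*":
                through_stop = True
            if translate_codon(nxt) == translate_codon(codon):
                syn += 1
            else:
                non += 1
            codon = nxt
        (blocked if through_stop else clean).append((syn, non))
    use = clean if clean else blocked
    return (
        sum(s for s, _ in use) / len(use),
        sum(n for _, n in use) / len(use),
    )


def jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.inf
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def jc_distance_tolerance(p: float) -> float:
    """Comparison tolerance for a Jukes–Cantor distance at proportion ``p``.

    d(p) = -(3/4) ln(1 - 4p/3) has derivative 1/(1 - 4p/3), so near
    saturation an ulp-level difference in p is amplified arbitrarily; the
    tolerance scales with that conditioning."""
    arg = max(1.0 - (4.0 / 3.0) * p, 1e-300)
    return 1e-9 + 1e-14 / arg


def ng86_bruteforce(codons: list[tuple[str, str]]) -> dict:
    """NG86 on a list of codon pairs (gap/stop/ambiguous codons skipped)."""
    s_sites = sd = nd = 0.0
    n_codons = 0
    for ca, cb in codons:
        if any(c not in _BASES for c in ca + cb):
            continue
        if ca in _STOPS or cb in _STOPS:
            continue
        n_codons += 1
        s_sites += (syn_sites_codon(ca) + syn_sites_codon(cb)) / 2.0
        if ca != cb:
            d_s, d_n = pathway_differences(ca, cb)
            sd += d_s
            nd += d_n
    n_sites = 3.0 * n_codons - s_sites
    ks = jukes_cantor(sd / s_sites) if s_sites > 0 else 0.0
    ka = jukes_cantor(nd / n_sites) if n_sites > 0 else 0.0
    return {
        "s_sites": s_sites,
        "n_sites": n_sites,
        "sd": sd,
        "nd": nd,
        "ka": ka,
        "ks": ks,
    }


# ---------------------------------------------------------------------------
# exhaustive global alignment (affine gaps) for tiny sequences


def best_alignment_score(
    a: str,
    b: str,
    score_fn,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Max over all global alignments, scored with an affine gap model where
    a gap of length k costs open + (k-1)*extend.  Exponential; len <= 6."""

    best = -math.inf

    def rec(i: int, j: int, state: str | None, score: float) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, None, score + score_fn(a[i], b[j]))
        if i < len(a):  # a[i] against a gap in b
            rec(i + 1, j, "b", score - (gap_extend if state == "b" else gap_open))
        if j < len(b):
            rec(i, j + 1, "a", score - (gap_extend if state == "a" else gap_open))

    rec(0, 0, None, 0.0)
    return best


# ---------------------------------------------------------------------------
# naive motif scan


def naive_scan(seq: str, signal: str, strands: str = "both") -> list[tuple[int, str]]:
    """Position-by-position IUPAC scan; returns (1-based start, strand)."""

    def window_matches(window: str, pattern: str) -> bool:
        return all(c in IUPAC_SETS[p] for c, p in zip(window, pattern))

    width = len(signal)
    out = []
    for start in range(len(seq) - width + 1):
        window = seq[start : start + width]
        if strands in ("+", "both") and window_matches(window, signal):
            out.append((start + 1, "+"))
        if strands in ("-", "both") and window_matches(revcomp(window), signal):
            out.append((start + 1, "-"))
    return out


# ---------------------------------------------------------------------------
# random additive trees (ground truth for distance-based reconstruction)


def random_additive_tree(n_taxa, rng, min_len=0.05, max_len=1.0):
    """Random unrooted binary tree with positive branch lengths; returns
    (skbio.TreeNode, skbio.DistanceMatrix of its exact tip-tip distances)."""
    from skbio import TreeNode

    nodes = [TreeNode(name=f"t{i}") for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = float(rng.uniform(min_len, max_len))
        b.length = float(rng.uniform(min_len, max_len))
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)]
        nodes.append(TreeNode(children=[a, b]))
    for x in nodes:
        x.length = float(rng.uniform(min_len, max_len))
    root = TreeNode(children=nodes)
    return root, root.tip_tip_distances()


# ---------------------------------------------------------------------------
# dense-grid pI


def grid_pi(sequence: str, net_charge_fn, resolution: float = 1e-4) -> float:
    """pH grid point where the net charge is closest to zero."""
    best_ph, best_abs = 0.0, math.inf
    steps = int(14.0 / resolution)
    for k in range(steps + 1):
        ph = k * resolution
        c = abs(net_charge_fn(sequence, ph))
        if c < best_abs:
            best_ph, best_abs = ph, c
    return best_ph
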