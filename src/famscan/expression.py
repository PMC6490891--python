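"""Expression profiling: RPKM, log2 heatmap ordering, shared-expression sets,
ortholog matching and 2^-ΔΔCt relative quantification.

RPKM[g, s] = 1e9 * C[g, s] / (N[s] * L[g]) with counts C, per-sample mapped
library sizes N and gene lengths L in bp.  Heatmap ordering applies
agglomerative clustering (average linkage, Euclidean, by default) to
log2(RPKM + pseudo-count).  A gene counts as "expressed" in a tissue group
when RPKM >= threshold (default 1) in at least one sample of the group.
qPCR fold changes use ΔΔCt against a reference gene and calibrator sample,
with replicate SDs propagated in quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import mean, stdev
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .io_formats import SequenceRecord
from .pairwise_align import AlignParams, global_align


@dataclass
class CountMatrix:
    """Raw counts (genes x samples) with gene lengths (bp) and library sizes."""

    counts: pd.DataFrame
    gene_length: pd.Series
    library_size: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.gene_length = self.gene_length.reindex(self.counts.index)
        self.library_size = self.library_size.reindex(self.counts.columns)
        if self.gene_length.isna().any() or (self.gene_length <= 0).any():
            raise ValueError("every gene needs a positive length")
        if self.library_size.isna().any():
            raise ValueError("every sample needs a library size")
        short = self.library_size < self.counts.sum(axis=0)
        if short.any():
            raise ValueError(
                f"library size below column sum for {list(self.library_size.index[short])}"
            )


def rpkm(cm: CountMatrix) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads."""
    zero = cm.library_size == 0
    if zero.any():
        raise ValueError(f"zero library size for samples {list(cm.library_size.index[zero])}")
    return 1e9 * cm.counts.div(cm.library_size, axis=1).div(cm.gene_length, axis=0)


@dataclass
class HeatmapLayout:
    log_matrix: pd.DataFrame  # rows/columns reordered
    row_order: list[str]
    col_order: list[str]


def heatmap_matrix(
    expr: pd.DataFrame,
    pseudo: float = 1.0,
    method: str = "average",
    metric: str = "euclidean",
) -> HeatmapLayout:
    """log2(RPKM + pseudo) with deterministic clustered row/column order.

    Rows are pre-sorted by gene id (and columns by sample id) so equal
    profiles tie-break reproducibly.
    """
    if expr.empty:
        raise ValueError("empty expression matrix")
    log_m = np.log2(expr.sort_index(axis=0).sort_index(axis=1) + pseudo)

    def order(frame: pd.DataFrame) -> list[str]:
        if len(frame) < 2:
            return list(frame.index)
        z = linkage(frame.to_numpy(), method=method, metric=metric)
        return [frame.index[i] for i in leaves_list(z)]

    rows = order(log_m)
    cols = order(log_m.T)
    return HeatmapLayout(log_m.loc[rows, cols], rows, cols)


def expression_sets(
    expr: pd.DataFrame,
    groups: Mapping[str, str],
    threshold: float = 1.0,
) -> dict[frozenset[str], set[str]]:
    """Venn-region membership over tissue groups.

    ``groups`` maps each sample to a group name.  Returns, per non-empty
    combination of groups, the genes expressed in exactly that combination;
    the regions partition the genes expressed in >= 1 group.
    """
    unknown = [s for s in groups if s not in expr.columns]
    if unknown:
        raise KeyError(f"samples {unknown} not in the expression matrix")
    names = sorted(set(groups.values()))
    if len(names) < 2:
        raise ValueError("need at least two groups")
    regions: dict[frozenset[str], set[str]] = {}
    for gene in expr.index:
        in_groups = frozenset(
            g
            for g in names
            if any(expr.at[gene, s] >= threshold for s, gg in groups.items() if gg == g)
        )
        if in_groups:
            regions.setdefault(in_groups, set()).add(gene)
    return regions


def match_orthologs(
    cds_a: Sequence[SequenceRecord],
    cds_b: Sequence[SequenceRecord],
    min_identity: float = 98.0,
    min_coverage: float = 70.0,
    params: AlignParams | None = None,
) -> list[tuple[str, str]]:
    """Reciprocal best hits among pairs with identity/coverage at or above
    the thresholds (inclusive), by nucleotide global alignment."""
    if not cds_a or not cds_b:
        raise ValueError("both CDS sets must be non-empty")
    params = params or AlignParams(matrix="NUC")
    stats: dict[tuple[str, str], tuple[float, float]] = {}
    for ra in cds_a:
        for rb in cds_b:
            aln = global_align(ra, rb, params)
            if aln.identity_pct >= min_identity and aln.coverage_pct >= min_coverage:
                stats[(ra.id, rb.id)] = (aln.identity_pct, aln.coverage_pct)

    def best(candidates: list[tuple[str, tuple[float, float]]]) -> str | None:
        if not candidates:
            return None
        # ties on (identity, coverage) break to the smallest id
        return min(candidates, key=lambda kv: (-kv[1][0], -kv[1][1], kv[0]))[0]

    best_ab = {
        ra.id: best([(b, v) for (a, b), v in stats.items() if a == ra.id])
        for ra in cds_a
    }
    best_ba = {
        rb.id: best([(a, v) for (a, b), v in stats.items() if b == rb.id])
        for rb in cds_b
    }
    return sorted(
        (a, b)
        for a, b in ((a, b) for a, b in best_ab.items() if b is not None)
        if best_ba.get(b) == a
    )


@dataclass
class QpcrMeasurement:
    sample_id: str
    target_ct: list[float]
    reference_ct: list[float]

    def __post_init__(self) -> None:
        if not self.target_ct or not self.reference_ct:
            raise ValueError(f"sample {self.sample_id}: missing Ct replicates")
        for ct in (*self.target_ct, *self.reference_ct):
            if not (0 < ct < 45):
                raise ValueError(f"sample {self.sample_id}: Ct {ct} outside (0, 45)")

    @property
    def delta_ct(self) -> float:
        return mean(self.target_ct) - mean(self.reference_ct)

    @property
    def delta_ct_sd(self) -> float:
        sd_t = stdev(self.target_ct) if len(self.target_ct) > 1 else 0.0
        sd_r = stdev(self.reference_ct) if len(self.reference_ct) > 1 else 0.0
        return math.hypot(sd_t, sd_r)


@dataclass
class FoldChange:
    sample_id: str
    fold: float
    ddct: float
    sd: float  # SD of ΔΔCt (cycles), replicate SDs combined in quadrature


def ddct(m: QpcrMeasurement, calibrator: QpcrMeasurement) -> FoldChange:
    """Relative expression 2^-ΔΔCt of a sample against the calibrator."""
    delta = m.delta_ct - calibrator.delta_ct
    sd = math.hypot(m.delta_ct_sd, calibrator.delta_ct_sd)
    return FoldChange(m.sample_id, 2.0 ** (-delta), delta, sd)


def ddct_table(
    ct: pd.DataFrame, target_gene: str, reference_gene: str, calibrator_sample: str
) -> pd.DataFrame:
    """Fold changes from a tidy Ct table with columns sample, gene, ct."""
    def measurement(sample: str) -> QpcrMeasurement:
        sub = ct[ct["sample"] == sample]
        tgt = sub.loc[sub["gene"] == target_gene, "ct"].tolist()
        ref = sub.loc[sub["gene"] == reference_gene, "ct"].tolist()
        return QpcrMeasurement(sample, tgt, ref)

    cal = measurement(calibrator_sample)
    rows = []
    for sample in ct["sample"].unique():
        fc = ddct(measurement(sample), cal)
        rows.append(
            {"sample": sample, "fold": fc.fold, "ddct": fc.ddct, "sd": fc.sd}
        )
    return pd.DataFrame(rows)
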