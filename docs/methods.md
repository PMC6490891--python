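# Methods

This note documents the models, conventions and numerical choices behind
famscan, and what the synthetic-data generators do and do not emulate.

## Identification

A protein is a family candidate when it carries at least one
nucleotide-binding-domain (NBD) hit with E-value ≤ 1e-5. The threshold is
inclusive because the exclusion rule is stated as "E-value > 1e-5 is
excluded"; boundary hits are kept. Pfam accessions are normalized to domain
tokens through a packaged, user-overridable table (PF00005 and PF01061 →
NBD, PF00664 → TMD): PF01061 marks the ABC-2 family, which carries the
nucleotide-binding fold, so it maps to NBD for topology purposes.

Redundancy is collapsed in two passes — isoforms of one locus (ids equal
after stripping a trailing `.N`), then byte-identical sequences — keeping
the longest sequence, with ties going to the lexicographically smallest id.
The rule is explicit because "redundant genes were excluded" does not by
itself determine a survivor.

Subfamily assignment is nearest-labeled-reference by global alignment
score (ties to the smallest reference id). This is a deterministic,
desk-scale stand-in for iterative profile search plus tree placement; the
NJ tree is still produced for clade-level inspection, and on synthetic
references the assignment recovers planted labels in ≥ 95% of queries at
10% mutational distance.

## Coordinates

Internally all genomic intervals are 0-based half-open. GFF3 (1-based
inclusive) is converted at the parser boundary in both directions, and BED
export needs no conversion. Protein coordinates in domain hits stay
1-based inclusive as HMMER prints them. This single-convention rule exists
to keep off-by-one errors impossible to express rather than merely tested
against.

## Topology classes

Overlapping same-type domain hits are merged when the overlap exceeds 50%
of the shorter hit; merged hits are ordered by alignment start to form the
N→C domain string. The string maps to one of nine classes: FULL_FORWARD
(TMD-NBD-TMD-NBD), FULL_REVERSE, HALF_FORWARD, HALF_REVERSE, QUARTER_NBD,
QUARTER_TMD, ABC2 (NBD-NBD), TMD-TMD, and UNIQUE for everything else —
including extended repeats such as (TMD-NBD)×2 plus a trailing TMD, which
are deliberately not folded into the full-sized class. `soluble` is an
independent flag (no TMD anywhere), so both the "soluble proteins" and the
"transporters" readings of the class totals are recoverable.

## Molecular weight and pI

Molecular weight is the sum of average residue masses plus one water
(Biopython's average-mass table). The theoretical pI solves
net_charge(pH) = 0 with Henderson–Hasselbalch terms for the termini and the
D, E, C, Y (acidic) and H, K, R (basic) side chains under the EMBOSS pKa
set, which is packaged as a replaceable YAML file. The charge curve is
strictly decreasing, so bisection on [0, 14] finds the unique root; we
iterate to 1e-6 pH units (tighter than needed, negligible cost) and verify
against a 1e-4 dense-grid scan in tests.

## Pairwise and codon alignment

Global alignment uses affine gaps where a gap of length k costs
open + (k−1)·extend, with the penalties 10 and 0.1 as defaults and BLOSUM62
for proteins, match/mismatch +2/−3 for nucleotides. The dynamic programming
is delegated to Bio.Align.PairwiseAligner; among co-optimal alignments the
library's first traceback is used, which is deterministic for fixed inputs.
Identity is matches over both-non-gap columns; coverage is both-non-gap
columns over the shorter sequence — the denominator is stated here because
"coverage of the alignment length" admits several readings, and it is
configurable in the statistics helpers. Paralog thresholds are strict
(> 70 / > 70); ortholog thresholds are inclusive (≥ 98 / ≥ 70), mirroring
how the criteria are written.

Codon alignment translates, aligns the proteins, and expands each aligned
residue back to its codon, so gaps come in whole-codon units and the frame
is preserved. One trailing stop codon is trimmed; internal stops are
errors.

## NG86 Ka/Ks

Sites: at each codon position, the fraction of the three single-base
changes that are synonymous, with stop-creating changes excluded from both
numerator and denominator; S per codon is the sum over positions, N = 3 − S,
and sites are averaged over the two sequences. Differences: codon pairs
differing at k positions are averaged over all k! minimal pathways,
excluding pathways through stop codons (if every pathway is blocked the
average falls back to all pathways). Codons with a gap, an ambiguous base
or a stop in either row are skipped entirely. Proportions p = d/sites get
the Jukes–Cantor correction; p ≥ 3/4 is reported as +inf with a saturation
flag rather than an exception, so downstream dating can propagate it.

The estimator choice is NG86 + JC (not a model-averaged estimator), so
per-pair values from other tools will differ row by row; the packaged
14-pair reference table is therefore summarized at column level (mean ω,
selection counts, mean age) rather than reproduced per row. Known NG86
behavior visible in our simulations: ω is recovered nearly unbiased under
purifying selection (median 0.205 at true 0.2) but ~10–15% low at ω = 2
(median ≈ 1.75), and Ks at 0.2 is recovered within ~1–2%. The duplication
clock is T = Ks/(2λ), λ = 6.96e-9 synonymous substitutions per site per
year, reported in million years.

Paralog discovery runs all-vs-all codon alignment and keeps edges passing
both thresholds. The "minimum of two duplication events" criterion is
exposed as a component-level `strongly_connected` flag (component with ≥ 2
retained edges) rather than a silent filter, because its intent is
ambiguous; `--require-strong` filters on it explicitly.

## Neighbor joining and bootstrap

p-distance with pairwise deletion of gap columns is the default distance
(the distance function argument is pluggable; the tool chain being
reproduced does not pin a model). NJ is the standard Saitou–Nei
agglomeration with a deterministic tie-break (smallest pair position on
equal Q); negative branch lengths are clamped to zero and flagged on the
returned tree. On additive matrices the reconstruction reproduces input
distances to 1e-9. Bootstrap resamples alignment columns with replacement,
rebuilds the tree per replicate, and reports for each non-trivial internal
bipartition of the point-estimate tree the percentage of replicates
containing it; everything is seeded. Newick output carries supports as
internal labels and branch lengths at 6 decimals.

## Promoters and cis-elements

Promoters are the 1,500 bp (configurable) upstream of the translation
start: for + genes the bases immediately 5' of the gene start, for − genes
the reverse complement of the downstream flank; truncation at contig bounds
is flagged, zero upstream bases is an error. Scanning compiles IUPAC
degenerate signals to position-wise character classes; every overlapping
occurrence is reported on both strands by default (minus-strand hits are
found by scanning the reverse-complemented pattern and reported in forward
coordinates). An N in the scanned sequence matches only a pattern N.
Presence/absence summaries (common elements) collapse multiplicity. The
packaged catalog has 23 entries (name, signal, site id, annotation) and any
catalog in the same TSV schema can be substituted.

## Expression

RPKM = 10⁹·C/(N·L) with L in bp and N the per-sample mapped library size
(taken from the count table's metadata, not recomputed from column sums).
The heatmap transform is log2(RPKM + 1); the pseudo-count is configurable
and defaults to 1 so zero RPKM maps to zero. Row/column order comes from
average-linkage Euclidean clustering on the transformed matrix, with inputs
pre-sorted by id so equal profiles tie-break reproducibly. A gene counts as
"expressed" in a tissue group at RPKM ≥ 1 in at least one sample of the
group — the threshold is a package convention (no published definition
exists) and is a parameter. Ortholog matching is reciprocal best hit under
the inclusive thresholds above. ΔΔCt uses replicate means, the reference
gene fixed by configuration (β-tubulin in the motivating assay), a
calibrator sample, and propagates replicate SDs in quadrature; fold change
is 2^−ΔΔCt.

Developmental stages in the fixtures are 6/16/25 days post-anthesis, the
sampling scheme of the motivating placenta assay.

## Synthetic data: what it emulates, and what it does not

The generators produce inputs with exactly the statistical structure each
stage assumes, plus machine-readable truth:

- **Proteomes** plant NBD (150 aa) / TMD (120 aa) segments with 25-aa
  linkers and matching domain-table rows (E-values log-uniform in
  [1e-50, 1e-10]); decoys lack an NBD hit, half of them carrying a TMD-only
  hit so the NBD requirement, not mere hit presence, is what rejects them.
  Gene models go non-overlapping on two chromosomes, both strands.
- **Diverged codon pairs** evolve an ancestor along two branches by uniform
  single-base proposals accepted at relative rate 1 (synonymous) vs ω
  (non-synonymous), rejecting stop-creating changes, until the realized
  synonymous events per synonymous site reach Ks/2 per branch. This is a
  rejection scheme, not a full codon-model simulator; its adequacy is
  judged solely by NG86 recovery tolerances, which is the only claim made.
- **Promoters** start from uniform background made catalog-free by
  iteratively resampling any window that matches the catalog (whole-sequence
  rejection cannot terminate at 1,500 bp: 4-bp signals like CAAT occur ~6
  times per random sequence). Planted instances are instantiated uniformly
  over degenerate letters, placed without overlap, on random strands.
- **Count matrices** invert the RPKM formula exactly (deterministic mode)
  or draw Poisson counts around the expectation (noisy mode).
- **Gene models** for promoter round-trips record the exact planted
  upstream sequence per gene on both strands.

None of this emulates real genome composition, codon usage bias,
transition/transversion bias, indels within duplicate pairs, promoter base
composition, or overdispersed RNA-seq counts. Passing tests therefore
demonstrate algorithmic correctness against controlled truth, not
robustness to every property of real pepper data.

## Problem sizes and determinism

Verification workloads are sized for a single CPU: 1,000 random short codon
alignments against the enumeration oracle, 100 simulated pairs of 500
codons per ω level, 100 random 4–8-taxon additive matrices, 1,000 random
200-bp sequences against the naive scanner oracle, and 3–5 promoters of
1,500 bp for planting checks. All randomness flows through explicit integer
seeds (NumPy `default_rng`), and `scripts/acceptance.py` derives per-stage
sub-seeds from its single `--seed`, so outputs are reproducible byte for
byte.

## Known limitations

- Subfamily assignment by nearest reference cannot place a query falling
  between subfamilies; the score margin is not currently reported.
- NG86 saturates near p = 3/4; deeply diverged pairs return +inf rates with
  a flag instead of estimates, and the Jukes–Cantor transform is
  ill-conditioned approaching saturation.
- The bootstrap supports only bipartitions present in the point-estimate
  tree; alternative splits are counted against, not enumerated.
- Coverage uses the shorter-sequence denominator; alignments dominated by
  end gaps can still reach 100% coverage when one sequence nests inside
  the other.
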