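"""Promoter extraction and cis-element scanning.

Generates gene models on both strands of a synthetic contig, extracts
1,500-bp promoters, plants three catalog cis-elements into synthetic
promoters and scans both strands with the packaged 23-element catalog.
"""

from famscan.cis_regulation import (
    PromoterConfig,
    common_elements,
    extract_promoters,
    load_catalog,
    scan_promoters,
)
from famscan.synthetic_data import gen_gene_models, gen_promoters

sim = gen_gene_models(4, seed=5)
proms = extract_promoters(sim.gene_models, sim.genome, PromoterConfig(1500))
ok = sum(p.sequence == sim.upstream_truth[g.gene_id]
         for p, g in zip(proms, sim.gene_models))
print(f"extracted {len(proms)} promoters; {ok} match the planted upstream "
      f"sequence exactly (both strands)")

catalog = load_catalog()
planted, truth = gen_promoters(3, 1500, catalog,
                               plant=["CAATBOX1", "ARFAT", "GT1CONSENSUS"], seed=9)
hits = scan_promoters(planted, catalog, strands="both")
common = common_elements(hits, {"set": [p.id for p in planted]})
print(f"{len(hits)} hits on motif-free background + planted elements")
print(f"elements common to all promoters: {sorted(common)}")
# the background is built to contain no catalog match, so the common set is
# exactly what was planted in every promoter.
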