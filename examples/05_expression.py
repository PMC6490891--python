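"""RPKM profiling, shared-expression sets and qPCR fold changes.

Simulates a count matrix from a known RPKM truth, recovers the RPKM values,
partitions genes into tissue-group Venn regions, and computes a 2^-ddCt
relative expression against a beta-tubulin-style reference gene.
"""

import pandas as pd

from famscan.expression import QpcrMeasurement, ddct, expression_sets, rpkm
from famscan.synthetic_data import gen_counts

genes = ["gA", "gB", "gC", "gD"]
truth = pd.DataFrame(
    {"placenta_6dpa": [12.0, 0.0, 3.0, 90.0],
     "placenta_16dpa": [15.0, 2.5, 0.0, 85.0],
     "placenta_25dpa": [0.0, 2.0, 0.0, 70.0]},
    index=genes,
)
libs = pd.Series([2e6, 3e6, 2.5e6], index=truth.columns)
lengths = pd.Series([1200, 800, 2000, 1500], index=genes)

expr = rpkm(gen_counts(truth, libs, lengths))
print("recovered RPKM (rounded):")
print(expr.round(1).to_string())

groups = {c: c.split("_")[1] for c in truth.columns}
regions = expression_sets(expr, groups, threshold=1.0)
for region, members in sorted(regions.items(), key=lambda kv: -len(kv[0])):
    print(f"expressed in {'+'.join(sorted(region))}: {sorted(members)}")

sample = QpcrMeasurement("16dpa", [19.8, 20.1, 20.1], [18.0, 18.1, 17.9])
calib = QpcrMeasurement("6dpa", [21.0, 21.1, 20.9], [18.0, 18.0, 18.0])
fc = ddct(sample, calib)
print(f"qPCR fold change 16dpa vs 6dpa: {fc.fold:.2f} (ddCt={fc.ddct:.2f}, sd={fc.sd:.2f})")
# fold > 1 means higher expression than the calibrator stage after
# normalizing both to the reference gene.
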