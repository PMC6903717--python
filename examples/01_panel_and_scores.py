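"""The susceptibility panel and the theoretical score ranges.

Loads the packaged 48-SNP colorectal-cancer panel, shows its composition,
and computes the genetic-risk-score extremes for a subject carrying the
maximal risk-allele dose at every SNP.
"""

import snpcc
from snpcc.panel import Cohort, SubjectRecord
import pandas as pd

panel = snpcc.load_panel()
print(f"panel: {len(panel)} SNPs, composition {panel.count_by_class()}")
entry = panel["rs6687758"]
print(f"rs6687758: risk allele {entry.risk_allele}, "
      f"published OR {entry.published_or}, {entry.gene_label}")

# a single male subject with the maximal dose everywhere
cohort = Cohort([
    SubjectRecord("ca0", "case", "P0", "male", age_group="60-69"),
    SubjectRecord("co0", "control", "P0", "male", age_group="60-69"),
])
doses = {e.rsid: pd.Series(
    {"ca0": 1.0 if e.chrom_class == "x_linked" else 2.0,
     "co0": 0.0}) for e in panel}
dm = snpcc.DosageMatrix(pd.DataFrame(doses))

c = snpcc.count_grs(dm, panel, cohort)
w = snpcc.weighted_grs(dm, panel, cohort, weight_mode="or")
print(f"maximal count GRS   : {c.loc['ca0', 'c_grs']:.0f}  "
      "(2 per autosomal SNP + 1 for the X-linked SNP)")
print(f"maximal weighted GRS: {w.loc['ca0', 'w_grs']:.2f}  "
      "(doses weighted by published ORs; ~105)")

thr = snpcc.bonferroni_threshold(0.05, len(panel))
print(f"Bonferroni-corrected significance level: {thr:.3g} "
      "(0.05 divided across 48 SNP tests)")
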