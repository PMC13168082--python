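"""Robust rank aggregation of the 20 panels and per-method consensus.

All fold x method rankings are combined by Beta order-statistic RRA into one
aggregated panel; each method's five fold rankings are also aggregated into
a cross-fold consensus, and the consensus panels' overlaps are tabulated.
"""

import pandas as pd
from common import make_config

from sexpanel.pipeline import stage_aggregate

cfg = make_config()
files = stage_aggregate(cfg)
for f in files:
    print(f"wrote {f}")

agg = pd.read_csv(cfg.workdir / "aggregate" / "aggregated.tsv", sep="\t")
truth = pd.read_csv(cfg.workdir / "inputs" / "truth.tsv", sep="\t",
                    keep_default_na=False).set_index("gene_id")
print("\ntop 10 aggregated genes (rho, planted class):")
for _, row in agg.head(10).iterrows():
    print(f"  {row['gene_id']}  rho={row['rho']:.2e}  "
          f"class={truth.loc[row['gene_id'], 'class']}")
frac = (truth.loc[agg['gene_id'].head(20), 'class'] != 'null').mean()
print(f"planted fraction of the top 20: {frac:.0%}")
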