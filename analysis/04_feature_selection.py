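"""Four-method feature selection per fold on the z-scored training data.

Each fold's DEG pool is ranked by the optimized random forest, linear
SVM-RFE, L1-penalised logistic regression, and the DGE adjusted p-value,
yielding 5 folds x 4 methods = 20 candidate panels.
"""

import pandas as pd
from common import make_config

from sexpanel.pipeline import stage_select

cfg = make_config()
files = stage_select(cfg)
for f in files:
    print(f"wrote {f}")

print()
head = {}
for path in sorted((cfg.workdir / "panels").glob("fold0_*.tsv")):
    table = pd.read_csv(path, sep="\t")
    head[table["method"][0]] = list(table["gene_id"].head(5))
for method, genes in head.items():
    print(f"fold 0, {method:>10}: top genes {genes}")
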