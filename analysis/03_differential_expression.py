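"""Per-fold batch-aware differential expression and task DEG pools.

For each of the five fold schemes, the male tumor vs non-tumor contrast runs
on the four training folds with the originating dataset as a model
covariate; the female contrast runs in parallel and genes regulated in the
same direction in both sexes are excluded, leaving the male-specific pool.
"""

import pandas as pd
from common import make_config

from sexpanel.pipeline import stage_dge

cfg = make_config()
files = stage_dge(cfg)
for f in files:
    print(f"wrote {f}")

print()
for f in range(cfg.k_folds):
    pool = pd.read_csv(cfg.workdir / "dge" / f"fold{f}_pool.tsv", sep="\t")
    n_up = (pool["direction"] == 1).sum()
    print(f"fold {f}: {len(pool)} DEGs in the male-specific pool "
          f"({n_up} up, {len(pool) - n_up} down)")
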