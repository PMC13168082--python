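"""Normalize each batch independently and merge the training cohort.

Counts -> TPM -> log2(x+1) -> per-dataset z-score, then concatenation on
common genes; external batches are z-scored with their own statistics.  This
is the step that removes dataset-of-origin clustering before any model sees
the data.
"""

import pandas as pd
from common import make_config

from sexpanel.pipeline import stage_folds, stage_normalize

cfg = make_config()
files = stage_normalize(cfg) + stage_folds(cfg)
for f in files:
    print(f"wrote {f}")

train = pd.read_csv(cfg.workdir / "normalized" / "train.tsv", sep="\t", index_col=0)
print(
    f"\nMerged training matrix: {train.shape[0]} genes x {train.shape[1]} samples; "
    f"per-gene means |mean| max = {train.mean(axis=1).abs().max():.2e} "
    "(z-scoring holds per batch, so the pooled mean is near zero)."
)
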