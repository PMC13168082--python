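"""Internal validation and external evaluation with bootstrap intervals.

Per-fold panels are scored on their own held-out folds; the aggregated and
consensus panels are refitted on the full training cohort and scored on the
two unseen external batches across the top-N ladder, each metric with a
500-resample 95% percentile bootstrap interval.
"""

import json

from common import make_config

from sexpanel.pipeline import stage_evaluate, stage_internal_validation

cfg = make_config()
files = stage_internal_validation(cfg) + stage_evaluate(cfg)
for f in files:
    print(f"wrote {f}")

reports = json.loads((cfg.workdir / "metrics.json").read_text())
print("\naggregated panel, external average:")
for d in reports:
    if d["panel"] == "aggregated" and d["dataset"] == "external_average":
        m = {k: round(v["point"], 3) for k, v in d["metrics"].items()
             if v["point"] is not None}
        print(f"  top {d['n_genes']:>3} genes, {d['model']}: {m}")
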