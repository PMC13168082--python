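"""Simulate the multi-batch study cohorts with planted sex-specific signal.

Generates three training batches (tumor-heavy, non-tumor-only, small mixed)
and two external batches at desk scale, mirroring the strong male/female
imbalance of the real cohorts, and writes the fixture the rest of the
analysis consumes.  Run from the repository root:

    python analysis/01_simulate_cohorts.py
"""

from common import make_config

from sexpanel.pipeline import stage_simulate

cfg = make_config()
files = stage_simulate(cfg)
for f in files:
    print(f"wrote {f}")
print(
    f"\nSimulated {cfg.sim.n_genes} genes across {len(cfg.sim.batch_specs)} batches; "
    f"{len(cfg.sim.planted.all_planted())} genes carry planted signal "
    "(see inputs/truth.tsv for the class of every gene)."
)
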