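"""Shared desk-scale run configuration for the numbered analysis scripts.

Every script drives one pipeline stage on the male-development task (tumor vs
non-tumor within males, the best-powered of the three tasks) inside
``results/male_dev``.  Iteration counts are reduced from the full-scale
defaults (1,000 optimized-RF iterations, four evaluation families, the full
top-N ladder) so the whole sequence runs in a few minutes on one CPU; every
knob is a field of :class:`sexpanel.RunConfig` if you want the full version.
"""

from pathlib import Path

from sexpanel.config import BootstrapConfig, SelectorConfig
from sexpanel.pipeline import RunConfig
from sexpanel.sim import default_config

WORKDIR = Path("results/male_dev")


def make_config(task: str = "male_dev", seed: int = 20) -> RunConfig:
    return RunConfig(
        task=task,
        workdir=WORKDIR if task == "male_dev" else Path("results") / task,
        sim=default_config(n_genes=2000),
        selector=SelectorConfig(
            rf_iterations=20,
            rf_grid={"n_estimators": [100], "max_depth": [None, 10]},
            svm_grid={"C": [0.1, 1.0]},
            logreg_grid={"C": [0.1, 1.0]},
            inner_cv_k=3,
        ),
        bootstrap=BootstrapConfig(n_resamples=500),
        eval_models=("rf", "svm"),
        internal_models=("rf",),
        top_n_ladder=(300, 100, 50, 20),
        eval_inner_k=3,
        eval_n_iter=5,
        seed=seed,
    )
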