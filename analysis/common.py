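"""Shared setup for the numbered analysis scripts.

Each script drives one stage of the pipeline on the default synthetic cohort
(92 tumor / 15 normal discovery, 112-sample validation) and writes its tables
under results/analysis/.  Stages are cheap enough that each script simply
replays its prerequisites, so every script is runnable on its own.
"""

from pathlib import Path

from mirnome.datagen import SimulationConfig
from mirnome.pipeline import STAGES, Pipeline, RunConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"
SEED = 0


def pipeline_through(stage: str) -> Pipeline:
    cfg = RunConfig(outdir=str(RESULTS), seed=SEED, simulation=SimulationConfig(seed=SEED))
    pl = Pipeline(cfg)
    for name in STAGES[: STAGES.index(stage) + 1]:
        pl.run_stage(name)
    return pl
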