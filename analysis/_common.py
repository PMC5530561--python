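"""Shared run configuration for the numbered analysis drivers.

One synthetic study: a discovery cohort of 73 cases / 83 controls and a
validation cohort of 24 / 31, with five planted co-abundance clusters
(two carrying case/control fold changes), simulated multi-mapping reads
over six toy genomes, and the stage thresholds at their printed
defaults.  All drivers share the output directory ``results/run`` so
each step consumes the tables the previous one wrote.
"""

from pathlib import Path

from quantmeta.pipeline import PipelineRun, load_config

RESULTS = Path(__file__).resolve().parent.parent / "results"
RUN_DIR = RESULTS / "run"

CONFIG = load_config({"seed": 20260921})


def get_run() -> PipelineRun:
    return PipelineRun(CONFIG, RUN_DIR)
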