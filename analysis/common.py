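"""Shared setup for the numbered analysis drivers.

All drivers work on one seeded synthetic dataset under ``results/run/`` so
each step can be re-run independently; stage parameters come from the
bundled demo configuration.
"""

from pathlib import Path

from nlr_atlas.pipeline import STAGES, RunConfig, demo_config_path

RESULTS = Path(__file__).resolve().parent.parent / "results"
RUN_DIR = RESULTS / "run"


def stage_config(*stages: str) -> RunConfig:
    cfg = RunConfig.from_yaml(demo_config_path())
    cfg.outdir = RUN_DIR
    cfg.stages = {s: s in stages for s in STAGES}
    return cfg
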