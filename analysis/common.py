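"""Shared configuration for the numbered analysis drivers.

All drivers operate on one output directory (``results/pipeline``) with one
seed, so any driver can be re-run after its predecessors without
re-simulating.
"""

from pathlib import Path

from mircross.config import PipelineConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "pipeline"
SEED = 1


def analysis_config() -> PipelineConfig:
    cfg = PipelineConfig(outdir=str(RESULTS), seed=SEED, permutations=1000)
    cfg.synthetic.seed = SEED
    return cfg
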