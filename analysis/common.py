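"""Shared driver plumbing: each numbered script runs the deterministic
pipeline up to its stage (earlier stages are cheap to recompute under the
fixed seed) and narrates that stage's result."""

from pathlib import Path

from awmnet.pipeline import STAGES, PipelineConfig, run_pipeline

RESULTS = Path(__file__).resolve().parent.parent / "results" / "pipeline"
SEED = 42


def run_through(stage: str) -> dict:
    upto = STAGES[: STAGES.index(stage) + 1]
    cfg = PipelineConfig(out_dir=str(RESULTS), seed=SEED, stages=upto,
                         log_level="WARNING")
    manifest = run_pipeline(cfg)
    return manifest["stages"]
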