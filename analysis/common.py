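"""Shared configuration for the numbered analysis scripts.

The benchmark study: a 1 Mb genome with 2,000 phased variants and 200
enriched regions at summit fold 10, analysed against the reference and
against haplotype 1 of the modified personal genome (MPG mode), plus a
degraded-assembly (DPG-mode) variant of the same study.
"""

from pathlib import Path

from apfind import PipelineConfig, SimConfig, run_pipeline

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def base_sim(seed: int = SEED) -> SimConfig:
    return SimConfig(seed=seed)


def mpg_config(seed: int = SEED) -> PipelineConfig:
    return PipelineConfig(sim=base_sim(seed))


def dpg_config(seed: int = SEED) -> PipelineConfig:
    sim = base_sim(seed)
    sim.dropout_fraction = 0.10
    return PipelineConfig(sim=sim, genome_mode="dpg")


def run(config: PipelineConfig):
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    return run_pipeline(config)
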