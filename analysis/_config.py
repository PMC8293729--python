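"""Shared run configuration for the numbered analysis scripts.

One seeded landscape, 160 x 240 pixels (12 km x 8 km at 50 m) in three
regions; ensemble cross-validation uses 5 repeats per pseudo-absence
replicate. Artifacts go to scratch/analysis_run, summary tables to results/.
"""

from pathlib import Path

from oakmap.config import PipelineConfig

ROOT = Path(__file__).resolve().parent.parent
RUN_DIR = ROOT / "scratch" / "analysis_run"
RESULTS = ROOT / "results"


def make_config(seed: int = 20) -> PipelineConfig:
    cfg = PipelineConfig(seed=seed, out_dir=str(RUN_DIR))
    cfg.simulation.n_rows = 160
    cfg.simulation.n_cols = 240
    cfg.simulation.export_geojson = False
    cfg.fit.n_repeats = 5
    RESULTS.mkdir(exist_ok=True)
    return cfg
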