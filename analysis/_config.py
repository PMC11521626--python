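"""Shared study configuration for the numbered analysis drivers.

One pipeline run (cached under results/pipeline) feeds every driver; each
driver narrates one stage and writes its tables under results/.
"""

from pathlib import Path

from shearlog import pipeline

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"
PIPELINE_DIR = SCRATCH / "analysis_pipeline"


def study_config(seed: int = 1) -> pipeline.RunConfig:
    return pipeline.RunConfig(out_dir=str(PIPELINE_DIR), seed=seed,
                              n_birds=10, n_years=4, n_boot=500)


def run(seed: int = 1):
    import warnings

    RESULTS.mkdir(exist_ok=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.run_pipeline(study_config(seed))
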