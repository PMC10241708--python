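"""Shared paths and the study-scale configuration for the analysis scripts.

Images are binary scratch output; tables and statistics are small text
files kept under ``results/``.
"""

from pathlib import Path

REPO = Path(__file__).resolve().parent.parent
SCRATCH = REPO / "scratch" / "analysis_run"
RESULTS = REPO / "results"

#: desk-scale stand-in for a TMA cohort: 30 cases, triplicate cores
RUN = dict(
    seed=2023,
    out_dir=str(SCRATCH),
    n_cases=30,
    cores_per_case=3,
    image_size_px=(768, 768),
    n_vessels_per_core=8,
    noise_sd_od=0.02,
    true_log_hr=1.0986122886681098,  # log 3: the effect size probed
    censoring_rate=0.3,
)


def run_config():
    from vesselquant.pipeline import RunConfig

    return RunConfig(**RUN)
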