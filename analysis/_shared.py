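"""Shared plumbing for the numbered analysis drivers."""

import argparse
from pathlib import Path

from mirsurv.pipeline import cohort_analysis_inputs
from mirsurv.simulate import SimulationConfig, simulate_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "analysis"


def parse_args(description, **extra):
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=1)
    for name, (typ, default, help_) in extra.items():
        ap.add_argument(f"--{name}", type=typ, default=default, help=help_)
    return ap.parse_args()


def default_cohort(seed):
    """The study cohort all drivers share: generator defaults, one seed."""
    return simulate_cohort(SimulationConfig(seed=seed))


def cohort_and_blocks(seed):
    cohort = default_cohort(seed)
    blocks, outcome, expr = cohort_analysis_inputs(cohort)
    return cohort, blocks, outcome, expr
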