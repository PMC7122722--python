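"""Shared study conditions for the numbered analysis drivers.

The drivers analyse a seeded synthetic fire-climate system generated at
the study scale (216 months, adjustment speed -0.611, wind elasticity
20.81) so that every stage's output can be judged against known truth.
Swap `dataset()` for a `load_timeseries(...)` call to run the same
analysis on real monthly fire-climate records.
"""

from pathlib import Path

from fireardl import DgpSpec, EcmSpec, generate_ecm_system

SEED = 2026
RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"


def dataset():
    """The study dataset (log scale) and its ground truth."""
    ds, truth = generate_ecm_system(DgpSpec(seed=SEED))
    return ds, truth


def model_spec(truth):
    """ARDL order matching the generating process (q=1 for every driver)."""
    return EcmSpec("area_burned", tuple(truth.long_run_elasticities))


def outdir():
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS
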