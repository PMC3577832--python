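"""Shared fixtures.

The two session-scoped population runs are the expensive fixtures: a
two-rate run at 1500/1000 ms used for median and regression checks, and a
smaller full-step-protocol run used for fast-rate (alternans) checks.  Both
are generated through the real pipeline so the tests also exercise the
orchestration layer.
"""

import numpy as np
import pandas as pd
import pytest

from cardiopop import (ConditionSpec, RunConfig, extract_biomarkers,
                       make_cell, run_pipeline, single_bcl_run)


@pytest.fixture(scope="session")
def baseline_cell():
    return make_cell()


@pytest.fixture(scope="session")
def baseline_trace_1500(baseline_cell):
    """Unscaled endocardial cell: final two beats after 100 paces at 1500 ms."""
    trace, _ = single_bcl_run(baseline_cell, 1500, 100)
    return trace


@pytest.fixture(scope="session")
def baseline_record_1500(baseline_trace_1500):
    return extract_biomarkers(baseline_trace_1500)


@pytest.fixture(scope="session")
def medians_run(tmp_path_factory):
    """200 cells per condition paced 100x at 1500 then 1000 ms.

    The two conditions share common uniform draws (quantile-matched cells),
    which leaves each population's marginals exactly as specified while
    sharply reducing the Monte-Carlo variance of between-condition median
    contrasts at this sample size.
    """
    from cardiopop.pipeline import simulate_stage
    from cardiopop.population import paired_population_frames

    out = tmp_path_factory.mktemp("medians_run")
    cfg = RunConfig(
        populations={"non-failing": ConditionSpec(200, 1001),
                     "failing": ConditionSpec(200, 1001)},
        bcls=(1500, 1000),
        output_dir=str(out),
    )
    pops = paired_population_frames(200, seed=1001)
    return simulate_stage(cfg, pops, out)


@pytest.fixture(scope="session")
def step_protocol_run(tmp_path_factory):
    """150 cells per condition through the full 11-BCL step protocol."""
    out = tmp_path_factory.mktemp("step_run")
    cfg = RunConfig(
        populations={"non-failing": ConditionSpec(150, 1001),
                     "failing": ConditionSpec(150, 2001)},
        output_dir=str(out),
    )
    run_pipeline(cfg)
    return pd.read_csv(out / "biomarkers.csv")
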