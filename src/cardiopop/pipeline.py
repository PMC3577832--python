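"""End-to-end orchestration: sample -> pace -> biomarkers -> regress -> summarize.

Artifacts written under ``config.output_dir``:

* ``populations.csv`` (+ JSON sidecars) — sampled scalings per condition
* ``biomarkers.csv`` — one row per (condition, cell, BCL), written
  incrementally so interrupted runs resume where they stopped
* ``regression.csv`` — tidy coefficients/R^2 per (condition, BCL, biomarker)
* ``summary.csv`` — medians and failing-vs-non-failing percent changes
* ``alternans.csv`` — alternans/capture counts per condition and BCL
* ``failed_cells.csv`` — cells whose integration failed (logged, skipped)
* ``config.yaml`` / ``run.json`` — config snapshot, code version, timings
* ``traces.h5`` — final-two-beat traces (only when ``save_traces``)
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .biomarkers import extract_biomarkers
from .config import RunConfig
from .ord import make_cell
from .pacing import SolverError, run_step_protocol
from .population import PopulationSpec, population_frame, write_population
from .regression import regress_all, results_frame
from .scalings import PARAM_NAMES, ScalingVector
from .summary import alternans_counts, summary_table

log = logging.getLogger("cardiopop")


def _pkg_version() -> str:
    from cardiopop import __version__

    return __version__


def sample_stage(config: RunConfig, out: Path) -> pd.DataFrame:
    """Sample all configured populations and write populations.csv."""
    frames = []
    for cond, cspec in config.populations.items():
        spec = PopulationSpec(cond, cspec.n_cells, cspec.seed)
        df = population_frame(spec)
        write_population(df, spec, out / f"population_{cond}.csv")
        frames.append(df)
    pops = pd.concat(frames, ignore_index=True)
    pops.to_csv(out / "populations.csv", index=False)
    return pops


def simulate_cell(scalings: ScalingVector, config: RunConfig):
    """Pace one cell through the step protocol; return per-BCL biomarkers."""
    cell = make_cell(scalings)
    traces, _ = run_step_protocol(cell, config.protocol(),
                                  settings=config.solver)
    records = {bcl: extract_biomarkers(tr, beat=config.beat)
               for bcl, tr in traces.items()}
    return records, traces


def simulate_stage(config: RunConfig, pops: pd.DataFrame, out: Path) -> pd.DataFrame:
    """Pace every cell, extracting biomarkers; resumable via biomarkers.csv."""
    bm_path = out / "biomarkers.csv"
    done = set()
    header_written = False
    if bm_path.exists():
        prev = pd.read_csv(bm_path)
        done = set(zip(prev["condition"], prev["cell"]))
        header_written = len(prev.columns) > 0
        if done:
            log.info("resuming: %d (condition, cell) pairs already simulated",
                     len(done))
    failures = []
    h5 = None
    if config.save_traces:
        import h5py

        h5 = h5py.File(out / "traces.h5", "a")
    cfg_hash = config.config_hash()
    t0 = time.time()
    n_total = len(pops)
    try:
        for count, row in enumerate(pops.itertuples(index=False)):
            key = (row.condition, row.cell)
            if key in done:
                continue
            sv = ScalingVector(**{p: getattr(row, p) for p in PARAM_NAMES})
            try:
                records, traces = simulate_cell(sv, config)
            except SolverError as err:
                log.warning("cell failed: %s", err)
                failures.append({"condition": row.condition, "cell": row.cell,
                                 **{p: getattr(sv, p) for p in PARAM_NAMES},
                                 "error": str(err)})
                continue
            seed = config.populations[row.condition].seed
            cell_rows = []
            for bcl, rec in records.items():
                out_row = {"condition": row.condition, "cell": row.cell,
                           "bcl": int(bcl), "seed": seed,
                           "config_hash": cfg_hash}
                out_row.update({p: getattr(sv, p) for p in PARAM_NAMES})
                out_row.update(rec.as_dict())
                cell_rows.append(out_row)
            if h5 is not None:
                for bcl, tr in traces.items():
                    grp = h5.require_group(f"{row.condition}/{row.cell}/{bcl}")
                    for name, arr in (("Vm", tr.vm), ("Cai", tr.cai)):
                        if name in grp:
                            del grp[name]
                        grp.create_dataset(name, data=arr)
            # checkpoint after every cell so interrupts lose at most one cell
            pd.DataFrame(cell_rows).to_csv(bm_path, index=False, mode="a",
                                           header=not header_written)
            header_written = True
            if (count + 1) % 50 == 0:
                log.info("simulated %d/%d cells (%.1f s elapsed)",
                         count + 1, n_total, time.time() - t0)
    finally:
        if h5 is not None:
            h5.close()
    table = pd.read_csv(bm_path)
    if failures:
        pd.DataFrame(failures).to_csv(out / "failed_cells.csv", index=False)
    return table


def regress_stage(config: RunConfig, table: pd.DataFrame, out: Path) -> pd.DataFrame:
    results = regress_all(table, standardize_x=config.standardize_x,
                          min_rows_factor=config.min_rows_factor)
    df = results_frame(results)
    df.to_csv(out / "regression.csv", index=False)
    return df


def summarize_stage(config: RunConfig, table: pd.DataFrame, out: Path) -> pd.DataFrame:
    have_both = {"non-failing", "failing"} <= set(table["condition"].unique())
    summary = summary_table(table) if have_both else pd.DataFrame()
    summary.to_csv(out / "summary.csv", index=False)
    alternans_counts(table).to_csv(out / "alternans.csv", index=False)
    return summary


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages; returns the output directory.

    Re-running with the same config reproduces biomarkers.csv exactly
    (sampling is seed-driven and integration is deterministic); a partially
    complete biomarkers.csv is resumed, not recomputed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    config.to_yaml(out / "config.yaml")
    timings = {}
    stages = [("sample", sample_stage)]
    t_all = time.time()
    pops = None
    for name, fn in stages:
        t0 = time.time()
        pops = fn(config, out)
        timings[name] = time.time() - t0
        log.info("stage %-9s %.2f s", name, timings[name])
    for name, fn in (("simulate", simulate_stage),
                     ("regress", regress_stage),
                     ("summarize", summarize_stage)):
        t0 = time.time()
        result = fn(config, pops if name == "simulate" else table, out)
        if name == "simulate":
            table = result
        timings[name] = time.time() - t0
        log.info("stage %-9s %.2f s", name, timings[name])
    snapshot = {"config": config.to_dict(), "config_hash": config.config_hash(),
                "version": _pkg_version(), "timings": timings,
                "total_seconds": time.time() - t_all}
    (out / "run.json").write_text(json.dumps(snapshot, indent=2, default=str))
    return out


def _setup_logging(out: Path) -> None:
    log.setLevel(logging.INFO)
    have_file = any(isinstance(h, logging.FileHandler)
                    and Path(getattr(h, "baseFilename", "")) == (out / "run.log").resolve()
                    for h in log.handlers)
    if not have_file:
        fh = logging.FileHandler(out / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(fh)
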