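"""Descriptive statistics over population biomarker tables.

Per-biomarker medians and failing-vs-non-failing percent changes, pairwise
biomarker correlations, and alternans incidence as a function of each
conductance scaling.  Exclusions (non-captured cells; for correlations also
alternans cells) mirror the regression module so that all reported
statistics refer to the same subpopulations.  Plotting helpers are
presentation-only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .biomarkers import BIOMARKER_NAMES
from .scalings import PARAM_NAMES

NON_FAILING, FAILING = "non-failing", "failing"


def _bcl_slice(table: pd.DataFrame, bcl: int) -> pd.DataFrame:
    sub = table[table["bcl"] == bcl]
    if sub.empty:
        raise ValueError(f"no rows at BCL={bcl} ms")
    return sub


def median_change(table: pd.DataFrame, biomarker: str, bcl: int) -> dict:
    """NF/HF medians of a biomarker at one BCL plus the percent change.

    ``percent_change`` is 100 * (median_HF - median_NF) / median_NF, sign
    preserved.  Non-captured and alternans-flagged cells are excluded
    consistently with the regression fits.
    """
    if biomarker not in table.columns:
        raise KeyError(f"biomarker {biomarker!r} not present in table")
    sub = _bcl_slice(table, bcl)
    kept = sub[sub["captured"].astype(bool)
               & ~sub["alternans_V"].astype(bool)
               & ~sub["alternans_Ca"].astype(bool)]
    med = {}
    for cond, key in ((NON_FAILING, "median_NF"), (FAILING, "median_HF")):
        vals = kept.loc[kept["condition"] == cond, biomarker].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"no usable {biomarker} values for {cond} at {bcl} ms")
        med[key] = float(np.median(vals))
    med["percent_change"] = 100.0 * (med["median_HF"] - med["median_NF"]) / med["median_NF"]
    med["n_NF"] = int((kept["condition"] == NON_FAILING).sum())
    med["n_HF"] = int((kept["condition"] == FAILING).sum())
    med["n_excluded"] = int(len(sub) - len(kept))
    return med


def summary_table(table: pd.DataFrame, biomarkers=BIOMARKER_NAMES,
                  bcls=None) -> pd.DataFrame:
    """Tidy medians/percent-change table over biomarkers and BCLs."""
    if bcls is None:
        bcls = sorted(table["bcl"].unique(), reverse=True)
    rows = []
    for bcl in bcls:
        for bm in biomarkers:
            rec = median_change(table, bm, int(bcl))
            rec.update(bcl=int(bcl), biomarker=bm)
            rows.append(rec)
    return pd.DataFrame(rows)


def pairwise_correlations(table: pd.DataFrame, condition: str,
                          bcl: int, biomarkers=BIOMARKER_NAMES) -> pd.DataFrame:
    """Pearson correlation matrix of the biomarkers for one condition/BCL.

    Alternans and non-captured cells are removed first.  Degenerate
    (constant) biomarkers yield NaN entries off the unit diagonal.
    """
    sub = _bcl_slice(table, bcl)
    sub = sub[(sub["condition"] == condition)
              & sub["captured"].astype(bool)
              & ~sub["alternans_V"].astype(bool)
              & ~sub["alternans_Ca"].astype(bool)]
    if sub.empty:
        raise ValueError(f"no usable cells for {condition} at {bcl} ms")
    mat = sub[list(biomarkers)].astype(float)
    corr = mat.corr()
    np.fill_diagonal(corr.values, 1.0)
    return corr


def alternans_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Cells flagged for voltage/calcium alternans per condition and BCL."""
    rows = []
    for (cond, bcl), sub in table.groupby(["condition", "bcl"]):
        rows.append({
            "condition": cond, "bcl": int(bcl), "n_cells": len(sub),
            "n_alternans_V": int(sub["alternans_V"].astype(bool).sum()),
            "n_alternans_Ca": int(sub["alternans_Ca"].astype(bool).sum()),
            "n_alternans_any": int((sub["alternans_V"].astype(bool)
                                    | sub["alternans_Ca"].astype(bool)).sum()),
            "n_not_captured": int((~sub["captured"].astype(bool)).sum()),
        })
    return pd.DataFrame(rows).sort_values(["condition", "bcl"],
                                          ascending=[True, False]).reset_index(drop=True)


def alternans_map(table: pd.DataFrame, bcl: int, n_bins: int = 10):
    """Alternans incidence per parameter, binned over each scaling's range.

    Returns ``(incidence, counts)``: ``incidence`` has one row per
    (condition, parameter, bin) with the fraction of cells in that scaling
    bin showing alternans (voltage or calcium); ``counts`` are the scalar
    totals per condition.
    """
    sub = _bcl_slice(table, bcl)
    flagged = sub["alternans_V"].astype(bool) | sub["alternans_Ca"].astype(bool)
    rows = []
    for cond, csub in sub.groupby("condition"):
        cflag = flagged.loc[csub.index]
        for p in PARAM_NAMES:
            vals = csub[p].to_numpy(dtype=float)
            edges = np.linspace(vals.min(), vals.max(), n_bins + 1)
            idx = np.clip(np.digitize(vals, edges) - 1, 0, n_bins - 1)
            for b in range(n_bins):
                in_bin = idx == b
                n = int(in_bin.sum())
                rows.append({
                    "condition": cond, "parameter": p, "bin": b,
                    "bin_low": edges[b], "bin_high": edges[b + 1],
                    "n_cells": n,
                    "incidence": float(cflag.to_numpy()[in_bin].mean()) if n else 0.0,
                })
    incidence = pd.DataFrame(rows)
    counts = {cond: int(flagged[sub["condition"] == cond].sum())
              for cond in sub["condition"].unique()}
    return incidence, counts


# --- plotting (presentation only; no computation) --------------------------

def plot_histograms(table, biomarker, bcl, ax=None, bins="fd"):
    """Overlaid NF/HF histograms of one biomarker at one BCL."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sub = _bcl_slice(table, bcl)
    for cond, color in ((NON_FAILING, "tab:blue"), (FAILING, "tab:red")):
        vals = sub.loc[(sub["condition"] == cond)
                       & sub["captured"].astype(bool), biomarker]
        vals = vals[np.isfinite(vals)]
        if len(vals):
            ax.hist(vals, bins=bins, alpha=0.5, color=color, label=cond)
    ax.set_xlabel(biomarker)
    ax.set_ylabel("cells")
    ax.set_title(f"BCL = {bcl} ms")
    ax.legend()
    return ax


def plot_scatter_matrix(table, condition, bcl, biomarkers=BIOMARKER_NAMES):
    """Biomarker-vs-biomarker scatter matrix (alternans cells removed)."""
    import matplotlib.pyplot as plt

    sub = _bcl_slice(table, bcl)
    sub = sub[(sub["condition"] == condition)
              & sub["captured"].astype(bool)
              & ~sub["alternans_V"].astype(bool)
              & ~sub["alternans_Ca"].astype(bool)]
    k = len(biomarkers)
    fig, axes = plt.subplots(k, k, figsize=(2.2 * k, 2.2 * k))
    for i, bi in enumerate(biomarkers):
        for j, bj in enumerate(biomarkers):
            ax = axes[i, j]
            if i == j:
                ax.hist(sub[bi].dropna(), bins=20)
            else:
                ax.plot(sub[bj], sub[bi], ".", ms=2, alpha=0.4)
            if i == k - 1:
                ax.set_xlabel(bj)
            if j == 0:
                ax.set_ylabel(bi)
    fig.suptitle(f"{condition}, BCL = {bcl} ms")
    return fig


def plot_alternans_map(incidence, condition):
    """Heat map of alternans incidence per parameter bin."""
    import matplotlib.pyplot as plt

    sub = incidence[incidence["condition"] == condition]
    params = list(PARAM_NAMES)
    n_bins = sub["bin"].max() + 1
    grid = np.zeros((len(params), n_bins))
    for i, p in enumerate(params):
        grid[i] = sub[sub["parameter"] == p].sort_values("bin")["incidence"].to_numpy()
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(grid, aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(params)), params)
    ax.set_xlabel("scaling bin (low to high)")
    ax.set_title(f"alternans incidence, {condition}")
    fig.colorbar(im, ax=ax, label="fraction of cells")
    return fig
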