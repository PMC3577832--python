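"""Descriptive statistics: medians, correlations, alternans maps."""

import numpy as np
import pandas as pd
import pytest

from cardiopop import (PARAM_NAMES, SurrogateSpec, alternans_counts,
                       alternans_map, generate_biomarker_table, median_change,
                       pairwise_correlations)
from cardiopop.biomarkers import BIOMARKER_NAMES
from cardiopop.summary import summary_table


def _synthetic_table(nf_value=100.0, hf_value=120.0, n=30):
    rows = []
    for cond, val in (("non-failing", nf_value), ("failing", hf_value)):
        for i in range(n):
            row = {"condition": cond, "cell": i, "bcl": 1500,
                   "alternans_V": False, "alternans_Ca": False,
                   "captured": True}
            row.update({p: 1.0 for p in PARAM_NAMES})
            row.update({bm: val for bm in BIOMARKER_NAMES})
            rows.append(row)
    return pd.DataFrame(rows)


class TestMedianChange:
    def test_twenty_percent_increase_exact(self):
        res = median_change(_synthetic_table(100.0, 120.0), "APD80", 1500)
        assert res["median_NF"] == 100.0
        assert res["median_HF"] == 120.0
        assert res["percent_change"] == pytest.approx(20.0, abs=1e-12)

    def test_identical_populations_give_exactly_zero(self):
        res = median_change(_synthetic_table(100.0, 100.0), "CaTD80", 1500)
        assert res["percent_change"] == 0.0

    def test_sign_preserved_for_decrease(self):
        res = median_change(_synthetic_table(100.0, 60.0), "CaTMax", 1500)
        assert res["percent_change"] == pytest.approx(-40.0)

    def test_unknown_biomarker_rejected(self):
        with pytest.raises(KeyError, match="QT"):
            median_change(_synthetic_table(), "QT", 1500)

    def test_row_permutation_invariance(self):
        spec = SurrogateSpec(effects={"APD80": {"s_Kr": -90.0}},
                             noise_sd={"APD80": 4.0}, seed=1)
        nf = generate_biomarker_table(100, "non-failing", spec, seed=1)
        hf = generate_biomarker_table(100, "failing", spec, seed=2)
        table = pd.concat([nf, hf], ignore_index=True)
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = median_change(table, "APD80", 1500)
        b = median_change(shuffled, "APD80", 1500)
        assert a["median_NF"] == b["median_NF"]
        assert a["percent_change"] == b["percent_change"]

    def test_summary_table_covers_all_biomarkers(self):
        df = summary_table(_synthetic_table())
        assert set(df["biomarker"]) == set(BIOMARKER_NAMES)


class TestCorrelations:
    def test_linearly_dependent_biomarkers_correlate_exactly(self):
        table = _synthetic_table()
        rng = np.random.default_rng(0)
        base = rng.normal(100, 10, (table["condition"] == "non-failing").sum())
        mask = table["condition"] == "non-failing"
        table.loc[mask, "APD80"] = base
        table.loc[mask, "APD3080"] = 2.0 * base + 5.0
        corr = pairwise_correlations(table, "non-failing", 1500,
                                     biomarkers=("APD80", "APD3080"))
        assert corr.loc["APD80", "APD3080"] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(np.diag(corr.values), 1.0)

    def test_matrix_is_symmetric_and_bounded(self):
        spec = SurrogateSpec(
            effects={"APD80": {"s_Kr": -90.0}, "CaTD80": {"s_up": -380.0}},
            noise_sd={bm: 1.0 for bm in BIOMARKER_NAMES}, seed=5)
        table = generate_biomarker_table(300, "non-failing", spec)
        corr = pairwise_correlations(table, "non-failing", 1500)
        assert np.allclose(corr.values, corr.values.T)
        assert (corr.values <= 1.0 + 1e-12).all()
        assert (corr.values >= -1.0 - 1e-12).all()

    def test_alternans_rows_removed_before_correlating(self):
        table = _synthetic_table()
        rng = np.random.default_rng(1)
        mask = table["condition"] == "non-failing"
        table.loc[mask, "APD80"] = rng.normal(100, 5, mask.sum())
        table.loc[mask, "APD3080"] = rng.normal(0.6, 0.05, mask.sum())
        flagged = table.index[mask][:5]
        table.loc[flagged, "alternans_V"] = True
        # give flagged rows wild values; they must not affect the result
        table.loc[flagged, ["APD80", "APD3080"]] = 1e6
        corr = pairwise_correlations(table, "non-failing", 1500,
                                     biomarkers=("APD80", "APD3080"))
        assert abs(corr.loc["APD80", "APD3080"]) < 0.5


class TestAlternansMaps:
    def test_zero_flags_give_all_zero_map(self):
        table = _synthetic_table()
        incidence, counts = alternans_map(table, 1500)
        assert (incidence["incidence"] == 0.0).all()
        assert counts == {"non-failing": 0, "failing": 0}

    def test_counts_table(self):
        table = _synthetic_table()
        hf_idx = table.index[table["condition"] == "failing"]
        table.loc[hf_idx[:3], "alternans_V"] = True
        table.loc[hf_idx[3:5], "alternans_Ca"] = True
        table.loc[hf_idx[5:6], "captured"] = False
        counts = alternans_counts(table)
        row = counts[counts["condition"] == "failing"].iloc[0]
        assert row["n_alternans_V"] == 3
        assert row["n_alternans_Ca"] == 2
        assert row["n_alternans_any"] == 5
        assert row["n_not_captured"] == 1

    def test_incidence_concentrates_where_flags_are_planted(self):
        spec = SurrogateSpec(seed=9)
        table = generate_biomarker_table(400, "non-failing", spec, seed=9)
        lo, hi = table["s_up"].min(), table["s_up"].max()
        flagged = table["s_up"] < lo + (hi - lo) / 5  # plant at low SERCA
        # (threshold aligned with the lowest of the five equal-width bins)
        table["alternans_Ca"] = flagged
        incidence, counts = alternans_map(table, 1500, n_bins=5)
        sup = incidence[(incidence["parameter"] == "s_up")
                        & (incidence["condition"] == "non-failing")]
        assert sup.iloc[0]["incidence"] == 1.0   # lowest bin fully flagged
        assert sup.iloc[-1]["incidence"] == 0.0  # highest bin clean
        assert counts["non-failing"] == int(flagged.sum())
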