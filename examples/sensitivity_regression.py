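"""Attribute biomarker variability to individual ionic conductances.

Paces a 100-cell non-failing population at 1500 ms, standardizes each
biomarker, and fits it against the seven conductance scalings.  The
coefficients say how many response standard deviations a one-SD change in
each scaling moves the biomarker; the study's headline finding is the
dominant negative I_Kr coefficient on APD80 (around -0.9) and the
SERCA/NCX control of the calcium-transient biomarkers.
"""

import pandas as pd

from cardiopop import (PARAM_NAMES, PopulationSpec, extract_biomarkers,
                       make_cell, sample_population, single_bcl_run)
from cardiopop.regression import fit_biomarker

rows = []
for i, sv in enumerate(sample_population(
        PopulationSpec("non-failing", n_cells=100, seed=5))):
    trace, _ = single_bcl_run(make_cell(sv), bcl=1500, n_paces=100)
    rec = extract_biomarkers(trace).as_dict()
    rec.update(condition="non-failing", cell=i, bcl=1500,
               **{p: getattr(sv, p) for p in PARAM_NAMES})
    rows.append(rec)
table = pd.DataFrame(rows)

print(f"{'biomarker':10s}" + "".join(f"{p:>9s}" for p in PARAM_NAMES) + f"{'R^2':>7s}")
for bm in ("APD80", "APD3080", "CaTD80", "CaTD3080", "CaTMax", "DAPCaT"):
    res = fit_biomarker(table, "non-failing", 1500, bm)
    coefs = "".join(f"{res.coefficients[p]:9.2f}" for p in PARAM_NAMES)
    print(f"{bm:10s}{coefs}{res.r_squared:7.2f}")
print("\nAPD80 is governed by s_Kr; CaT duration/shape by s_up and s_NaCa, "
      "opposed by s_CaL — the study's sensitivity structure.")
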