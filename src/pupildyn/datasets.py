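"""Published clinical-covariate summaries of the reference TBI coma cohort.

These are group-level descriptive statistics (n = 21 admitted patients,
15 favorable / 6 unfavorable at 6 months) — means and SDs for quantitative
covariates and per-group counts for categorical findings. Patient-level
series were never published, but these printed summaries are sufficient
inputs for the pooled-t and chi-square covariate comparisons.
"""

from __future__ import annotations

import numpy as np

#: Quantitative covariates: (mean_F, sd_F, n_F, mean_U, sd_U, n_U)
QUANTITATIVE = {
    "age_years": (43.06, 16.15, 15, 46.0, 23.12, 6),
    "sedation_days": (10.0, 6.0, 15, 8.0, 7.0, 6),
    "icu_stay_days": (18.0, 8.0, 15, 15.0, 12.0, 6),
}

#: Binary CT/management findings: (present_F, absent_F, present_U, absent_U)
BINARY_COUNTS = {
    "tsah": (12, 3, 0, 6),
    "edh": (5, 10, 0, 6),
    "ivh": (0, 15, 1, 5),
    "neurosurgery": (3, 12, 3, 3),
    "invasive_neuromonitoring": (10, 5, 5, 1),
}

#: Marshall CT score distribution, categories (II, III, V, VI), rows F then U.
MARSHALL_TABLE = np.array([[10, 2, 1, 2], [1, 3, 2, 0]])


def clinical_summary_table():
    """Run every reproducible covariate comparison; returns a DataFrame."""
    import pandas as pd

    from .stats import chi2_2x2_yates, chi2_rxc, pooled_t_from_summary

    rows = []
    for name, (m1, s1, n1, m2, s2, n2) in QUANTITATIVE.items():
        t, p = pooled_t_from_summary(m1, s1, n1, m2, s2, n2)
        rows.append({"variable": name, "test": "pooled_t", "statistic": abs(t),
                     "df": n1 + n2 - 2, "p": p})
    for name, (a, b, c, d) in BINARY_COUNTS.items():
        chi2, p = chi2_2x2_yates(a, b, c, d)
        rows.append({"variable": name, "test": "chi2_yates", "statistic": chi2,
                     "df": 1, "p": p})
    chi2, df, p = chi2_rxc(MARSHALL_TABLE)
    rows.append({"variable": "marshall_score", "test": "chi2_pearson",
                 "statistic": chi2, "df": df, "p": p})
    return pd.DataFrame(rows)
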