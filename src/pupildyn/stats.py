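"""Group-level inference: mixed repeated-measures ANOVA, the six post-hoc
contrasts, and summary-statistic tests for clinical covariates.

The central design is a 2x2 mixed ANOVA — outcome group (favorable vs
unfavorable) as the between-subject factor and period (during vs after
sedation) as the within-subject factor — run separately on each pupillary
index, with Bonferroni correction over six post-hoc comparisons. Covariate
tables are compared with a pooled-variance two-sample t for quantitative
variables, a Yates-corrected chi-square for 2x2 counts, and a plain Pearson
chi-square for r x c counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class InsufficientDataError(ValueError):
    """A group has too few complete patients for the requested test."""


@dataclass(frozen=True)
class AnovaResult:
    """F, p and degrees of freedom for the three effects of the 2x2 design."""

    F_between: float
    p_between: float
    df_between: tuple[int, int]
    F_within: float
    p_within: float
    df_within: tuple[int, int]
    F_interaction: float
    p_interaction: float
    df_interaction: tuple[int, int]
    n_complete: int

    def as_dict(self) -> dict:
        return {
            "F_between": self.F_between, "p_between": self.p_between,
            "df_between": list(self.df_between),
            "F_within": self.F_within, "p_within": self.p_within,
            "df_within": list(self.df_within),
            "F_interaction": self.F_interaction, "p_interaction": self.p_interaction,
            "df_interaction": list(self.df_interaction),
            "n_complete": self.n_complete,
        }


@dataclass(frozen=True)
class PosthocResult:
    comparison: str
    t: float
    df: int
    p_raw: float
    p_bonferroni: float


def _complete_cases(pre, post, groups):
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    groups = np.asarray(groups)
    if not (len(pre) == len(post) == len(groups)):
        raise ValueError("pre, post and groups must have equal length")
    ok = np.isfinite(pre) & np.isfinite(post)
    pre, post, groups = pre[ok], post[ok], groups[ok]
    labels = np.unique(groups)
    if len(labels) != 2:
        raise InsufficientDataError(f"exactly 2 groups required, got {list(labels)}")
    for g in labels:
        if (groups == g).sum() < 2:
            raise InsufficientDataError(f"group {g!r} has < 2 complete patients")
    return pre, post, groups, labels


def mixed_anova(pre, post, groups) -> AnovaResult:
    """2x2 mixed ANOVA: between = group, within = period (PRE/POST).

    Patients with a missing PRE or POST value are excluded listwise. With zero
    error variance the F ratios are undefined and returned as NaN with a
    warning rather than raising.
    """
    import pingouin as pg

    pre, post, groups, _ = _complete_cases(pre, post, groups)
    n = len(pre)
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), 2),
            "group": np.repeat(groups, 2),
            "period": np.tile(["pre", "post"], n),
            "y": np.column_stack([pre, post]).ravel(),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            aov = pg.mixed_anova(long, dv="y", within="period", subject="subject",
                                 between="group").set_index("Source")
        except Exception:  # degenerate input (e.g. zero variance everywhere)
            warnings.warn("mixed ANOVA undefined (zero error variance); returning NaN",
                          stacklevel=2)
            nan = float("nan")
            df1, df2 = 1, n - 2
            return AnovaResult(nan, nan, (df1, df2), nan, nan, (df1, df2),
                               nan, nan, (df1, df2), n)

    def eff(src):
        row = aov.loc[src]
        # pingouin omits F/p columns entirely when the ratio is undefined
        F = float(row["F"]) if "F" in row.index else float("nan")
        p = float(row["p_unc"]) if "p_unc" in row.index else float("nan")
        if not np.isfinite(F):
            warnings.warn(f"{src} effect undefined (zero error variance)", stacklevel=2)
        return F, p, (int(row["DF1"]), int(row["DF2"]))

    Fb, pb, dfb = eff("group")
    Fw, pw, dfw = eff("period")
    Fi, pi_, dfi = eff("Interaction")
    return AnovaResult(Fb, pb, dfb, Fw, pw, dfw, Fi, pi_, dfi, n)


_SIX = (
    "U_pre vs F_pre",
    "U_post vs F_post",
    "F_pre vs F_post",
    "U_pre vs U_post",
    "group main (patient means)",
    "period main (pre vs post)",
)


def posthoc_six(pre, post, groups, *, favorable_label="FAVORABLE") -> list[PosthocResult]:
    """The six post-hoc contrasts of the 2x2 design, Bonferroni-corrected x6.

    Between-group contrasts (at PRE, at POST, and on patient means) use the
    pooled-variance independent-samples t; within-group and period contrasts
    use the paired t. Each raw p is multiplied by 6 and capped at 1.
    """
    pre, post, groups, labels = _complete_cases(pre, post, groups)
    fav = groups == favorable_label
    if favorable_label not in labels:
        # fall back: treat the first label as "favorable" side of the contrast
        fav = groups == labels[0]
    unf = ~fav

    results = []

    def indep(name, x_u, x_f):
        t, p = sps.ttest_ind(x_u, x_f, equal_var=True)
        results.append(PosthocResult(name, float(t), len(x_u) + len(x_f) - 2,
                                     float(p), min(1.0, 6.0 * float(p))))

    def paired(name, a, b):
        t, p = sps.ttest_rel(a, b)
        results.append(PosthocResult(name, float(t), len(a) - 1,
                                     float(p), min(1.0, 6.0 * float(p))))

    indep(_SIX[0], pre[unf], pre[fav])
    indep(_SIX[1], post[unf], post[fav])
    paired(_SIX[2], pre[fav], post[fav])
    paired(_SIX[3], pre[unf], post[unf])
    means = (pre + post) / 2.0
    indep(_SIX[4], means[unf], means[fav])
    paired(_SIX[5], pre, post)
    return results


def pooled_t_from_summary(mean1, sd1, n1, mean2, sd2, n2) -> tuple[float, float]:
    """Pooled-variance two-sample t from printed group summaries.

    df = n1 + n2 - 2; two-sided p. Zero pooled variance gives t = 0 for equal
    means and signed infinity otherwise.
    """
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    diff = mean1 - mean2
    if sp2 == 0:
        if diff == 0:
            return 0.0, 1.0
        return float(np.sign(diff)) * float("inf"), 0.0
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p)


def chi2_2x2_yates(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Yates continuity-corrected chi-square for the 2x2 table [[a,b],[c,d]].

    chi2 = n * max(0, |ad - bc| - n/2)^2 / ((a+b)(c+d)(a+c)(b+d)); p from
    chi-square with 1 df. The correction floors the statistic at 0 when
    |ad - bc| <= n/2.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("counts must be non-negative integers")
    n = a + b + c + d
    if n < 1:
        raise ValueError("empty table")
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("zero marginal: chi-square undefined")
    num = n * max(0.0, abs(a * d - b * c) - n / 2.0) ** 2
    chi2 = num / np.prod([float(m) for m in margins])
    p = float(sps.chi2.sf(chi2, 1))
    return float(chi2), p


def chi2_rxc(table) -> tuple[float, int, float]:
    """Plain Pearson chi-square for an r x c table; df = (r-1)(c-1)."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0):
        raise ValueError("table must be a 2-D array of non-negative counts")
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero marginal: chi-square undefined")
    expected = np.outer(rows, cols) / t.sum()
    chi2 = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return chi2, df, float(sps.chi2.sf(chi2, df))
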