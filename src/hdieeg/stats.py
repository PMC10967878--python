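"""Group-level statistics: normality-gated two-group tests, Friedman
repeated-measures comparison with a rank-based effect size, and
repeated-measures correlation.

The decision logic mirrors common practice in applied neuroergonomics:
Shapiro-Wilk gates the choice between Student's t and Mann-Whitney for
two-group comparisons; three or more within-subject conditions go to the
Friedman rank ANOVA, with Kendall's W (= chi2 / (n (k - 1))) reported as the
effect size; the common within-subject association between two repeated
variables is the repeated-measures correlation (subject-intercept ANCOVA,
Bakdash-Marusich formulation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "FriedmanResult",
    "RmCorrResult",
    "choose_two_group_test",
    "friedman",
    "rm_corr",
    "pairwise_posthoc",
]


@dataclass
class TestResult:
    name: str          # "t-test" or "mann-whitney" (or "wilcoxon")
    statistic: float
    p: float
    shapiro_p: tuple[float, float]


def choose_two_group_test(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.05,
    paired_alternative: bool = False,
) -> TestResult:
    """Two-group comparison with a Shapiro-Wilk normality gate.

    Shapiro-Wilk is run on each sample; if both p-values exceed ``alpha``
    the comparison uses Student's t-test, otherwise the Mann-Whitney U test.
    ``paired_alternative=True`` swaps the non-parametric branch for the
    Wilcoxon signed-rank test (for within-subject designs of equal length);
    the default follows the independent-samples convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least 3 observations per sample")
    sw_x = sps.shapiro(x).pvalue
    sw_y = sps.shapiro(y).pvalue
    if sw_x > alpha and sw_y > alpha:
        res = sps.ttest_ind(x, y)
        return TestResult("t-test", float(res.statistic), float(res.pvalue),
                          (sw_x, sw_y))
    if paired_alternative:
        res = sps.wilcoxon(x, y)
        return TestResult("wilcoxon", float(res.statistic), float(res.pvalue),
                          (sw_x, sw_y))
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return TestResult("mann-whitney", float(res.statistic), float(res.pvalue),
                      (sw_x, sw_y))


@dataclass
class FriedmanResult:
    chi_squared: float
    p: float
    eta_squared: float  # Kendall's W, the rank-based effect size
    n_subjects: int
    n_conditions: int


def _pivot_balanced(table: pd.DataFrame) -> pd.DataFrame:
    required = {"subject", "condition", "value"}
    if not required <= set(table.columns):
        raise ValueError(f"long table needs columns {sorted(required)}")
    wide = table.pivot_table(index="subject", columns="condition",
                             values="value", aggfunc="mean")
    if wide.isna().any().any():
        missing = wide.isna().sum().to_dict()
        raise ValueError(f"unbalanced design: missing cells per condition {missing}")
    return wide

def friedman(table: pd.DataFrame) -> FriedmanResult:
    """Friedman rank ANOVA on a long-format repeated-measures table.

    ``table`` holds one value per (subject, condition); the design must be
    balanced. The effect size is Kendall's W = chi2 / (n (k - 1)), the
    rank-concordance analogue reported alongside the chi-squared statistic.
    """
    wide = _pivot_balanced(table)
    n, k = wide.shape
    if k < 3:
        raise ValueError("Friedman test needs at least 3 conditions")
    arr = wide.to_numpy()
    if np.all(arr == arr[:, :1]):
        # every subject ties all conditions: no rank variation at all
        return FriedmanResult(0.0, 1.0, 0.0, n, k)
    chi2, p = sps.friedmanchisquare(*[arr[:, j] for j in range(k)])
    w = float(chi2) / (n * (k - 1))
    return FriedmanResult(float(chi2), float(p), w, n, k)


@dataclass
class RmCorrResult:
    r: float
    p: float
    dof: int
    n_subjects: int
    n_obs: int


def rm_corr(data: pd.DataFrame, x: str = "x", y: str = "y",
            subject: str = "subject") -> RmCorrResult:
    """Repeated-measures correlation: the common within-subject association
    between ``x`` and ``y`` across subjects (ANCOVA with subject intercepts;
    dof = N_obs - N_subjects - 1).

    Subjects with fewer than two paired observations are dropped with a
    warning; fewer than two usable subjects is an error.
    """
    import warnings

    import pingouin as pg

    df = data[[subject, x, y]].dropna()
    counts = df.groupby(subject).size()
    bad = counts[counts < 2].index.tolist()
    if bad:
        warnings.warn(
            f"dropping subjects with <2 paired observations: {bad}",
            stacklevel=2,
        )
        df = df[~df[subject].isin(bad)]
    k = df[subject].nunique()
    if k < 2:
        raise ValueError("rm_corr needs at least 2 subjects with >=2 observations")
    if k >= 3:
        res = pg.rm_corr(data=df, x=x, y=y, subject=subject)
        return RmCorrResult(
            r=float(res["r"].iloc[0]),
            p=float(res["pval"].iloc[0]),
            dof=int(res["dof"].iloc[0]),
            n_subjects=k,
            n_obs=len(df),
        )
    # two-subject edge: the ANCOVA partial correlation equals the plain
    # correlation of within-subject-centered x and y
    g = df.groupby(subject)
    xc = (df[x] - g[x].transform("mean")).to_numpy()
    yc = (df[y] - g[y].transform("mean")).to_numpy()
    r = float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))
    dof = len(df) - k - 1
    t = r * np.sqrt(dof / max(1e-300, 1 - r**2))
    p = float(2 * sps.t.sf(abs(t), dof))
    return RmCorrResult(r=r, p=p, dof=dof, n_subjects=k, n_obs=len(df))


def pairwise_posthoc(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Post-hoc pairwise Wilcoxon signed-rank tests with Bonferroni
    correction over all condition pairs (the omnibus Friedman does not say
    *which* conditions differ)."""
    wide = _pivot_balanced(table)
    conds = list(wide.columns)
    pairs = [(a, b) for i, a in enumerate(conds) for b in conds[i + 1 :]]
    rows = []
    for a, b in pairs:
        stat, p = sps.wilcoxon(wide[a], wide[b])
        rows.append({"a": a, "b": b, "statistic": float(stat), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(out["p_raw"] * len(pairs), 1.0)
    out["significant"] = out["p_bonferroni"] < alpha
    return out
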