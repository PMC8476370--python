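"""The statistical battery: trend, location, and factorial tests.

Everything returns a :class:`StatResult` so the pipeline can serialize a
flat results file.  The Mann-Kendall trend test is implemented here
(S-statistic, tie-corrected variance, continuity-corrected normal
approximation); t tests and the Mann-Whitney U come from scipy, and the
factorial ANOVA / ANCOVA are Type III sums of squares with sum-to-zero
effect coding fitted through statsmodels, the convention that handles
the unbalanced cells produced by post-hoc learner sorting.  Tukey
pairwise comparisons use the Tukey-Kramer adjustment for unequal n.
All p values are two-sided.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence as TypingSequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class StatResult:
    test_name: str
    statistic: float
    df: tuple[float, ...] = ()
    p_value: float = float("nan")
    effect_sizes: dict[str, float] = field(default_factory=dict)
    group_summaries: list[dict] = field(default_factory=list)
    term: str = ""
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "term": self.term,
            "statistic": float(self.statistic),
            "df": [float(v) for v in self.df],
            "p_value": float(self.p_value),
            "effect_sizes": {k: float(v) for k, v in self.effect_sizes.items()},
            "group_summaries": self.group_summaries,
            **({"extras": self.extras} if self.extras else {}),
        }


def _summary(label: str, x: np.ndarray) -> dict:
    return {
        "label": label,
        "n": int(len(x)),
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if len(x) > 1 else float("nan"),
    }


# ---------------------------------------------------------------------------
# Mann-Kendall
# ---------------------------------------------------------------------------

def mann_kendall(series: TypingSequence[float]) -> StatResult:
    """Mann-Kendall test for a monotonic trend in an ordered series.

    S = sum_{i<j} sign(x_j - x_i); tau is S normalized with the tie
    correction (time itself is untied); the p value uses the normal
    approximation with tie-adjusted variance and continuity correction.
    An all-equal series returns tau 0, p 1.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("Mann-Kendall needs at least 3 observations")
    diff_sign = np.sign(x[None, :] - x[:, None])
    s = float(np.triu(diff_sign, k=1).sum())
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    d0 = n * (n - 1) / 2.0
    tie_pairs = float((ties * (ties - 1) / 2.0).sum())
    denom = np.sqrt(d0 * (d0 - tie_pairs))
    tau = 0.0 if denom == 0 else s / denom
    var_s = (
        n * (n - 1) * (2 * n + 5) - float((ties * (ties - 1) * (2 * ties + 5)).sum())
    ) / 18.0
    if var_s <= 0 or s == 0:
        z = 0.0
    elif s > 0:
        z = (s - 1) / np.sqrt(var_s)
    else:
        z = (s + 1) / np.sqrt(var_s)
    p = 2.0 * scipy.stats.norm.sf(abs(z))
    return StatResult(
        test_name="mann_kendall",
        statistic=tau,
        p_value=float(min(p, 1.0)),
        effect_sizes={"tau": tau},
        extras={"S": s, "var_S": var_s, "z": float(z), "n": n},
    )


# ---------------------------------------------------------------------------
# location tests
# ---------------------------------------------------------------------------

def one_sample_t(values: TypingSequence[float], mu0: float = 0.0) -> StatResult:
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("zero variance: t statistic undefined")
    t, p = scipy.stats.ttest_1samp(x, mu0)
    d = (np.mean(x) - mu0) / sd
    return StatResult(
        test_name="one_sample_t",
        statistic=float(t),
        df=(len(x) - 1,),
        p_value=float(p),
        effect_sizes={"cohen_d": float(d)},
        group_summaries=[_summary("values", x)],
    )


def independent_t(a: TypingSequence[float], b: TypingSequence[float]) -> StatResult:
    """Two-sample t with pooled variance; d uses the pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    pooled_var = (
        (len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1)
    ) / (len(a) + len(b) - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    t, p = scipy.stats.ttest_ind(a, b, equal_var=True)
    d = (np.mean(a) - np.mean(b)) / np.sqrt(pooled_var)
    return StatResult(
        test_name="independent_t",
        statistic=float(t),
        df=(len(a) + len(b) - 2,),
        p_value=float(p),
        effect_sizes={"cohen_d": float(d)},
        group_summaries=[_summary("a", a), _summary("b", b)],
    )


def mann_whitney_u(a: TypingSequence[float], b: TypingSequence[float]) -> StatResult:
    """Mann-Whitney U, normal approximation with tie correction and continuity."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    res = scipy.stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    u = float(res.statistic)
    rank_biserial = 1.0 - 2.0 * u / (len(a) * len(b))
    return StatResult(
        test_name="mann_whitney_u",
        statistic=u,
        p_value=float(res.pvalue),
        effect_sizes={"rank_biserial": rank_biserial},
        group_summaries=[_summary("a", a), _summary("b", b)],
    )


# ---------------------------------------------------------------------------
# factorial models
# ---------------------------------------------------------------------------

def _check_cells(table: pd.DataFrame, factors: TypingSequence[str]) -> None:
    levels = [sorted(table[f].unique()) for f in factors]
    sizes = table.groupby(list(factors), observed=False).size()
    for cell in itertools.product(*levels):
        key = cell if len(cell) > 1 else cell[0]
        n = int(sizes.get(key, 0))
        if n == 0:
            raise ValueError(f"empty cell {dict(zip(factors, cell))}")
        if n < 2:
            raise ValueError(f"cell {dict(zip(factors, cell))} has fewer than 2 observations")


def _anova_formula(response: str, factors: TypingSequence[str], covariate: str | None) -> str:
    terms = " * ".join(f"C({f}, Sum)" for f in factors)
    if covariate:
        terms = f"{terms} + {covariate}"
    return f"{response} ~ {terms}"


def _pretty_term(raw: str, factors: TypingSequence[str]) -> str:
    name = raw
    for f in factors:
        name = name.replace(f"C({f}, Sum)", f)
    return name.replace(":", " x ")


def _anova_results(
    table: pd.DataFrame,
    factors: TypingSequence[str],
    response: str,
    covariate: str | None,
    ss_type: int,
    test_name: str,
) -> list[StatResult]:
    model = smf.ols(_anova_formula(response, factors, covariate), data=table).fit()
    aov = sm.stats.anova_lm(model, typ=ss_type)
    ss_resid = float(aov.loc["Residual", "sum_sq"])
    df_resid = float(aov.loc["Residual", "df"])
    rows = [r for r in aov.index if r not in ("Residual", "Intercept")]
    ss_total = float(sum(aov.loc[r, "sum_sq"] for r in rows)) + ss_resid
    results = []
    for row in rows:
        ss = float(aov.loc[row, "sum_sq"])
        results.append(
            StatResult(
                test_name=test_name,
                term=_pretty_term(row, factors),
                statistic=float(aov.loc[row, "F"]),
                df=(float(aov.loc[row, "df"]), df_resid),
                p_value=float(aov.loc[row, "PR(>F)"]),
                effect_sizes={
                    "eta_sq": ss / ss_total,
                    "partial_eta_sq": ss / (ss + ss_resid),
                },
                extras={"sum_sq": ss, "ss_resid": ss_resid},
            )
        )
    return results


def factorial_anova(
    table: pd.DataFrame,
    factors: TypingSequence[str],
    response: str,
    ss_type: int = 3,
) -> list[StatResult]:
    """Between-subjects factorial ANOVA (Type III, effect coding).

    ``factors`` are column names of categorical factors (e.g. training,
    testing, learner_class); all main effects and interactions are
    reported with classical and partial eta squared.  Empty cells raise
    with the cell named.
    """
    _check_cells(table, factors)
    return _anova_results(table, factors, response, None, ss_type, "factorial_anova")


def ancova(
    table: pd.DataFrame,
    factors: TypingSequence[str],
    covariate: str,
    response: str,
    ss_type: int = 3,
) -> list[StatResult]:
    """Factorial ANCOVA: Type III tests for factors, interaction and covariate."""
    _check_cells(table, factors)
    return _anova_results(table, factors, response, covariate, ss_type, "ancova")


def simple_effects(
    table: pd.DataFrame,
    factor: str,
    across: str,
    response: str,
) -> list[StatResult]:
    """Effect of ``factor`` within each level of ``across``.

    Each simple effect is a one-way ANOVA on the subset, i.e. it uses the
    within-level error term.
    """
    out = []
    for level in sorted(table[across].unique()):
        sub = table[table[across] == level]
        res = _anova_results(sub, [factor], response, None, 3, "simple_effect")
        for r in res:
            r.term = f"{factor} | {across}={level}"
        out.extend(res)
    return out


def tukey_pairwise(
    table: pd.DataFrame,
    group: str,
    response: str,
    alpha: float = 0.05,
) -> list[StatResult]:
    """Tukey-Kramer pairwise comparisons between the levels of ``group``."""
    hsd = pairwise_tukeyhsd(table[response].to_numpy(float), table[group].to_numpy(), alpha=alpha)
    groups = list(hsd.groupsunique)
    pairs = list(itertools.combinations(groups, 2))
    results = []
    for (g1, g2), diff, p, (lo, hi), reject in zip(
        pairs, hsd.meandiffs, hsd.pvalues, hsd.confint, hsd.reject
    ):
        results.append(
            StatResult(
                test_name="tukey_kramer",
                term=f"{g1} vs {g2}",
                statistic=float(diff),
                p_value=float(p),
                extras={"lower": float(lo), "upper": float(hi), "reject": bool(reject)},
            )
        )
    return results
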