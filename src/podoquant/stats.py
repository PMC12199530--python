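"""Group statistics: normality-dispatched tests, control-referenced multiple
comparisons, Pearson correlation, and ΔΔCt relative quantification.

Dispatch mirrors common practice for imaging and qPCR readouts: normality of
each group is assessed with the Kolmogorov–Smirnov test in its
estimated-parameters form (Lilliefors — the only meaningful variant when the
normal's mean and SD come from the sample itself). Normally distributed data
get parametric tests — Welch's t for two groups, Brown–Forsythe-corrected
one-way ANOVA (the F* statistic robust to unequal variances) with Dunnett's
two-sided comparisons against a declared control for more — and non-normal
data fall back to Mann–Whitney U or Kruskal–Wallis (with Bonferroni-adjusted
Mann–Whitney comparisons vs control).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "NormalityResult",
    "ComparisonRecord",
    "ComparisonResult",
    "QpcrResult",
    "CorrelationResult",
    "test_normality",
    "brown_forsythe_anova",
    "compare_groups",
    "ddct_fold",
    "correlate",
]


@dataclass
class NormalityResult:
    statistic: float
    p_value: float
    is_normal: bool


@dataclass
class ComparisonRecord:
    """One group-vs-control comparison inside a multi-group test."""

    group: str
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass
class ComparisonResult:
    """Outcome of a dispatched group comparison.

    ``test_name`` records which branch ran; for multi-group data the
    per-comparison records carry raw and multiplicity-adjusted p-values
    against the declared control.
    """

    test_name: str
    statistic: float
    p_value: float
    all_normal: bool
    alpha: float = 0.05
    records: list[ComparisonRecord] = field(default_factory=list)


@dataclass
class QpcrResult:
    """Relative expression of one sample by the ΔΔCt method (fold = 2^(−ΔΔCt))."""

    sample_id: str
    group: str
    delta_ct: float
    delta_delta_ct: float
    fold: float


@dataclass
class CorrelationResult:
    n: int
    pearson_r: float
    r_squared: float
    p_value: float


def test_normality(values, alpha: float = 0.05) -> NormalityResult:
    """Kolmogorov–Smirnov normality test with estimated parameters (Lilliefors).

    Requires at least 5 observations and nonzero spread.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError(f"normality test needs n >= 5, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality undefined (zero SD)")
    stat, p = lilliefors(x, dist="norm")
    return NormalityResult(float(stat), float(p), bool(p >= alpha))


def brown_forsythe_anova(samples: list[np.ndarray]) -> tuple[float, float, float, float]:
    """Brown–Forsythe one-way ANOVA F* (robust to unequal variances).

    Returns ``(f_star, p, df1, df2)`` with Satterthwaite denominator degrees
    of freedom.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    k = len(samples)
    if k < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    n = np.array([len(s) for s in samples], dtype=float)
    m = np.array([s.mean() for s in samples])
    v = np.array([s.var(ddof=1) for s in samples])
    N = n.sum()
    grand = np.concatenate(samples).mean()
    num = np.sum(n * (m - grand) ** 2)
    w = (1.0 - n / N) * v
    den = w.sum()
    if den == 0:
        raise ValueError("all groups have zero variance")
    f_star = num / den
    c = w / den
    df1 = k - 1.0
    df2 = 1.0 / np.sum(c**2 / (n - 1.0))
    p = float(sps.f.sf(f_star, df1, df2))
    return float(f_star), p, df1, df2


def compare_groups(
    table: pd.DataFrame,
    control: str | None = None,
    alpha: float = 0.05,
    value_col: str = "value",
    group_col: str = "group",
) -> ComparisonResult:
    """Dispatch a group comparison on a tidy table.

    Two groups → Welch's t (normal) or Mann–Whitney U; more than two →
    Brown–Forsythe ANOVA with two-sided Dunnett comparisons vs ``control``
    (normal) or Kruskal–Wallis with Bonferroni-adjusted Mann–Whitney
    comparisons vs ``control``. Every group needs n >= 3; normality
    assessment (n >= 5 per group) marks data non-normal when any group
    rejects. Groups too small to test cannot reject normality, so they
    stay on the parametric branch.
    """
    groups = list(dict.fromkeys(table[group_col]))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    samples = {g: table.loc[table[group_col] == g, value_col].to_numpy(float) for g in groups}
    for g, s in samples.items():
        if len(s) < 3:
            raise ValueError(f"group {g!r} has n={len(s)} < 3")
        if not np.all(np.isfinite(s)):
            raise ValueError(f"group {g!r} contains non-finite values")

    try:
        all_normal = all(test_normality(s, alpha).is_normal for s in samples.values())
    except ValueError:
        # groups too small (or degenerate) for a normality test cannot reject
        # normality; stay on the parametric branch
        all_normal = True

    if len(groups) == 2:
        a, b = samples[groups[0]], samples[groups[1]]
        if all_normal:
            t = sps.ttest_ind(a, b, equal_var=False)
            return ComparisonResult("welch_t", float(t.statistic), float(t.pvalue), True, alpha)
        u = sps.mannwhitneyu(a, b, alternative="two-sided")
        return ComparisonResult("mann_whitney", float(u.statistic), float(u.pvalue), False, alpha)

    if control is None or control not in samples:
        raise ValueError("multi-group comparison requires a control group label")
    others = [g for g in groups if g != control]

    if all_normal:
        f_star, p, _, _ = brown_forsythe_anova(list(samples.values()))
        # fixed random state: the multivariate-t integration inside Dunnett's
        # adjustment is Monte Carlo, and results must be run-to-run identical
        res = sps.dunnett(
            *[samples[g] for g in others],
            control=samples[control],
            random_state=np.random.default_rng(0),
        )
        # raw p of each Dunnett t statistic (pooled-SD df = N - k), before
        # the multiplicity adjustment; the adjusted p can only be larger
        n_total = sum(len(s) for s in samples.values())
        df = n_total - len(groups)
        records = []
        for g, stat, p_adj in zip(others, np.atleast_1d(res.statistic), np.atleast_1d(res.pvalue)):
            p_raw = float(2.0 * sps.t.sf(abs(stat), df))
            records.append(
                ComparisonRecord(g, p_raw, float(p_adj), bool(p_adj < alpha))
            )
        return ComparisonResult(
            "brown_forsythe_anova_dunnett", float(f_star), float(p), True, alpha, records
        )

    h, p = sps.kruskal(*[samples[g] for g in groups])
    records = []
    m = len(others)
    for g in others:
        u = sps.mannwhitneyu(samples[g], samples[control], alternative="two-sided")
        p_raw = float(u.pvalue)
        p_adj = min(1.0, m * p_raw)
        records.append(ComparisonRecord(g, p_raw, p_adj, bool(p_adj < alpha)))
    return ComparisonResult("kruskal_wallis", float(h), float(p), False, alpha, records)


def ddct_fold(ct: pd.DataFrame, calibrator_group: str) -> list[QpcrResult]:
    """Relative fold expression by the ΔΔCt method.

    ``ct`` needs columns ``sample_id, group, target_ct, reference_ct``.
    ΔCt = target − reference per sample; ΔΔCt subtracts the calibrator
    group's mean ΔCt; fold = 2^(−ΔΔCt) (ideal doubling per cycle). The
    calibrator group's geometric-mean fold is exactly 1.
    """
    required = {"sample_id", "group", "target_ct", "reference_ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    vals = ct[["target_ct", "reference_ct"]].to_numpy(float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("Ct values must be finite")
    delta = ct["target_ct"].to_numpy(float) - ct["reference_ct"].to_numpy(float)
    calib = delta[(ct["group"] == calibrator_group).to_numpy()]
    if calib.size == 0:
        raise ValueError(f"calibrator group {calibrator_group!r} is empty")
    ddct = delta - calib.mean()
    # scalar power keeps fold == 2**(-ddct) bit-exact for downstream identities
    return [
        QpcrResult(str(s), str(g), float(d), float(dd), 2.0 ** (-float(dd)))
        for s, g, d, dd in zip(ct["sample_id"], ct["group"], delta, ddct)
    ]


def correlate(x, y) -> CorrelationResult:
    """Pearson correlation with two-sided p from the t distribution (n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(int(x.size), float(r), float(r**2), float(p))
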