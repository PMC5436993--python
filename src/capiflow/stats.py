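"""Vasodilator-challenge statistics, method agreement and protocol arithmetic.

The challenge protocol compares microcirculatory readouts (total vessel
density, venular flow velocity, APSI) across three conditions — native,
after topical acetylcholine (ACH, endothelium-dependent NO release) and
after topical nitroglycerin (NG, endothelium-independent NO donor).  The
statistical pathway is: one-way ANOVA across conditions, pairwise two-sample
tests with Benjamini-Hochberg correction, Mann-Whitney U and Fisher's exact
test for ancillary comparisons, Pearson correlation and Bland-Altman
analysis for manual-vs-automated method agreement.  Values are summarized as
mean +/- SEM.

`anova_from_summary` reconstructs the identical one-way ANOVA from printed
per-group (mean, SEM, n) summaries, so published tables can be checked
without raw data.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "CONDITIONS",
    "ClipMeasurement",
    "GroupSummary",
    "BlandAltmanResult",
    "PairwiseResult",
    "group_summary",
    "anova_oneway",
    "anova_from_summary",
    "bh_adjust",
    "pairwise_bh",
    "mann_whitney",
    "fisher_exact",
    "pearson_r",
    "bland_altman",
    "topical_dose",
    "simulate_challenge_table",
    "challenge_report",
]

CONDITIONS = ("native", "ACH", "NG")


@dataclass
class ClipMeasurement:
    """Per-clip analysis record (one CSV row of the measurement table)."""

    subject_id: str
    condition: str
    tvd_auto: float | None = None
    tvd_manual: float | None = None
    apsi: float | None = None
    st_velocity: float | None = None
    massey_total: int = 0
    source_id: str = ""

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        for name in ("tvd_auto", "tvd_manual"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def analyzable(self) -> bool:
        return self.massey_total < 10


@dataclass(frozen=True)
class GroupSummary:
    """Printed-table group summary: n, mean, SEM."""

    n: int
    mean: float
    sem: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("group summary requires n >= 2")
        if self.sem <= 0:
            raise ValueError("SEM must be > 0")

    @property
    def sd(self) -> float:
        return self.sem * np.sqrt(self.n)


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement of paired measurements via their differences."""

    bias: float
    precision: float  # SD of the differences
    loa_low: float
    loa_high: float
    n: int


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    p_raw: float
    p_adjusted: float
    statistic: float


def group_summary(values) -> GroupSummary:
    values = np.asarray(values, dtype=float)
    return GroupSummary(n=len(values), mean=float(values.mean()),
                        sem=float(values.std(ddof=1) / np.sqrt(len(values))))


def _validate_groups(groups):
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    out = []
    for i, g in enumerate(groups):
        g = np.asarray(g, dtype=float)
        if len(g) < 2:
            raise ValueError(f"group {i} has n < 2")
        if not np.all(np.isfinite(g)):
            raise ValueError(f"group {i} contains non-finite values")
        out.append(g)
    return out


def anova_oneway(groups) -> tuple[float, int, int, float]:
    """Classic fixed-effects one-way ANOVA: returns (F, df1, df2, p)."""
    groups = _validate_groups(groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    concat = np.concatenate(groups)
    if np.ptp(concat) == 0:  # all values identical: no effect, no noise
        return 0.0, df1, df2, 1.0
    f, p = sps.f_oneway(*groups)
    return float(f), df1, df2, float(p)


def anova_from_summary(summaries) -> tuple[float, int, int, float]:
    """One-way ANOVA reconstructed from per-group (n, mean, SEM).

    Between-group sum of squares comes from the group means and sizes;
    the pooled within-group mean square from n * SEM^2 = group variance with
    n_i - 1 degrees of freedom each.  Fed the exact summaries of raw
    samples, this reproduces :func:`anova_oneway` to floating-point
    accuracy.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 group summaries")
    ns = np.array([s.n for s in summaries], dtype=float)
    means = np.array([s.mean for s in summaries])
    variances = np.array([s.n * s.sem**2 for s in summaries])
    grand = np.sum(ns * means) / ns.sum()
    df1 = len(summaries) - 1
    df2 = int(ns.sum()) - len(summaries)
    ss_between = np.sum(ns * (means - grand) ** 2)
    ms_within = np.sum((ns - 1) * variances) / df2
    if ms_within == 0:
        return (0.0, df1, df2, 1.0) if ss_between == 0 else (np.inf, df1, df2, 0.0)
    f = (ss_between / df1) / ms_within
    return float(f), df1, df2, float(sps.f.sf(f, df1, df2))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.ndim != 1 or len(pvalues) == 0:
        raise ValueError("need a non-empty 1-D array of p-values")
    _, adjusted, _, _ = multipletests(pvalues, method="fdr_bh")
    return adjusted


def pairwise_bh(groups, labels=None, test: str = "welch") -> list[PairwiseResult]:
    """All unordered pairwise two-sample tests with BH step-up correction.

    ``test`` is ``"welch"`` (unequal-variance t, default) or ``"ranksum"``
    (Mann-Whitney U).  Adjusted p-values are the Benjamini-Hochberg
    step-up values, monotone and capped at 1.
    """
    groups = _validate_groups(groups)
    labels = list(labels) if labels is not None else [str(i) for i in range(len(groups))]
    if len(labels) != len(groups):
        raise ValueError("labels must match groups")
    pairs = list(itertools.combinations(range(len(groups)), 2))
    raws, statistics = [], []
    for i, j in pairs:
        if test == "welch":
            t, p = sps.ttest_ind(groups[i], groups[j], equal_var=False)
        elif test == "ranksum":
            t, p = mann_whitney(groups[i], groups[j])
        else:
            raise ValueError(f"unknown pairwise test {test!r}")
        raws.append(float(p))
        statistics.append(float(t))
    adjusted = bh_adjust(raws)
    return [
        PairwiseResult(pair=(labels[i], labels[j]), p_raw=r, p_adjusted=float(a), statistic=s)
        for (i, j), r, a, s in zip(pairs, raws, adjusted, statistics)
    ]


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact null enumeration for combined n <= 12 without ties, the normal
    approximation with tie correction otherwise.  Returns (U for x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= 12 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("table entries must be non-negative integers")
    _, p = sps.fisher_exact(table, alternative="two-sided")
    return float(p)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p (t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def bland_altman(a, b) -> BlandAltmanResult:
    """Bland-Altman agreement of paired measurements.

    Differences are oriented ``a - b`` (conventionally automated - manual;
    the orientation is logged).  Bias is their mean, precision their sample
    SD, limits of agreement bias +/- 1.96 SD.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    logger.info("Bland-Altman on %d pairs (orientation a - b): bias %.3f, precision %.3f",
                len(d), bias, sd)
    return BlandAltmanResult(bias=bias, precision=sd,
                             loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, n=len(d))


def topical_dose(volume_ml: float, concentration_mol_l: float, dilution: float = 1.0) -> float:
    """Amount of agent delivered per topical application, in micromoles.

    A drop of ``volume_ml`` of a ``concentration_mol_l`` stock, optionally
    pre-diluted by ``dilution``: amount = V * C / dilution.
    """
    if volume_ml <= 0 or concentration_mol_l <= 0 or dilution <= 0:
        raise ValueError("volume, concentration and dilution must be > 0")
    return volume_ml * 1e-3 * concentration_mol_l / dilution * 1e6


def simulate_challenge_table(
    summaries_by_condition: dict[str, GroupSummary],
    rng: np.random.Generator,
    variable: str = "value",
) -> pd.DataFrame:
    """Draw a synthetic per-subject challenge table.

    Each condition's per-subject values are normal with the summary's mean
    and per-subject SD (SEM * sqrt(n)).  Used to check that the analysis
    pathway reproduces significance *patterns* from published summaries.
    """
    rows = []
    for cond, s in summaries_by_condition.items():
        values = rng.normal(s.mean, s.sd, size=s.n)
        rows.extend(
            {"subject_id": f"{cond}-{i}", "condition": cond, variable: v}
            for i, v in enumerate(values)
        )
    return pd.DataFrame(rows)


def challenge_report(
    df: pd.DataFrame,
    variables: list[str],
    condition_col: str = "condition",
    test: str = "welch",
) -> pd.DataFrame:
    """Per-variable challenge summary: mean +/- SEM per condition, ANOVA p,
    and BH-adjusted pairwise significance letters (a = vs native, b = vs ACH).
    """
    records = []
    for var in variables:
        sub = df.dropna(subset=[var])
        groups, labels = [], []
        for cond in CONDITIONS:
            vals = sub.loc[sub[condition_col] == cond, var].to_numpy()
            if len(vals) >= 2:
                groups.append(vals)
                labels.append(cond)
        if len(groups) < 2:
            continue
        f, df1, df2, p = anova_oneway(groups)
        pw = pairwise_bh(groups, labels, test=test)
        sig = {r.pair: r.p_adjusted < 0.05 for r in pw}
        rec = {"variable": var, "anova_F": f, "anova_p": p}
        for cond, g in zip(labels, groups):
            s = group_summary(g)
            letters = ""
            if cond != "native" and sig.get(tuple(sorted(("native", cond), key=CONDITIONS.index))):
                letters += "a"
            if cond == "NG" and sig.get(("ACH", "NG")):
                letters += "b"
            rec[cond] = f"{s.mean:.2f} +/- {s.sem:.2f}{letters and ' ' + letters}"
        records.append(rec)
    return pd.DataFrame(records)
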