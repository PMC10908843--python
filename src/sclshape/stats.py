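"""Nonparametric group comparisons and the power computation.

Guided vs. self-produced comparisons are paired per (person, scene), so the
Wilcoxon signed-rank test applies; tier comparisons (Tiers 1-3 vs. Tier 4)
are between independent samples, so the Mann-Whitney U test applies. The
reported statistics follow the conventions consistent with the study's
tables: W = min(W+, W-) over the signed rank sums (zero differences
discarded, midranks for ties), and U is reported for the first group,
U_A = R_A - n_A (n_A + 1) / 2. p values come from exact enumeration where
feasible and from the tie-corrected normal approximation otherwise.

Feature-level outlier filtering reuses the 1.5 IQR fence per feature and
group before testing. The standardized mean difference d = |mean diff| / sd
and noncentral-t power computation reproduce the study's power check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import GUIDED, SELF
from .errors import InvalidParameterError, TooShortError
from .preprocess import iqr_fence

__all__ = [
    "TestReport", "PowerResult", "SignCounts", "filter_feature_outliers",
    "wilcoxon_signed_rank", "mann_whitney_u", "sign_pattern_counts",
    "smd", "t_power", "modality_tests", "tier_tests",
]


@dataclass
class TestReport:
    """One hypothesis test: statistic (W or U), two-sided p, sizes, context."""

    test: str
    statistic: float
    p: float
    n: tuple[int, ...]
    feature: str = ""
    modality: str = ""
    direction: str = ""

    def as_row(self) -> dict:
        return {"test": self.test, "feature": self.feature, "modality": self.modality,
                "statistic": self.statistic, "p": self.p,
                "n": "x".join(str(v) for v in self.n), "direction": self.direction}


@dataclass
class PowerResult:
    mean_diff: float
    sd: float
    d: float
    alpha: float
    n: int
    design: str
    power: float


@dataclass
class SignCounts:
    """Direct per-person counts of the dominant modality direction."""

    n_lower_in_self: int
    n_higher_in_self: int
    n_tied: int
    excluded: list[str]


def filter_feature_outliers(
    records: pd.DataFrame,
    feature: str,
    group_cols: tuple[str, ...] = ("phase",),
    k: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop records whose ``feature`` value lies outside the 1.5 IQR fence
    computed within each group (default: per modality).

    Groups with fewer than 4 records are left untouched (logged). Returns
    (filtered records, removal log with person/scene/group/value/reason).
    """
    keep = np.ones(len(records), dtype=bool)
    log_rows = []
    for key, grp in records.groupby(list(group_cols)):
        if len(grp) < 4:
            log_rows.append({"group": str(key), "person": "", "scene": "",
                             "value": np.nan, "reason": "group too small, skipped"})
            continue
        lo, hi = iqr_fence(grp[feature].to_numpy(), k)
        bad = grp[(grp[feature] < lo) | (grp[feature] > hi)]
        for _, row in bad.iterrows():
            log_rows.append({"group": str(key), "person": row.get("person", ""),
                             "scene": row.get("scene", ""), "value": row[feature],
                             "reason": f"outside [{lo:.4g}, {hi:.4g}]"})
        keep[records.index.get_indexer(bad.index)] = False
    log = pd.DataFrame(log_rows, columns=["group", "person", "scene", "value", "reason"])
    return records[keep].reset_index(drop=True), log


def _signed_rank_W(d: np.ndarray) -> tuple[float, float, int]:
    """(W = min(W+, W-), W+, n) after discarding zero differences."""
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    return min(w_plus, w_minus), w_plus, n


def wilcoxon_signed_rank(
    x: np.ndarray, y: np.ndarray, feature: str = "", modality: str = ""
) -> TestReport:
    """Paired Wilcoxon signed-rank test of x vs. y.

    Zero differences are discarded; |differences| are midranked;
    W = min(W+, W-). Exact two-sided p when n <= 25 without ties, else the
    tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidParameterError("paired samples must have equal length")
    d = x - y
    if np.all(d == 0):
        raise InvalidParameterError("all paired differences are zero")
    W, w_plus, n = _signed_rank_W(d)
    if n < 5:
        raise TooShortError(f"need >= 5 non-zero differences, got {n}")
    dd = d[d != 0]
    ties = np.unique(np.abs(dd)).size < dd.size
    method = "exact" if (n <= 25 and not ties) else "approx"
    res = sps.wilcoxon(dd, zero_method="wilcox", method=method)
    direction = "x<y" if w_plus < (n * (n + 1) / 4) else "x>y"
    return TestReport(test="wilcoxon", statistic=W, p=float(res.pvalue), n=(n,),
                      feature=feature, modality=modality, direction=direction)


def mann_whitney_u(
    x: np.ndarray, y: np.ndarray, feature: str = "", modality: str = ""
) -> TestReport:
    """Mann-Whitney U test between independent groups; U reported for x.

    Exact two-sided p when n_x * n_y <= 400 without ties, else the
    tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidParameterError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size * y.size <= 400 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u_x = float(res.statistic)
    direction = "x>y" if u_x > x.size * y.size / 2 else "x<y"
    return TestReport(test="mannwhitney", statistic=u_x, p=float(res.pvalue),
                      n=(x.size, y.size), feature=feature, modality=modality,
                      direction=direction)


def sign_pattern_counts(
    records: pd.DataFrame,
    feature: str,
    tol_frac: float = 0.05,
    min_scenes: int = 4,
) -> SignCounts:
    """Per-person majority direction of self-produced vs. guided values.

    A person whose |mean (self - guided)| across scenes is below
    ``tol_frac`` * pooled sd counts as tied ("almost the same"); otherwise
    the scene-wise majority (mean difference breaking a vote tie) decides.
    Persons with fewer than ``min_scenes`` paired scenes are excluded.
    """
    wide = records.pivot_table(index=["person", "scene"], columns="phase",
                               values=feature, aggfunc="first")
    pooled_sd = float(records[feature].std(ddof=1))
    tol = tol_frac * pooled_sd
    lower = higher = tied = 0
    excluded: list[str] = []
    for person, grp in wide.groupby(level="person"):
        paired = grp.dropna(subset=[GUIDED, SELF])
        if len(paired) < min_scenes:
            excluded.append(str(person))
            continue
        diff = paired[SELF] - paired[GUIDED]
        if abs(diff.mean()) < tol:
            tied += 1
            continue
        n_lower = int((diff < 0).sum())
        n_higher = int((diff > 0).sum())
        if n_lower > n_higher:
            lower += 1
        elif n_higher > n_lower:
            higher += 1
        else:
            lower, higher = (lower + 1, higher) if diff.mean() < 0 else (lower, higher + 1)
    return SignCounts(lower, higher, tied, excluded)


def smd(mean_diff: float, sd: float) -> float:
    """Standardized mean difference d = |mean difference| / sd."""
    if sd <= 0:
        raise InvalidParameterError(f"sd must be positive, got {sd}")
    return abs(mean_diff) / sd


def t_power(d: float, n: int, alpha: float = 0.05, design: str = "one-sample") -> float:
    """Two-sided power of a t test at effect size ``d`` from the noncentral
    t distribution.

    Noncentrality is d * sqrt(n) with df = n - 1 for one-sample/paired
    designs, and d * sqrt(n/2) with df = 2n - 2 for a two-sample design with
    n per group. At d = 0 the power equals alpha.
    """
    if n < 2:
        raise InvalidParameterError("n must be >= 2")
    if not 0 < alpha < 1:
        raise InvalidParameterError("alpha must be in (0, 1)")
    if design in ("one-sample", "paired"):
        df, nc = n - 1, d * np.sqrt(n)
    elif design == "two-sample":
        df, nc = 2 * n - 2, d * np.sqrt(n / 2.0)
    else:
        raise InvalidParameterError(f"unknown design {design!r}")
    t_crit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(1.0 - sps.nct.cdf(t_crit, df, nc) + sps.nct.cdf(-t_crit, df, nc))


def _paired_feature(records: pd.DataFrame, feature: str) -> tuple[np.ndarray, np.ndarray]:
    wide = records.pivot_table(index=["person", "scene"], columns="phase",
                               values=feature, aggfunc="first")
    wide = wide.dropna(subset=[GUIDED, SELF])
    return wide[GUIDED].to_numpy(), wide[SELF].to_numpy()


def modality_tests(
    records: pd.DataFrame,
    features: tuple[str, ...] = ("nSCL_mean", "nSCL_var", "nSCL_slope", "nSCL_nfsc"),
    filter_outliers: bool = True,
) -> list[TestReport]:
    """Wilcoxon guided-vs-self tests per feature (pairs: person x scene)."""
    out = []
    for feature in features:
        recs = records
        if filter_outliers:
            recs, _ = filter_feature_outliers(records, feature)
        guided, self_ = _paired_feature(recs, feature)
        rep = wilcoxon_signed_rank(guided, self_, feature=feature, modality="paired")
        rep.direction = rep.direction.replace("x", "guided").replace("y", "self")
        out.append(rep)
    return out


def tier_tests(
    records: pd.DataFrame,
    features: tuple[str, ...] = ("nSCL_mean", "nSCL_var", "nSCL_slope", "nSCL_nfsc"),
    filter_outliers: bool = True,
) -> list[TestReport]:
    """Mann-Whitney Tiers 1-3 vs. Tier 4 tests per feature and modality."""
    from .core import TIER_4, TIERS_1_3

    out = []
    for modality in (GUIDED, SELF):
        sub = records[records["phase"] == modality]
        for feature in features:
            recs = sub
            if filter_outliers:
                recs, _ = filter_feature_outliers(sub, feature, group_cols=("tier",))
            a = recs.loc[recs["tier"] == TIERS_1_3, feature].to_numpy()
            b = recs.loc[recs["tier"] == TIER_4, feature].to_numpy()
            rep = mann_whitney_u(a, b, feature=feature, modality=modality)
            rep.direction = rep.direction.replace("x", "tiers1_3").replace("y", "tier4")
            out.append(rep)
    return out
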