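"""Consecutive-planting-year effects on seed density and diversity.

Sites are grouped into three year classes (< 5 years, 5–7 years,
≥ 8 years of consecutive organic planting).  Responses (total seed
density, H′, λ, E, C) are compared across classes by one-way ANOVA with
unconditional LSD (least significant difference) pairwise tests on the
pooled error, plus Shapiro–Wilk normality and Levene homoscedasticity
diagnostics.  Total density and E are conventionally log(x+1)
transformed first.  Class means are labelled with a compact letter
display (insert-and-absorb): classes sharing no letter differ at the
stated α.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import ValidationError

YEAR_CLASS_LABELS = {1: "<5", 2: "5-7", 3: ">=8"}


def year_class(years: int) -> int:
    """Year class of a consecutive-planting-years value: 1 (<5),
    2 (5–7) or 3 (≥8)."""
    if years < 1:
        raise ValidationError("consecutive planting years must be >= 1")
    if years < 5:
        return 1
    if years < 8:
        return 2
    return 3


def _absorb(columns: list[set[int]]) -> list[set[int]]:
    """Drop letter columns contained in (or duplicating) another column."""
    kept = []
    for i, c in enumerate(columns):
        redundant = any(
            (c < other) or (c == other and j < i)
            for j, other in enumerate(columns)
            if j != i
        )
        if not redundant:
            kept.append(c)
    return kept


def compact_letters(
    levels: Sequence, means: Sequence[float], significant: np.ndarray
) -> dict:
    """Compact letter display by insert-and-absorb.

    ``significant[i, j]`` marks pairs that differ.  Letters are assigned
    in order of descending mean; levels sharing a letter do not differ.
    Deterministic given the mean ordering (ties broken by level label).
    """
    order = sorted(range(len(levels)), key=lambda i: (-means[i], str(levels[i])))
    columns: list[set[int]] = [set(range(len(levels)))]
    for a in range(len(levels)):
        for b in range(a + 1, len(levels)):
            if not significant[a, b]:
                continue
            for col in [c for c in columns if a in c and b in c]:
                columns.remove(col)
                columns.extend([col - {a}, col - {b}])
            columns = _absorb(columns)
    # letter order follows the best mean each column contains
    def col_rank(col):
        return min(order.index(i) for i in col) if col else len(order)

    columns.sort(key=col_rank)
    letters = {lv: "" for lv in levels}
    for k, col in enumerate(columns):
        ch = chr(ord("a") + k)
        for i in sorted(col, key=order.index):
            letters[levels[i]] += ch
    return letters


@dataclass
class TrendResult:
    response: str
    transform: str | None
    class_stats: pd.DataFrame  # index: class labels; columns n, mean, sd
    F: float
    df: tuple[int, int]
    p_value: float
    levene_p: float
    shapiro_p: float
    lsd_p: pd.DataFrame  # symmetric pairwise p-value matrix
    letters: dict
    alpha: float


def anova_lsd(
    values: Sequence[float],
    classes: Sequence,
    alpha: float = 0.05,
    transform: str | None = None,
    response: str = "",
) -> TrendResult:
    """One-way ANOVA with LSD pairwise comparisons and letter display.

    ``transform='log1p'`` applies log(x+1) before testing (used for
    total density and evenness).  Class statistics are reported on the
    transformed scale.  Every class needs at least 2 observations.
    """
    y = np.asarray(values, dtype=float)
    labels = np.asarray(classes)
    if transform == "log1p":
        if (y < 0).any():
            raise ValidationError("log1p transform requires non-negative values")
        y = np.log1p(y)
    elif transform is not None:
        raise ValidationError(f"unknown transform {transform!r}")

    class_rank = {lab: i for i, lab in enumerate(YEAR_CLASS_LABELS.values())}
    levels = sorted(pd.unique(labels), key=lambda lv: (class_rank.get(lv, len(class_rank)), str(lv)))
    groups = [y[labels == lv] for lv in levels]
    if len(levels) < 2:
        raise ValidationError("ANOVA needs at least 2 non-empty classes")
    for lv, grp in zip(levels, groups):
        if len(grp) < 2:
            raise ValidationError(f"class {lv!r} has fewer than 2 observations")

    n = len(y)
    g = len(levels)
    grand = y.mean()
    ss_between = sum(len(grp) * (grp.mean() - grand) ** 2 for grp in groups)
    ss_within = sum(((grp - grp.mean()) ** 2).sum() for grp in groups)
    df_b, df_w = g - 1, n - g
    mse = ss_within / df_w
    if ss_between <= 0:
        f = 0.0
    elif mse > 0:
        f = (ss_between / df_b) / mse
    else:
        f = np.inf
    p = float(stats.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0

    resid = np.concatenate([grp - grp.mean() for grp in groups])
    shapiro_p = float(stats.shapiro(resid).pvalue) if np.ptp(resid) > 0 else 1.0
    levene_p = (
        float(stats.levene(*groups, center="median").pvalue)
        if all(np.ptp(grp) > 0 for grp in groups)
        else 1.0
    )

    # pairwise LSD t-tests on the pooled MSE
    lsd = np.ones((g, g))
    for a in range(g):
        for b in range(a + 1, g):
            if mse > 0:
                se = np.sqrt(mse * (1 / len(groups[a]) + 1 / len(groups[b])))
                t = (groups[a].mean() - groups[b].mean()) / se
                pv = 2 * float(stats.t.sf(abs(t), df_w))
            else:
                pv = 0.0 if groups[a].mean() != groups[b].mean() else 1.0
            lsd[a, b] = lsd[b, a] = pv
    means = [grp.mean() for grp in groups]
    letters = compact_letters(levels, means, lsd < alpha)

    class_stats = pd.DataFrame(
        {
            "n": [len(grp) for grp in groups],
            "mean": means,
            "sd": [grp.std(ddof=1) for grp in groups],
            "letters": [letters[lv] for lv in levels],
        },
        index=pd.Index(levels, name="class"),
    )
    return TrendResult(
        response=response,
        transform=transform,
        class_stats=class_stats,
        F=float(f),
        df=(df_b, df_w),
        p_value=p,
        levene_p=levene_p,
        shapiro_p=shapiro_p,
        lsd_p=pd.DataFrame(lsd, index=levels, columns=levels),
        letters=letters,
        alpha=alpha,
    )


#: responses log(x+1)-transformed before the year-class ANOVA
LOG1P_RESPONSES = ("total_density", "evenness_E")


def year_trends(
    profile: pd.DataFrame,
    practices,
    responses: Sequence[str] = ("total_density", "H_prime", "lambda_simpson", "evenness_E", "dominance_C"),
    by_mode: bool = False,
    alpha: float = 0.05,
) -> list[TrendResult]:
    """Year-class trend tests over a per-quadrat diversity profile.

    Quadrats are the observational units; each inherits the year class
    of its site.  With ``by_mode`` the tests run separately per
    production mode (one result per mode × response).
    """
    years = {p.site_id: p.consecutive_years for p in practices}
    df = profile.copy()
    df["year_class"] = df["site"].map(lambda s: YEAR_CLASS_LABELS[year_class(years[s])])
    results = []
    blocks = df.groupby("mode") if by_mode else [("all", df)]
    for mode, block in blocks:
        for resp in responses:
            vals = block[resp].to_numpy()
            ok = np.isfinite(vals)
            res = anova_lsd(
                vals[ok],
                block["year_class"].to_numpy()[ok],
                alpha=alpha,
                transform="log1p" if resp in LOG1P_RESPONSES else None,
                response=f"{mode}:{resp}" if by_mode else resp,
            )
            results.append(res)
    return results
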