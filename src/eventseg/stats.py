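"""Inferential layer: nonparametric group comparisons and videos-as-cases ANOVAs.

Participant-level metrics are compared nonparametrically (Mann-Whitney U
between groups, Wilcoxon signed-rank within participants).  Within-group
boundary agreement (n-bound) is compared treating single videos as cases:
both groups score every video, so the group factor is within-video and the
one-way repeated-measures F is the squared paired t on per-video
differences.  Style and difficulty effects on per-video n-bound, TBR and
ROO are assessed per group with per-outcome between-cases F tests plus a
Pillai multivariate omnibus.

No multiple-testing correction is applied; result collections carry the
number of tests run so readers can adjust.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class StatResult:
    """One test result: statistic, p, effect size, sample size, factors."""

    test: str
    statistic: float
    p: float
    effect_size: float | None = None
    effect_size_name: str | None = None
    n: int = 0
    df: tuple | None = None
    factors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (math.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError(f"p out of range: {self.p}")

    def as_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "p": self.p,
            "effect_size": self.effect_size,
            "effect_size_name": self.effect_size_name,
            "n": self.n,
            "df": list(self.df) if self.df is not None else None,
            **({"factors": self.factors} if self.factors else {}),
        }


def mann_whitney(x: Sequence[float], y: Sequence[float], **factors) -> StatResult:
    """Two-sided Mann-Whitney U with rank-biserial effect size."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("mann_whitney requires >= 2 observations per level")
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    rank_biserial = 2.0 * res.statistic / (len(x) * len(y)) - 1.0
    return StatResult(
        test="mann_whitney_u",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        effect_size=float(rank_biserial),
        effect_size_name="rank_biserial",
        n=len(x) + len(y),
        factors=factors,
    )


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float], **factors) -> StatResult:
    """Paired two-sided Wilcoxon signed-rank (Pratt zero handling).

    Identical samples (all differences zero) are reported as statistic 0,
    p = 1: no evidence of a shift.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if len(x) < 2:
        raise ValueError("wilcoxon requires >= 2 pairs")
    d = x - y
    if np.all(d == 0):
        return StatResult(
            test="wilcoxon_signed_rank", statistic=0.0, p=1.0,
            effect_size=0.0, effect_size_name="rank_biserial",
            n=len(x), factors=factors,
        )
    res = sps.wilcoxon(x, y, zero_method="pratt", alternative="two-sided")
    # matched-pairs rank-biserial from signed ranks (zeros excluded)
    nz = d[d != 0]
    ranks = sps.rankdata(np.abs(d))[d != 0]
    r_plus = float(ranks[nz > 0].sum())
    r_minus = float(ranks[nz < 0].sum())
    total = r_plus + r_minus
    rank_biserial = (r_plus - r_minus) / total if total > 0 else 0.0
    return StatResult(
        test="wilcoxon_signed_rank",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        effect_size=float(rank_biserial),
        effect_size_name="rank_biserial",
        n=len(x),
        factors=factors,
    )


def videos_as_cases_anova(
    expert: Sequence[float], control: Sequence[float], **factors
) -> StatResult:
    """One-way repeated-measures ANOVA on per-video scores, group within video.

    With two levels this F equals the squared paired t on the per-video
    differences; reported with df (1, V-1) and partial eta squared
    F / (F + V - 1).  Degenerate inputs: zero differences give F = 0, p = 1;
    a constant nonzero difference gives F = inf, p = 0.
    """
    e = np.asarray(expert, dtype=float)
    c = np.asarray(control, dtype=float)
    if e.shape != c.shape or len(e) < 2:
        raise ValueError("both groups must score the same >= 2 videos")
    v = len(e)
    d = e - c
    if np.allclose(np.var(d, ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            f, p = 0.0, 1.0
        else:
            f, p = math.inf, 0.0
    else:
        t, p = sps.ttest_rel(e, c)
        f = float(t) ** 2
        p = float(p)
    eta_p2 = 1.0 if math.isinf(f) else f / (f + (v - 1))
    return StatResult(
        test="videos_as_cases_rm_anova",
        statistic=f,
        p=p,
        effect_size=eta_p2,
        effect_size_name="partial_eta_squared",
        n=v,
        df=(1, v - 1),
        factors=factors,
    )


def _oneway_between(values: np.ndarray, labels: np.ndarray, **factors) -> StatResult:
    levels = np.unique(labels)
    if len(levels) != 2:
        raise ValueError("factor must have exactly two levels")
    groups = [values[labels == lv] for lv in levels]
    if min(len(g) for g in groups) < 2:
        raise ValueError("need >= 2 cases per factor level")
    n = len(values)
    dfh, dfe = len(levels) - 1, n - len(levels)
    grand = values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_within <= 0:
        f = 0.0 if ss_between <= 0 else math.inf
        p = 1.0 if f == 0.0 else 0.0
    else:
        f = (ss_between / dfh) / (ss_within / dfe)
        p = float(sps.f.sf(f, dfh, dfe))
    eta_p2 = 1.0 if math.isinf(f) else ss_between / (ss_between + ss_within) if (ss_between + ss_within) > 0 else 0.0
    return StatResult(
        test="oneway_between_anova",
        statistic=float(f),
        p=p,
        effect_size=float(eta_p2),
        effect_size_name="partial_eta_squared",
        n=n,
        df=(dfh, dfe),
        factors=factors,
    )


def style_difficulty_manova(
    table: pd.DataFrame,
    factor: str,
    outcomes: Sequence[str] = ("n_bound", "tbr_s", "roo_pct"),
    **factors,
) -> dict:
    """Per-video multivariate ANOVA of ``factor`` (style or difficulty) on the
    outcome set, videos as cases.

    Returns a dict with one univariate :class:`StatResult` per outcome and,
    when estimable, a Pillai-trace omnibus under key ``"multivariate"``.
    Neither gates the other.
    """
    if factor not in table.columns:
        raise ValueError(f"factor column {factor!r} not in table")
    labels = table[factor].to_numpy()
    counts = pd.Series(labels).value_counts()
    if len(counts) == 2 and counts.nunique() > 1:
        import warnings

        warnings.warn(f"unbalanced levels for factor {factor!r}: {counts.to_dict()}")
    results: dict = {}
    for outcome in outcomes:
        values = table[outcome].to_numpy(dtype=float)
        results[outcome] = _oneway_between(values, labels, factor=factor, outcome=outcome, **factors)
    results["multivariate"] = _pillai_omnibus(table, factor, outcomes, **factors)
    results["n_tests"] = len(outcomes)
    return results


def _pillai_omnibus(table, factor, outcomes, **factors) -> StatResult | None:
    try:
        import warnings

        from statsmodels.multivariate.manova import MANOVA

        clean = table[[factor, *outcomes]].rename(
            columns={c: c.replace(".", "_") for c in outcomes}
        )
        dep = " + ".join(c.replace(".", "_") for c in outcomes)
        mv = MANOVA.from_formula(f"{dep} ~ C({factor})", data=clean)
        with warnings.catch_warnings():
            # near-singular outcome covariance on few cases emits benign
            # divide warnings before we validate the Pillai row
            warnings.simplefilter("ignore", RuntimeWarning)
            frame = mv.mv_test().results[f"C({factor})"]["stat"]
        row = frame.loc["Pillai's trace"]
        return StatResult(
            test="manova_pillai",
            statistic=float(row["F Value"]),
            p=min(max(float(row["Pr > F"]), 0.0), 1.0),
            effect_size=float(row["Value"]),
            effect_size_name="pillai_trace",
            n=len(table),
            df=(float(row["Num DF"]), float(row["Den DF"])),
            factors={"factor": factor, **factors},
        )
    except Exception:
        # singular outcome covariance (e.g. a constant outcome) — omnibus
        # not estimable; univariate results stand on their own
        return None


def compare_participants(
    summary: pd.DataFrame,
    metric: str,
    factor: str,
    *,
    group: str | None = None,
) -> StatResult:
    """Dispatch the participant-level comparison for ``metric``.

    ``factor="group"`` runs Mann-Whitney U expert vs control on
    per-participant values (column ``metric``).  ``factor`` in
    ``{"style", "block"}`` runs a paired Wilcoxon on the per-participant
    level means, expecting columns ``{metric}_{level}`` (e.g.
    ``tbr_s_ITF`` / ``tbr_s_WT``); optionally restricted to one group.
    """
    t = summary if group is None else summary[summary["group"] == group]
    if factor == "group":
        x = t.loc[t["group"] == "expert", metric].dropna()
        y = t.loc[t["group"] == "control", metric].dropna()
        return mann_whitney(x, y, metric=metric, factor="group", group=group or "all")
    if factor == "style":
        levels = ("ITF", "WT")
    elif factor == "block":
        levels = ("b1", "b2")
    else:
        raise ValueError(f"unknown factor {factor!r}")
    cols = [f"{metric}_{lv}" for lv in levels]
    paired = t[cols].dropna()
    if len(paired) < 2:
        raise ValueError(
            f"insufficient participants with both levels for metric={metric}, "
            f"factor={factor}, group={group}"
        )
    return wilcoxon_signed_rank(
        paired[cols[0]], paired[cols[1]],
        metric=metric, factor=factor, group=group or "all",
    )
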