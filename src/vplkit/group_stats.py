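"""Group-level frequentist statistics for the learning study: percent
improvement, one-way ANOVA (raw data or published summary statistics),
two-way mixed (split-plot) ANOVA with eta-squared, Fisher's LSD post hoc
comparisons and the Pearson chi-square homogeneity test.

The summary-statistics one-way ANOVA exists so that published demographic
tables (group means, SDs and ns) can be re-analysed without the raw data;
the raw-data form is algebraically identical to it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "percent_improvement",
    "oneway_anova_summary",
    "oneway_anova",
    "mixed_anova",
    "lsd_posthoc",
    "chi_square_homogeneity",
]


@dataclass(frozen=True)
class GroupSummary:
    """Published per-group summary: mean, sample SD and n."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass(frozen=True)
class AnovaResult:
    """One tested effect: F, degrees of freedom, p and eta-squared."""

    effect: str
    f_stat: float
    df_num: int
    df_den: int
    p: float
    eta_sq: float


def percent_improvement(pre: float, post: float) -> float:
    """Percent threshold improvement, (pre - post) / pre * 100.

    Negative when performance worsened.
    """
    if pre <= 0:
        raise ValueError("pre-test threshold must be positive")
    return (pre - post) / pre * 100.0


def oneway_anova_summary(groups: Sequence[GroupSummary]) -> AnovaResult:
    """One-way between-groups ANOVA from group means, SDs and ns.

    SS_between is computed from the group means about the grand (weighted)
    mean; SS_within is the pooled sum of (n_i - 1) * sd_i**2.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    means = np.array([g.mean for g in groups], dtype=float)
    sds = np.array([g.sd for g in groups], dtype=float)
    ns = np.array([g.n for g in groups], dtype=float)
    grand = float(np.sum(ns * means) / np.sum(ns))
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(np.sum((ns - 1) * sds**2))
    df_between = len(groups) - 1
    df_within = int(np.sum(ns)) - len(groups)
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        raise ValueError("degenerate within-group variance (all SDs zero)")
    f_stat = (ss_between / df_between) / ms_within
    p = float(stats.f.sf(f_stat, df_between, df_within))
    eta_sq = ss_between / (ss_between + ss_within)
    return AnovaResult("group", f_stat, df_between, df_within, p, eta_sq)


def oneway_anova(samples: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way between-groups ANOVA from raw per-group values.

    Identical to :func:`oneway_anova_summary` applied to the computed group
    means and SDs.
    """
    groups = [
        GroupSummary(
            label=str(label),
            mean=float(np.mean(v)),
            sd=float(np.std(v, ddof=1)),
            n=len(v),
        )
        for label, v in samples.items()
    ]
    return oneway_anova_summary(groups)


def mixed_anova(
    pre: Sequence[float],
    post: Sequence[float],
    group: Sequence[str],
    *,
    partial: bool = False,
) -> list[AnovaResult]:
    """Two-way mixed (split-plot) ANOVA: one between factor, two within levels.

    ``pre``/``post`` hold each observer's value at the two within-subject
    levels (e.g. pretest and posttest thresholds); ``group`` is the
    between-subject factor. Every observer must be complete. Returns the
    between-groups main effect, the within (test) main effect and the
    group-by-test interaction. The between effect is tested against
    subjects-within-groups; the within effects against the subject-by-test
    residual. Balanced designs give df (G-1, G(n-1)) / (1, G(n-1)) /
    (G-1, G(n-1)).

    ``eta_sq`` is classical (SS_effect / SS_total); set ``partial=True`` for
    partial eta-squared (SS_effect / (SS_effect + SS_error)).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    group = np.asarray(group)
    if pre.shape != post.shape or pre.shape != group.shape:
        raise ValueError("pre, post and group must have equal length")
    if np.any(np.isnan(pre)) or np.any(np.isnan(post)):
        raise ValueError("incomplete observers (NaN values); no imputation is done")
    labels = pd.unique(group)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")

    x = np.stack([pre, post], axis=1)  # subjects x 2
    grand = x.mean()
    subj_means = x.mean(axis=1)
    level_means = x.mean(axis=0)
    n_subj = len(pre)

    ss_total = float(((x - grand) ** 2).sum())
    ss_between_subj = float(2.0 * ((subj_means - grand) ** 2).sum())

    ss_group = 0.0
    df_subj_wg = 0
    cell_dev_sq = 0.0
    for lab in labels:
        m = group == lab
        n_g = int(m.sum())
        if n_g < 2:
            raise ValueError(f"group {lab!r} needs at least 2 observers")
        g_mean = x[m].mean()
        ss_group += 2.0 * n_g * (g_mean - grand) ** 2
        df_subj_wg += n_g - 1
        for j in range(2):
            cell = x[m, j].mean()
            cell_dev_sq += n_g * (cell - g_mean - level_means[j] + grand) ** 2
    ss_subj_wg = ss_between_subj - ss_group

    ss_within_total = float(((x - subj_means[:, None]) ** 2).sum())
    ss_test = float(n_subj * ((level_means - grand) ** 2).sum())
    ss_interaction = float(cell_dev_sq)
    ss_error_within = ss_within_total - ss_test - ss_interaction

    df_group = len(labels) - 1
    df_test = 1
    df_error = df_subj_wg  # subject x test residual has the same df

    tiny = 1e-12 * max(ss_total, 1.0)

    def build(effect: str, ss: float, df_num: int, ss_err: float, df_den: int):
        ms_err = ss_err / df_den
        if ms_err <= tiny:
            if ss <= tiny:  # no effect and no error variance: F defined as 0
                return AnovaResult(effect, 0.0, df_num, df_den, 1.0, 0.0)
            raise ValueError(f"degenerate error variance for effect {effect!r}")
        f_stat = (ss / df_num) / ms_err
        p = float(stats.f.sf(f_stat, df_num, df_den))
        denom = (ss + ss_err) if partial else ss_total
        eta = ss / denom if denom > tiny else 0.0
        return AnovaResult(effect, f_stat, df_num, df_den, p, eta)

    return [
        build("group", ss_group, df_group, ss_subj_wg, df_subj_wg),
        build("test", ss_test, df_test, ss_error_within, df_error),
        build("group:test", ss_interaction, df_group * df_test, ss_error_within, df_error),
    ]


def lsd_posthoc(
    samples: Mapping[str, Sequence[float]],
    error_ms: float | None = None,
    error_df: int | None = None,
) -> pd.DataFrame:
    """Fisher's least-significant-difference pairwise comparisons.

    Each pair is tested with t = (m_i - m_j) / sqrt(MSE * (1/n_i + 1/n_j))
    using the pooled ANOVA error mean square (computed from the samples
    unless supplied) and unadjusted two-sided p values.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if error_ms is None or error_df is None:
        values = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
        ss_within = sum(((v - v.mean()) ** 2).sum() for v in values.values())
        error_df = sum(len(v) - 1 for v in values.values())
        error_ms = float(ss_within / error_df)
    if error_ms <= 0:
        raise ValueError("degenerate (zero) error variance")
    rows = []
    for (a, va), (b, vb) in itertools.combinations(samples.items(), 2):
        va, vb = np.asarray(va, dtype=float), np.asarray(vb, dtype=float)
        diff = va.mean() - vb.mean()
        se = np.sqrt(error_ms * (1.0 / len(va) + 1.0 / len(vb)))
        t = diff / se
        p = float(2.0 * stats.t.sf(abs(t), error_df))
        rows.append(
            {"group_a": a, "group_b": b, "mean_diff": diff, "t": t,
             "df": error_df, "p": p}
        )
    return pd.DataFrame(rows)


def chi_square_homogeneity(table: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Pearson chi-square test of homogeneity on an r x c count table.

    No continuity correction; expected counts come from the row/column
    marginals; df = (r - 1)(c - 1).
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need a 2-D table with at least 2 rows and 2 columns")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("degenerate table: zero row or column marginal")
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(chi2), int(df), float(p)
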