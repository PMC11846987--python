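"""Cohort-level statistics for genre comparisons.

The analysis ladder applied to each kinematic metric across genre groups:
Shapiro–Wilk and Levene assumption checks, natural-log transform with a
simple percentile bootstrap of the transformed group means (B = 1000, 95%
by default), one-way ANOVA with η² effect size, and Fisher's LSD pairwise
follow-ups (unadjusted t tests on the pooled within-group mean square).
Cursor-sensitivity (DPI) choice is compared with Pearson chi-square
contingency analysis, with Šidák-corrected pairwise 2×2 follow-ups, and the
ellipse long:short ratio is tested against 1 (a circle) with one-sample
t tests per genre.

η² = SS_between / SS_total; from a printed ANOVA summary it is recovered as
df1·F / (df1·F + df2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as spstats

from .errors import ConfigurationError, DegenerateInputError


@dataclass
class GroupComparison:
    """One-way ANOVA summary for one metric, with LSD follow-ups."""

    variable: str
    F: float
    df1: int
    df2: int
    p: float
    eta2: float
    posthoc: list[tuple[str, float]] = field(default_factory=list)


@dataclass
class ContingencyResult:
    """Omnibus chi-square plus Šidák-gated pairwise follow-ups."""

    chi2: float
    df: int
    p: float
    pairwise: list[tuple[str, float, bool]] = field(default_factory=list)
    sidak_alpha: float = 0.05


@dataclass
class OneSampleResult:
    """One-sample t test of a group mean against a reference value."""

    t: float
    df: int
    p: float
    mu0: float = 1.0


def check_assumptions(groups: Sequence[Sequence[float]]) -> dict:
    """Shapiro–Wilk normality per group and Levene homogeneity across groups.

    Returns ``{"normality_p": [...], "homogeneity_p": float}``; no decision
    is taken here.  Zero-spread inputs (Levene statistic undefined) report a
    homogeneity p of 1.0 rather than erroring.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size < 3:
            raise DegenerateInputError(
                f"group {i} has n={g.size} < 3; assumption checks need n >= 3")
    normality = [float(spstats.shapiro(g).pvalue) if np.ptp(g) > 0 else 1.0
                 for g in arrays]
    with np.errstate(invalid="ignore", divide="ignore"):
        lev = spstats.levene(*arrays)
    hom_p = float(lev.pvalue)
    if not np.isfinite(hom_p):
        hom_p = 1.0
    return {"normality_p": normality, "homogeneity_p": hom_p}


def log_bootstrap(
    values: Sequence[float],
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Natural-log transform plus a percentile bootstrap CI of the log-mean.

    ``B`` simple resamples with replacement; deterministic given ``seed``.
    """
    x = np.asarray(values, dtype=float)
    bad = np.flatnonzero(x <= 0)
    if bad.size:
        raise DegenerateInputError(
            f"log transform of a non-positive value at index {int(bad[0])}")
    if B < 1:
        raise ConfigurationError("B must be >= 1")
    logx = np.log(x)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(B, x.size))
    means = logx[idx].mean(axis=1)
    lo, hi = np.percentile(means, [(1 - level) / 2 * 100,
                                   (1 + level) / 2 * 100])
    return logx, (float(lo), float(hi))


def _ss_decomposition(arrays: list[np.ndarray]) -> tuple[float, float]:
    """(SS_between, SS_within) of a one-way layout."""
    allx = np.concatenate(arrays)
    grand = allx.mean()
    ss_b = sum(g.size * (g.mean() - grand) ** 2 for g in arrays)
    ss_w = sum(float(np.sum((g - g.mean()) ** 2)) for g in arrays)
    return float(ss_b), float(ss_w)


def one_way_anova(groups: Sequence[Sequence[float]], variable: str = ""
                  ) -> GroupComparison:
    """One-way between-groups ANOVA with η² = SS_between / SS_total.

    An all-identical input is a legitimate degenerate case and returns
    F = 0, η² = 0, p = 1 rather than an error.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(g.size < 2 for g in arrays):
        raise DegenerateInputError("ANOVA needs >= 2 groups of n >= 2 each")
    k = len(arrays)
    n_total = sum(g.size for g in arrays)
    df1, df2 = k - 1, n_total - k
    ss_b, ss_w = _ss_decomposition(arrays)
    ss_t = ss_b + ss_w
    if ss_t <= 0:
        return GroupComparison(variable, F=0.0, df1=df1, df2=df2, p=1.0,
                               eta2=0.0)
    if ss_w <= 0:  # perfect separation
        return GroupComparison(variable, F=np.inf, df1=df1, df2=df2, p=0.0,
                               eta2=1.0)
    F = (ss_b / df1) / (ss_w / df2)
    p = float(spstats.f.sf(F, df1, df2))
    return GroupComparison(variable, F=float(F), df1=df1, df2=df2, p=p,
                           eta2=ss_b / ss_t)


def lsd_posthoc(
    groups: Sequence[Sequence[float]],
    anova: GroupComparison,
    labels: Sequence[str] | None = None,
) -> list[tuple[str, float]]:
    """Fisher's LSD: unadjusted pairwise t tests on the pooled MS_within.

    Each pair uses t = (m_i − m_j) / √(MSW·(1/n_i + 1/n_j)) with the ANOVA's
    within-group degrees of freedom; by definition no multiplicity
    correction is applied.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    labels = list(labels) if labels is not None else [
        f"g{i}" for i in range(len(arrays))]
    _, ss_w = _ss_decomposition(arrays)
    msw = ss_w / anova.df2
    out: list[tuple[str, float]] = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            gi, gj = arrays[i], arrays[j]
            diff = gi.mean() - gj.mean()
            if msw <= 0:
                p = 1.0 if diff == 0 else 0.0
            else:
                se = np.sqrt(msw * (1 / gi.size + 1 / gj.size))
                t = diff / se
                p = float(2 * spstats.t.sf(abs(t), anova.df2))
            out.append((f"{labels[i]} x {labels[j]}", p))
    return out


def eta_squared_from_summary(F: float, df1: int, df2: int) -> float:
    """Recover η² from a printed one-way ANOVA summary (F, df1, df2)."""
    if F < 0 or df1 < 1 or df2 < 1:
        raise ValueError("need F >= 0 and positive degrees of freedom")
    return df1 * F / (df1 * F + df2)


def one_sample_t(values: Sequence[float], mu0: float = 1.0) -> OneSampleResult:
    """Two-sided one-sample t test of the mean against ``mu0``."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegenerateInputError("one-sample t needs n >= 2")
    if np.ptp(x) == 0:
        raise DegenerateInputError("one-sample t with zero variance")
    res = spstats.ttest_1samp(x, popmean=mu0)
    return OneSampleResult(t=float(res.statistic), df=x.size - 1,
                           p=float(res.pvalue), mu0=mu0)


def chi_square_contingency(table: np.ndarray) -> ContingencyResult:
    """Pearson chi-square on a contingency table (no continuity correction)."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise DegenerateInputError("contingency table has a zero marginal")
    chi2, p, dof, _ = spstats.chi2_contingency(obs, correction=False)
    return ContingencyResult(chi2=float(chi2), df=int(dof), p=float(p))


def sidak_threshold(m: int, alpha: float = 0.05) -> float:
    """Šidák per-comparison threshold 1 − (1 − α)^(1/m) for m comparisons."""
    if m < 1 or not (0.0 < alpha < 1.0):
        raise ValueError("need m >= 1 and 0 < alpha < 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def dpi_contingency_analysis(
    genres: Sequence[str],
    dpis: Sequence[int],
    genre_labels: Sequence[str],
    dpi_levels: Sequence[int] = (400, 1000, 1600),
    alpha: float = 0.05,
) -> ContingencyResult:
    """Genre × DPI contingency analysis with Šidák-corrected follow-ups.

    The omnibus test uses the full genre × DPI count table.  Follow-ups are
    2×2 tables (genre pair × chose-this-DPI vs not) for every genre pair at
    every DPI level — 9 comparisons for 3 genres and 3 levels — each flagged
    significant when its p-value falls below the Šidák threshold.
    """
    genres = list(genres)
    dpis = list(dpis)
    table = np.array([
        [sum(1 for g, d in zip(genres, dpis) if g == gl and d == dl)
         for dl in dpi_levels]
        for gl in genre_labels
    ])
    # a level nobody chose carries no information for the omnibus test
    omnibus = table[:, table.sum(axis=0) > 0]
    omnibus = omnibus[omnibus.sum(axis=1) > 0, :]
    if omnibus.shape[0] >= 2 and omnibus.shape[1] >= 2:
        result = chi_square_contingency(omnibus)
    else:
        result = ContingencyResult(chi2=0.0, df=0, p=1.0)

    m = len(dpi_levels) * (len(genre_labels) * (len(genre_labels) - 1)) // 2
    thr = sidak_threshold(m, alpha)
    pairwise: list[tuple[str, float, bool]] = []
    for kd, dl in enumerate(dpi_levels):
        for i in range(len(genre_labels)):
            for j in range(i + 1, len(genre_labels)):
                sub = np.array([
                    [table[i, kd], table[i].sum() - table[i, kd]],
                    [table[j, kd], table[j].sum() - table[j, kd]],
                ])
                label = f"{genre_labels[i]} x {genre_labels[j]} @ {dl} DPI"
                try:
                    p = chi_square_contingency(sub).p
                except DegenerateInputError:
                    p = 1.0  # nobody (or everybody) chose this level
                pairwise.append((label, p, p <= thr))
    result.pairwise = pairwise
    result.sidak_alpha = thr
    return result
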