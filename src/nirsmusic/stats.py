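"""Group-level inference for connectivity outcomes.

Implements the tests used on left-right correlations and edge-count curves
from their standard formulas, so exact/approximate branches and tie handling
are explicit and testable:

* Kruskal-Wallis rank test with tie correction, p from chi-square(g - 1).
* Wilcoxon signed-rank test: exact signed-rank null distribution (dynamic
  programming over rank sums) for n <= 25, normal approximation with
  continuity and tie corrections otherwise.  The reported statistic is
  W = min(W+, W-).
* Split-plot (one within, optionally one between factor) repeated-measures
  ANOVA with the threshold levels as the repeated factor, Mauchly's
  sphericity test on the orthonormal-contrast covariance, Greenhouse-Geisser
  epsilon applied to the within-factor degrees of freedom when sphericity is
  rejected (or unconditionally when the covariance cannot support the test),
  and Bonferroni-adjusted pairwise post hoc comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sstats

__all__ = [
    "StatResult",
    "kruskal_wallis",
    "wilcoxon_signed_rank",
    "rm_anova",
    "bonferroni",
    "gg_epsilon",
    "mauchly_test",
]


@dataclass
class StatResult:
    test_name: str
    statistic: float
    df: float | tuple[float, float]
    p: float
    correction: str = "none"
    epsilon: float | None = None
    extra: dict = field(default_factory=dict)

    def __repr__(self) -> str:  # compact, summary-friendly
        df = (f"({self.df[0]:.3g}, {self.df[1]:.3g})"
              if isinstance(self.df, tuple) else f"{self.df:.3g}")
        s = f"{self.test_name}: stat={self.statistic:.4g}, df={df}, p={self.p:.4g}"
        if self.correction != "none":
            s += f" [{self.correction}]"
        return s


def kruskal_wallis(*groups: Sequence[float]) -> StatResult:
    """Kruskal-Wallis H with tie correction; p from chi-square(g - 1)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    gs = [np.asarray(g, float).ravel() for g in groups]
    if any(len(g) < 3 for g in gs):
        raise ValueError("each group needs at least 3 values")
    pooled = np.concatenate(gs)
    n_total = len(pooled)
    if np.ptp(pooled) == 0:
        return StatResult("kruskal_wallis", 0.0, len(gs) - 1, 1.0)
    ranks = sstats.rankdata(pooled)
    h = 0.0
    start = 0
    for g in gs:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts ** 3 - counts) / (n_total ** 3 - n_total)
    if tie > 0:
        h /= tie
    df = len(gs) - 1
    p = float(sstats.chi2.sf(h, df))
    return StatResult("kruskal_wallis", float(h), df, p)


def _signed_rank_distribution(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact null pmf of W+ = sum of positive-difference ranks, conditioning
    on the observed (possibly tied, average) ranks.  Rank values are doubled
    so half-integer average ranks become integers."""
    scaled = np.round(2 * ranks).astype(int)
    total = scaled.sum()
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in scaled:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: len(pmf) - r]
        pmf = 0.5 * (pmf + shifted)
    support = np.arange(total + 1) / 2.0
    return support, pmf


def wilcoxon_signed_rank(paired_a: Sequence[float],
                         paired_b: Sequence[float]) -> StatResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; requires >= 5 non-zero pairs.  Exact p for
    n <= 25, else normal approximation with continuity correction.
    """
    a = np.asarray(paired_a, float).ravel()
    b = np.asarray(paired_b, float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return StatResult("wilcoxon_signed_rank", 0.0, 0, 1.0,
                          extra={"note": "all differences zero"})
    if n < 5:
        raise ValueError("need at least 5 non-zero differences")
    ranks = sstats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n <= 25:
        support, pmf = _signed_rank_distribution(ranks)
        lo = float(pmf[support <= w + 1e-9].sum())
        hi = float(pmf[support >= w - 1e-9].sum())
        p = min(1.0, 2.0 * min(lo, hi))
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(np.abs(d), return_counts=True)
        tie_term = np.sum(counts ** 3 - counts) / 48.0
        sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        z = (w - mean + 0.5) / sd
        p = float(min(1.0, 2.0 * sstats.norm.cdf(z)))
        method = "normal"
    return StatResult("wilcoxon_signed_rank", w, n, p,
                      extra={"method": method, "w_plus": w_plus, "w_minus": w_minus})


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni adjustment: p_adj = min(1, p * m)."""
    ps = list(p_values)
    m = len(ps)
    if any(not 0 <= p <= 1 for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    return [min(1.0, p * m) for p in ps]


def _orthonormal_contrasts(p: int) -> np.ndarray:
    """(p-1) x p orthonormal contrast matrix (rows orthogonal to the mean)."""
    basis = np.eye(p) - 1.0 / p
    q, _ = np.linalg.qr(basis.T)
    return q[:, : p - 1].T


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a levels x levels covariance matrix."""
    cov = np.asarray(cov, float)
    p = cov.shape[0]
    c = _orthonormal_contrasts(p)
    sd = c @ cov @ c.T
    lam = np.linalg.eigvalsh(sd)
    lam = np.clip(lam, 0.0, None)
    denom = (p - 1) * float(np.sum(lam ** 2))
    if denom <= 0:
        return 1.0 / (p - 1)
    eps = float(np.sum(lam)) ** 2 / denom
    return float(np.clip(eps, 1.0 / (p - 1), 1.0))


def mauchly_test(cov: np.ndarray, n_error: int) -> StatResult:
    """Mauchly's sphericity test on the contrast covariance.

    ``n_error`` is the error df the covariance was estimated with
    (N - g for g groups).
    """
    cov = np.asarray(cov, float)
    p = cov.shape[0]
    k = p - 1
    c = _orthonormal_contrasts(p)
    sd = c @ cov @ c.T
    lam = np.linalg.eigvalsh(sd)
    if np.any(lam <= 0) or n_error <= k:
        return StatResult("mauchly", np.nan, k * (k + 1) // 2 - 1, np.nan,
                          extra={"singular": True})
    w = float(np.prod(lam) / (np.mean(lam) ** k))
    f = 1.0 - (2.0 * k ** 2 + k + 2.0) / (6.0 * k * n_error)
    chi2 = -f * n_error * np.log(w)
    df = k * (k + 1) // 2 - 1
    p_val = float(sstats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return StatResult("mauchly", w, df, p_val, extra={"chi2": float(chi2)})


def _as_groups(counts, group_labels) -> dict[str, np.ndarray]:
    if isinstance(counts, Mapping):
        return {str(k): np.atleast_2d(np.asarray(v, float)) for k, v in counts.items()}
    arr = np.atleast_2d(np.asarray(counts, float))
    if group_labels is None:
        return {"all": arr}
    labels = np.asarray(group_labels)
    return {str(lbl): arr[labels == lbl] for lbl in np.unique(labels)}


def rm_anova(counts, group_labels=None, alpha: float = 0.05,
             force_gg: bool = False) -> list[StatResult]:
    """Split-plot repeated-measures ANOVA on subject x level matrices.

    Parameters
    ----------
    counts : dict group -> (subjects x levels) matrix, or a single matrix
        with ``group_labels`` giving each row's group.
    alpha : level used to trigger the GG correction and post hoc tests.
    force_gg : apply the Greenhouse-Geisser correction regardless of
        Mauchly's test.

    Returns StatResults for the between-group factor (if >= 2 groups), the
    within-subject (level) factor, the interaction, Mauchly's test, and any
    Bonferroni post hoc comparisons (in ``extra['comparison']``).
    """
    groups = _as_groups(counts, group_labels)
    g = len(groups)
    mats = list(groups.values())
    p = mats[0].shape[1]
    if any(m.shape[1] != p for m in mats):
        raise ValueError("all groups must share the level count")
    if any(m.shape[0] < 2 for m in mats):
        raise ValueError("need at least 2 subjects per group")
    if any(np.isnan(m).any() for m in mats):
        raise ValueError("matrices must be complete (no missing cells)")
    data = np.vstack(mats)
    n_total = data.shape[0]
    grand = data.mean()

    subj_means = data.mean(axis=1)
    group_sizes = [m.shape[0] for m in mats]
    group_means = [m.mean() for m in mats]

    ss_group = p * sum(n_i * (gm - grand) ** 2
                       for n_i, gm in zip(group_sizes, group_means))
    ss_subj_within = p * sum(
        ((m.mean(axis=1) - m.mean()) ** 2).sum() for m in mats)
    level_means = data.mean(axis=0)
    ss_level = n_total * np.sum((level_means - grand) ** 2)
    ss_inter = 0.0
    for m, gm in zip(mats, group_means):
        cell = m.mean(axis=0)
        ss_inter += m.shape[0] * np.sum((cell - level_means - gm + grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_error = ss_total - ss_group - ss_subj_within - ss_level - ss_inter

    df_group = g - 1
    df_subj = n_total - g
    df_level = p - 1
    df_inter = df_group * df_level
    df_error = df_subj * df_level

    def _f(ss_num, df_num, ss_den, df_den, name, corr="none", eps=None):
        if df_num <= 0:
            return None
        ms_num = ss_num / df_num
        ms_den = ss_den / df_den if df_den > 0 else np.nan
        if not np.isfinite(ms_den) or ms_den <= 0:
            # degenerate (e.g. identical flat rows): no variance anywhere
            fval = 0.0 if ss_num <= 1e-12 else np.inf
            return StatResult(name, fval, (df_num, df_den),
                              1.0 if fval == 0.0 else 0.0, correction=corr,
                              epsilon=eps)
        fval = ms_num / ms_den
        d1, d2 = df_num, df_den
        if eps is not None and corr == "greenhouse_geisser":
            d1, d2 = eps * d1, eps * d2
        return StatResult(name, float(fval), (float(d1), float(d2)),
                          float(sstats.f.sf(fval, d1, d2)), correction=corr,
                          epsilon=eps)

    results: list[StatResult] = []

    # sphericity handling on the pooled within-group level covariance
    pooled = np.zeros((p, p))
    for m in mats:
        if m.shape[0] > 1:
            pooled += (m.shape[0] - 1) * np.cov(m, rowvar=False)
    pooled /= max(df_subj, 1)
    mau = mauchly_test(pooled, df_subj)
    eps = gg_epsilon(pooled)
    use_gg = force_gg or mau.extra.get("singular", False) or (
        np.isfinite(mau.p) and mau.p < alpha)
    corr = "greenhouse_geisser" if use_gg else "none"
    mau.epsilon = eps
    results.append(mau)

    between = None
    if g >= 2:
        between = _f(ss_group, df_group, ss_subj_within, df_subj, "rm_anova_between")
        results.insert(0, between)
    within = _f(ss_level, df_level, ss_error, df_error, "rm_anova_within",
                corr=corr, eps=eps if use_gg else None)
    if within is not None:
        results.insert(1 if between is not None else 0, within)
    if g >= 2:
        inter = _f(ss_inter, df_inter, ss_error, df_error, "rm_anova_interaction",
                   corr=corr, eps=eps if use_gg else None)
        if inter is not None:
            results.append(inter)

    # Bonferroni post hoc on subject means, pairwise between groups
    if between is not None and between.p < alpha and g >= 2:
        names = list(groups)
        raw = []
        labels = []
        start = 0
        means_by_group = []
        for m in mats:
            means_by_group.append(m.mean(axis=1))
        for i in range(g):
            for j in range(i + 1, g):
                t, pv = sstats.ttest_ind(means_by_group[i], means_by_group[j])
                raw.append(float(pv))
                labels.append((names[i], names[j], float(t)))
        adj = bonferroni(raw)
        for (a, b, t), pv_raw, pv_adj in zip(labels, raw, adj):
            results.append(StatResult("posthoc_t", t,
                                      len(means_by_group[0]) + len(means_by_group[1]) - 2,
                                      pv_adj, correction="bonferroni",
                                      extra={"comparison": (a, b), "p_raw": pv_raw}))
    return results
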