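"""Frequentist group statistics for the connectivity and pupil analyses.

Covers the summary-statistics level of the analysis: one- and two-sample
t-tests with Benjamini-Hochberg FDR correction applied *within each
parameter class* (endogenous, per-input modulatory, driving), split-plot
("mixed") ANOVAs with one between-subject factor (handedness) and one or
two within-subject factors, and the bootstrap lateralization index

    LI = (sum L - sum R) / (sum L + sum R)

summarizing hemispheric dominance of suprathreshold activation (positive =
left-dominant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ParameterClass",
    "LIResult",
    "ttest_and_fdr",
    "mixed_anova_2x2",
    "mixed_anova_3way",
    "bootstrap_li",
]


@dataclass
class ParameterClass:
    label: str
    members: list[int]


def ttest_and_fdr(
    values: np.ndarray,
    classes: list[ParameterClass],
    mode: str = "one-sample",
    values2: np.ndarray | None = None,
    alpha: float = 0.05,
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-parameter t-tests with BH-FDR applied within each class.

    ``values`` is (n_subjects, n_parameters); for ``mode="two-sample"``,
    ``values2`` holds the second group.  Parameters with zero variance are
    flagged and excluded from testing and from the FDR family.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] < 3:
        raise ValueError("need at least 3 subjects per group")
    if mode not in ("one-sample", "two-sample"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "two-sample":
        if values2 is None:
            raise ValueError("two-sample mode needs a second group")
        values2 = np.atleast_2d(np.asarray(values2, dtype=float))
        if values2.shape[0] < 3:
            raise ValueError("need at least 3 subjects per group")

    members = sorted(i for c in classes for i in c.members)
    if len(members) != len(set(members)):
        raise ValueError("parameter classes must not overlap")

    n_params = values.shape[1]
    t = np.full(n_params, np.nan)
    p = np.full(n_params, np.nan)
    tested = np.zeros(n_params, dtype=bool)
    for j in members:
        x = values[:, j]
        degenerate = np.allclose(x, x[0])
        if mode == "two-sample":
            y2 = values2[:, j]
            degenerate = degenerate and np.allclose(y2, y2[0])
        if degenerate:
            continue
        if mode == "one-sample":
            res = stats.ttest_1samp(x, 0.0)
        else:
            res = stats.ttest_ind(x, values2[:, j])
        t[j], p[j] = res.statistic, res.pvalue
        tested[j] = True

    p_adj = np.full(n_params, np.nan)
    signif = np.zeros(n_params, dtype=bool)
    class_of = np.full(n_params, "", dtype=object)
    for c in classes:
        idx = [j for j in c.members if tested[j]]
        class_of[c.members] = c.label
        if idx:
            rej, padj, *_ = multipletests(p[idx], alpha=alpha, method="fdr_bh")
            p_adj[idx] = padj
            signif[idx] = rej

    index = names if names is not None else list(range(n_params))
    return pd.DataFrame({
        "class": class_of, "t": t, "p": p, "p_fdr": p_adj,
        "significant": signif, "tested": tested,
    }, index=index)


def _anova_row(ss_eff, df_eff, ss_err, df_err):
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err
    F = ms_eff / ms_err if ms_err > 0 else np.nan
    p = stats.f.sf(F, df_eff, df_err) if np.isfinite(F) else np.nan
    return {"ss": ss_eff, "df1": df_eff, "df2": df_err, "F": F, "p": p}


def mixed_anova_2x2(data: np.ndarray, group: np.ndarray) -> pd.DataFrame:
    """Split-plot ANOVA: 2-level between factor x 2-level within factor.

    ``data`` is (n_subjects, 2) with the two within-factor levels;
    ``group`` the between-factor label per subject (2 levels).  Returns F
    and p for the between main effect, the within main effect and their
    interaction, each on (1, N-2) degrees of freedom.
    """
    data = np.asarray(data, dtype=float)
    group = np.asarray(group)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("data must be (n_subjects, 2)")
    if np.any(~np.isfinite(data)):
        raise ValueError("missing cells are not supported")
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValueError("between factor must have exactly 2 levels")
    n_g = np.array([(group == g).sum() for g in levels])
    if np.any(n_g < 2):
        raise ValueError("need at least 2 subjects per group")
    N = data.shape[0]

    subj_mean = data.mean(axis=1)
    grand = subj_mean.mean()
    g_mean = np.array([subj_mean[group == g].mean() for g in levels])
    ss_G = 2 * (n_g * (g_mean - grand) ** 2).sum()
    ss_SwG = 2 * sum(
        ((subj_mean[group == g] - g_mean[k]) ** 2).sum()
        for k, g in enumerate(levels)
    )

    w_mean = data.mean(axis=0)
    ss_W = (n_g.sum()) * ((w_mean - data.mean()) ** 2).sum()
    gw_mean = np.array([data[group == g].mean(axis=0) for g in levels])
    ss_GW = sum(
        n_g[k] * ((gw_mean[k] - g_mean[k] - w_mean + grand) ** 2).sum()
        for k in range(2)
    )
    resid = np.zeros_like(data)
    for k, g in enumerate(levels):
        m = group == g
        resid[m] = data[m] - subj_mean[m, None] - gw_mean[k][None, :] + g_mean[k]
    ss_WS = (resid ** 2).sum()

    rows = {
        "group": _anova_row(ss_G, 1, ss_SwG, N - 2),
        "within": _anova_row(ss_W, 1, ss_WS, N - 2),
        "group x within": _anova_row(ss_GW, 1, ss_WS, N - 2),
    }
    return pd.DataFrame(rows).T


def mixed_anova_3way(data: np.ndarray, group: np.ndarray) -> pd.DataFrame:
    """Mixed ANOVA: between-subject group x within A (stimulus) x within B
    (hemifield).

    ``data`` is (n_subjects, a, b); complete cells required.  Classical
    univariate split-plot decomposition with separate error strata per
    within-factor combination; no sphericity correction is applied (the
    two-level factor needs none).
    """
    data = np.asarray(data, dtype=float)
    group = np.asarray(group)
    if data.ndim != 3:
        raise ValueError("data must be (n_subjects, a, b)")
    if np.any(~np.isfinite(data)):
        raise ValueError("incomplete design: non-finite cells")
    levels = np.unique(group)
    G = len(levels)
    if G != 2:
        raise ValueError("between factor must have exactly 2 levels")
    n_g = np.array([(group == g).sum() for g in levels])
    if len(set(n_g)) != 1:
        raise ValueError("group sizes must be equal for the 3-way ANOVA")
    N, a, b = data.shape

    gi = np.array([np.nonzero(group == g)[0] for g in levels])
    grand = data.mean()
    m_s = data.mean(axis=(1, 2))                      # subject
    m_g = np.array([data[gi[k]].mean() for k in range(G)])
    m_i = data.mean(axis=(0, 2))                      # A levels
    m_j = data.mean(axis=(0, 1))                      # B levels
    m_gi = np.array([data[gi[k]].mean(axis=(0, 2)) for k in range(G)])
    m_gj = np.array([data[gi[k]].mean(axis=(0, 1)) for k in range(G)])
    m_ij = data.mean(axis=0)
    m_gij = np.array([data[gi[k]].mean(axis=0) for k in range(G)])
    m_si = data.mean(axis=2)                          # subject x A
    m_sj = data.mean(axis=1)                          # subject x B

    ss_G = a * b * (n_g * (m_g - grand) ** 2).sum()
    ss_SwG = a * b * sum(
        ((m_s[gi[k]] - m_g[k]) ** 2).sum() for k in range(G)
    )
    ss_A = b * N * ((m_i - grand) ** 2).sum()
    ss_GA = b * sum(
        n_g[k] * ((m_gi[k] - m_g[k] - m_i + grand) ** 2).sum() for k in range(G)
    )
    ss_AS = b * sum(
        ((m_si[gi[k]] - m_s[gi[k], None] - m_gi[k][None] + m_g[k]) ** 2).sum()
        for k in range(G)
    )
    ss_B = a * N * ((m_j - grand) ** 2).sum()
    ss_GB = a * sum(
        n_g[k] * ((m_gj[k] - m_g[k] - m_j + grand) ** 2).sum() for k in range(G)
    )
    ss_BS = a * sum(
        ((m_sj[gi[k]] - m_s[gi[k], None] - m_gj[k][None] + m_g[k]) ** 2).sum()
        for k in range(G)
    )
    ss_AB = N * ((m_ij - m_i[:, None] - m_j[None, :] + grand) ** 2).sum()
    ss_GAB = sum(
        n_g[k] * ((m_gij[k] - m_gi[k][:, None] - m_gj[k][None, :] + m_g[k]
                   - m_ij + m_i[:, None] + m_j[None, :] - grand) ** 2).sum()
        for k in range(G)
    )
    resid = np.zeros_like(data)
    for k in range(G):
        idx = gi[k]
        resid[idx] = (
            data[idx]
            - m_si[idx][:, :, None]
            - m_sj[idx][:, None, :]
            + m_s[idx][:, None, None]
            - m_gij[k][None]
            + m_gi[k][None, :, None]
            + m_gj[k][None, None, :]
            - m_g[k]
        )
    ss_ABS = (resid ** 2).sum()

    df_sub = N - G
    rows = {
        "group": _anova_row(ss_G, G - 1, ss_SwG, df_sub),
        "stimulus": _anova_row(ss_A, a - 1, ss_AS, (a - 1) * df_sub),
        "hemifield": _anova_row(ss_B, b - 1, ss_BS, (b - 1) * df_sub),
        "group x stimulus": _anova_row(ss_GA, a - 1, ss_AS, (a - 1) * df_sub),
        "group x hemifield": _anova_row(ss_GB, b - 1, ss_BS, (b - 1) * df_sub),
        "stimulus x hemifield": _anova_row(
            ss_AB, (a - 1) * (b - 1), ss_ABS, (a - 1) * (b - 1) * df_sub),
        "group x stimulus x hemifield": _anova_row(
            ss_GAB, (a - 1) * (b - 1), ss_ABS, (a - 1) * (b - 1) * df_sub),
    }
    return pd.DataFrame(rows).T


@dataclass
class LIResult:
    li: float
    ci: tuple[float, float]
    threshold: float | None
    n_boot: int
    trim: float
    seed: int | None
    bootstrap_mean: float = field(default=np.nan)

    def __post_init__(self):
        if np.isfinite(self.li) and not (-1.0 - 1e-12 <= self.li <= 1.0 + 1e-12):
            raise ValueError("LI must lie in [-1, 1]")


def bootstrap_li(
    left_values: np.ndarray,
    right_values: np.ndarray,
    n_boot: int = 10_000,
    trim: float = 0.25,
    threshold: float | None = None,
    seed: int | None = 0,
) -> LIResult:
    """Bootstrap lateralization index over suprathreshold voxel values.

    Values below the threshold (default: half the overall maximum) are
    discarded; each side is then resampled with replacement ``n_boot``
    times and LI = (sum L - sum R)/(sum L + sum R) computed per resample.
    The reported LI is the symmetric ``trim``-trimmed mean of the bootstrap
    distribution.  If thresholding empties one side, the LI degenerates to
    +/-1 (full dominance of the surviving side); if it empties both, the LI
    is undefined (NaN).
    """
    left = np.asarray(left_values, dtype=float).ravel()
    right = np.asarray(right_values, dtype=float).ravel()
    if left.size == 0 and right.size == 0:
        raise ValueError("both sides empty: LI undefined")
    if threshold is None:
        allmax = max(left.max(initial=-np.inf), right.max(initial=-np.inf))
        threshold = 0.5 * allmax
    left = left[left >= threshold]
    right = right[right >= threshold]
    if left.size == 0 and right.size == 0:
        return LIResult(np.nan, (np.nan, np.nan), threshold, 0, trim, seed)
    if left.size == 0 or right.size == 0:
        li = 1.0 if right.size == 0 else -1.0
        return LIResult(li, (li, li), threshold, 0, trim, seed)

    rng = np.random.default_rng(seed)
    sl = left[rng.integers(0, left.size, size=(n_boot, left.size))].sum(axis=1)
    sr = right[rng.integers(0, right.size, size=(n_boot, right.size))].sum(axis=1)
    lis = (sl - sr) / (sl + sr)
    li = float(stats.trim_mean(lis, trim))
    lo, hi = np.percentile(lis, [2.5, 97.5])
    return LIResult(li, (float(lo), float(hi)), threshold, n_boot, trim, seed,
                    bootstrap_mean=float(lis.mean()))
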