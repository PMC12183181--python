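"""Edgewise group inference: mass-univariate ANOVA with BH-FDR control,
pairwise post-hoc t-tests, and summary-statistic demographic tests.

The omnibus comparison is a one-way fixed-effects ANOVA per edge across the
diagnostic groups; edges surviving Benjamini-Hochberg FDR at q < 0.05 are
followed up with uncorrected pooled-variance two-sample t-tests per group
pair, summarized as a qualitative ordering pattern (e.g. ``HAD<HC, HAD<LAD,
LAD~HC``). Group covariates are deliberately NOT entered here: they are
handled upstream by ComBat harmonization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def edgewise_anova(features, group_labels):
    """Vectorized one-way ANOVA per feature column.

    Returns (F, p) arrays with df (g-1, N-g). Features constant across all
    subjects get F = 0 and p = 1 by convention (nothing to test) and are
    reported via the third returned array of flags.
    """
    y = np.asarray(features, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    labels = np.asarray(group_labels)
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    ns = np.array([(labels == g).sum() for g in groups], dtype=float)
    if (ns < 2).any():
        small = [str(g) for g, n in zip(groups, ns) if n < 2]
        raise ValueError(f"group(s) with fewer than 2 subjects: {small}")
    if np.isnan(y).any():
        raise ValueError("missing values at tested edges; drop or impute first")
    n_total = y.shape[0]
    g = len(groups)
    grand = y.mean(axis=0)
    ssb = np.zeros(y.shape[1])
    ssw = np.zeros(y.shape[1])
    for gi, lab in enumerate(groups):
        yg = y[labels == lab]
        mg = yg.mean(axis=0)
        ssb += ns[gi] * (mg - grand) ** 2
        ssw += ((yg - mg) ** 2).sum(axis=0)
    df_b, df_w = g - 1, n_total - g
    constant = (ssb + ssw) <= 1e-12 * np.maximum(1.0, np.abs(grand))
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
    p = stats.f.sf(f, df_b, df_w)
    f[constant] = 0.0
    p[constant] = 1.0
    return f, p, constant


def fdr_bh(p, q_threshold: float = 0.05):
    """Benjamini-Hochberg step-up: (adjusted q values, significance mask).

    q_(k) = min over j >= k of m * p_(j) / j, capped at 1; the mask marks
    q <= q_threshold.
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=q_threshold, method="fdr_bh")
    return q, q <= q_threshold


def _pooled_t(a, b):
    """Vectorized pooled-variance two-sided two-sample t over columns."""
    n1, n2 = a.shape[0], b.shape[0]
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    v1 = a.var(axis=0, ddof=1)
    v2 = b.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    t = np.where(sp2 == 0, 0.0, t)
    p = 2 * stats.t.sf(np.abs(t), n1 + n2 - 2)
    return t, p


def _welch_t(a, b):
    res = stats.ttest_ind(a, b, axis=0, equal_var=False)
    return np.atleast_1d(res.statistic), np.atleast_1d(res.pvalue)


def posthoc_ttests(features, group_labels, edges, alpha: float = 0.05, welch: bool = False):
    """Pairwise two-sample t-tests at the given (FDR-significant) edges.

    Returns a DataFrame with one row per edge: per group pair the t statistic
    and uncorrected p value, plus a qualitative ``pattern`` label derived from
    which pairs pass p < alpha and the direction of their mean difference
    (``A<B`` / ``A>B`` / ``A~B``).
    """
    y = np.asarray(features, dtype=float)
    labels = np.asarray(group_labels)
    groups = list(pd.unique(labels))
    edges = np.asarray(edges, dtype=int)
    sub = y[:, edges]
    rows = {"edge": edges}
    per_pair = {}
    for ga, gb in combinations(groups, 2):
        a, b = sub[labels == ga], sub[labels == gb]
        if a.shape[0] < 2 or b.shape[0] < 2:
            raise ValueError(f"group {ga!r} or {gb!r} has fewer than 2 subjects")
        t, p = (_welch_t if welch else _pooled_t)(a, b)
        rows[f"t_{ga}_vs_{gb}"] = t
        rows[f"p_{ga}_vs_{gb}"] = p
        diff = a.mean(axis=0) - b.mean(axis=0)
        per_pair[(ga, gb)] = (p, diff)
    patterns = []
    for k in range(len(edges)):
        parts = []
        for (ga, gb), (p, diff) in per_pair.items():
            if p[k] < alpha:
                parts.append(f"{ga}<{gb}" if diff[k] < 0 else f"{ga}>{gb}")
            else:
                parts.append(f"{ga}~{gb}")
        patterns.append(", ".join(parts))
    rows["pattern"] = patterns
    return pd.DataFrame(rows)


class EdgewiseGroupModel:
    """Omnibus-plus-post-hoc edgewise group comparison.

    ``fit()`` runs the per-edge one-way ANOVA, BH-FDR correction at
    ``q_threshold`` and, for surviving edges only, the pairwise post-hoc
    t-tests, returning :class:`EdgewiseResults`.
    """

    def __init__(self, features, group_labels, edge_map=None, kind: str = ""):
        self.features = np.asarray(features, dtype=float)
        self.group_labels = np.asarray(group_labels)
        self.edge_map = edge_map
        self.kind = kind

    def fit(self, q_threshold: float = 0.05, posthoc_alpha: float = 0.05, welch: bool = False):
        f, p, constant = edgewise_anova(self.features, self.group_labels)
        q, sig = fdr_bh(p, q_threshold)
        sig_edges = np.flatnonzero(sig)
        posthoc = (
            posthoc_ttests(self.features, self.group_labels, sig_edges, posthoc_alpha, welch)
            if sig_edges.size
            else None
        )
        groups = list(pd.unique(self.group_labels))
        means = {
            g: self.features[self.group_labels == g].mean(axis=0) for g in groups
        }
        sems = {
            g: stats.sem(self.features[self.group_labels == g], axis=0) for g in groups
        }
        return EdgewiseResults(
            f=f, p=p, q=q, significant=sig, constant=constant,
            posthoc=posthoc, group_means=means, group_sems=sems,
            edge_map=self.edge_map, kind=self.kind,
            q_threshold=q_threshold, posthoc_alpha=posthoc_alpha,
        )


@dataclass
class EdgewiseResults:
    """Per-edge omnibus and post-hoc statistics.

    Post-hoc fields are populated only for edges significant at the FDR
    threshold; ``group_means`` / ``group_sems`` support group-mean bar plots
    of the significant edges.
    """

    f: np.ndarray
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray
    constant: np.ndarray
    posthoc: pd.DataFrame | None
    group_means: dict
    group_sems: dict
    edge_map: object
    kind: str
    q_threshold: float
    posthoc_alpha: float

    @property
    def significant_edges(self) -> np.ndarray:
        return np.flatnonzero(self.significant)

    def to_frame(self) -> pd.DataFrame:
        """One row per edge: flat index, (i, j), F, p, q, flag, post-hoc columns."""
        n = len(self.f)
        if self.edge_map is not None:
            pairs = self.edge_map.pairs()
            base = {"edge": np.arange(n), "roi_i": pairs[:, 0], "roi_j": pairs[:, 1]}
        else:
            base = {"edge": np.arange(n)}
        df = pd.DataFrame({**base, "F": self.f, "p": self.p, "q": self.q,
                           "significant": self.significant})
        if self.posthoc is not None:
            df = df.merge(self.posthoc, on="edge", how="left")
        return df

    def summary(self) -> str:
        lines = [
            f"Edgewise group comparison ({self.kind or 'features'})",
            f"  edges tested:        {len(self.f)}",
            f"  FDR q threshold:     {self.q_threshold}",
            f"  significant edges:   {int(self.significant.sum())}",
            f"  min q value:         {self.q.min():.4g}",
        ]
        if self.posthoc is not None and len(self.posthoc):
            counts = self.posthoc["pattern"].value_counts()
            lines.append("  post-hoc patterns:")
            for pat, cnt in counts.items():
                lines.append(f"    {pat}: {cnt}")
        return "\n".join(lines)


def chi_square_from_counts(table):
    """Pearson chi-square (no continuity correction) on a 2 x G count table."""
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    if (expected <= 0).any():
        raise ValueError("expected counts must be positive")
    return float(chi2), float(p)


def anova_from_summary(means, sds, ns):
    """One-way ANOVA reconstructed from per-group means, SDs and sizes.

    Between-group SS from the group means and sizes, within-group SS from
    (n-1) * sd^2; identical to the raw-data ANOVA up to rounding of the
    summaries.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if (ns < 2).any():
        raise ValueError("every group needs n >= 2")
    if (sds <= 0).any():
        raise ValueError("group SDs must be positive")
    g = len(ns)
    n_total = ns.sum()
    grand = (ns * means).sum() / n_total
    ssb = (ns * (means - grand) ** 2).sum()
    ssw = ((ns - 1) * sds**2).sum()
    f = (ssb / (g - 1)) / (ssw / (n_total - g))
    return float(f), float(stats.f.sf(f, g - 1, n_total - g))


def ttest_from_summary(m1, s1, n1, m2, s2, n2, welch: bool = False):
    """Two-sided two-sample t-test from group summaries (pooled by default)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)
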