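"""Clinical association analyses: symptom coupling score, covariate-adjusted
partial correlations, and per-group edge-edge correlations.

The coupling score is the ratio of depression to anxiety severity
(HAMD / HAMA); within each patient group it is related to the altered edges'
FC values by partial correlation controlling for age, sex, education and
head motion. Cross-edge coupling of altered edges is assessed per group by
plain Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def coupling_score(hamd, hama):
    """Symptom coupling: HAMD divided by HAMA (element-wise for arrays)."""
    hamd = np.asarray(hamd, dtype=float)
    hama = np.asarray(hama, dtype=float)
    if np.any(hama <= 0):
        raise ValueError("HAMA must be positive to form the coupling score")
    out = hamd / hama
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class PartialCorrResult:
    """Partial correlation with its two-sided p value.

    ``df`` = n - 2 - K residual degrees of freedom after removing K
    covariates (plus intercept) from both variables.
    """

    r: float
    p: float
    df: int
    n: int
    n_covariates: int

    def __iter__(self):  # allow r, p = partial_corr(...)
        return iter((self.r, self.p))


def _residualize(v, x):
    beta, *_ = np.linalg.lstsq(x, v, rcond=None)
    return v - x @ beta


def partial_corr(x, y, covariates=None) -> PartialCorrResult:
    """Pearson correlation of x and y after regressing out covariates.

    Both variables are residualized on [intercept | covariates]; the p value
    comes from t = r * sqrt(df / (1 - r^2)) with df = n - 2 - K. With no
    covariates this reduces exactly to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have the same length")
    if covariates is None or np.size(covariates) == 0:
        z = np.ones((n, 1))
        k = 0
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        if cov.shape[0] != n:
            raise ValueError("covariate matrix must have n rows")
        z = np.column_stack([np.ones(n), cov])
        if np.linalg.matrix_rank(z) < z.shape[1]:
            raise ValueError("covariate matrix is rank deficient")
        k = cov.shape[1]
    df = n - 2 - k
    if df < 1:
        raise ValueError(f"not enough observations: df = {df} < 1 (n={n}, K={k})")
    rx = _residualize(x, z)
    ry = _residualize(y, z)
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise ValueError("zero residual variance; correlation undefined")
    r = float(np.clip((rx * ry).sum() / denom, -1.0, 1.0))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2 * stats.t.sf(abs(t), df))
    return PartialCorrResult(r=r, p=p, df=df, n=n, n_covariates=k)


def edge_edge_correlation(features, edge_a: int, edge_b: int, group_labels) -> pd.DataFrame:
    """Per-group Pearson correlation between two edges' subject-level values.

    Returns a DataFrame with one row per group: group, r, p, n. Self-pairs
    give r = 1 in every group.
    """
    y = np.asarray(features, dtype=float)
    labels = np.asarray(group_labels)
    a = y[:, edge_a]
    b = y[:, edge_b]
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("missing edge values")
    rows = []
    for g in pd.unique(labels):
        mask = labels == g
        if mask.sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 subjects")
        if edge_a == edge_b:
            r, p = 1.0, 0.0
        else:
            r, p = stats.pearsonr(a[mask], b[mask])
        rows.append({"group": str(g), "r": float(r), "p": float(p), "n": int(mask.sum())})
    return pd.DataFrame(rows)


def coupling_associations(features, records, edges, covariate_columns=("age", "sex", "education", "mean_fd"), groups=("HAD", "LAD")) -> pd.DataFrame:
    """Partial correlations between altered edges and the coupling score.

    For each patient group and each supplied edge index, correlates the
    subjects' edge values with HAMD/HAMA, controlling for the named
    phenotype covariates (sex coded as a 0/1 indicator). Returns a tidy
    DataFrame: group, edge, r, p, n, df, covariates.
    """
    pheno = pd.DataFrame([r.as_dict() for r in records])
    y = np.asarray(features, dtype=float)
    rows = []
    for g in groups:
        mask = (pheno["group"] == g).to_numpy()
        if mask.sum() == 0:
            continue
        sub = pheno[mask]
        score = coupling_score(sub["hamd"].to_numpy(), sub["hama"].to_numpy())
        cov_cols = []
        for c in covariate_columns:
            v = sub[c]
            if v.dtype == object:
                v = (v == v.iloc[0]).astype(float)  # binary indicator
            cov_cols.append(v.to_numpy(dtype=float))
        cov = np.column_stack(cov_cols) if cov_cols else None
        for e in edges:
            res = partial_corr(y[mask, e], score, cov)
            rows.append(
                {
                    "group": g, "edge": int(e), "r": res.r, "p": res.p,
                    "n": res.n, "df": res.df,
                    "covariates": ",".join(covariate_columns),
                }
            )
    return pd.DataFrame(rows)
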