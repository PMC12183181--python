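"""Parametric empirical-Bayes ComBat harmonization of cohort feature matrices.

The location-scale batch model: feature v of subject j at site i is

    y_ijv = alpha_v + x_j' beta_v + gamma_iv + delta_iv * eps_ijv

where gamma_iv and delta_iv are additive and multiplicative site effects.
After standardizing features by the covariate-adjusted fit, per-site location
and scale estimates are shrunk toward empirical priors (normal on gamma,
inverse-gamma on delta, hyperparameters moment-matched across features; the
conditional posterior modes are found by the standard fixed-point iteration)
and the site effects are removed while the covariate-linked structure is
restored. Deterministic given its inputs.

Exposed both as a statsmodels-style model object
(``CombatModel(features, site, covariates).fit()`` returning
:class:`CombatResults`) and as the functional pair
``fit_combat`` / ``apply_combat``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


class CombatError(ValueError):
    """Raised for designs ComBat cannot harmonize (single site, singleton site, ...)."""


def _design(site_labels, covariates, sites):
    """[site one-hot | covariates] design matrix in the model's site order."""
    onehot = np.column_stack([(site_labels == s).astype(float) for s in sites])
    if covariates is None or np.size(covariates) == 0:
        return onehot
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != len(site_labels):
        cov = cov.T
    return np.column_stack([onehot, cov])


class CombatModel:
    """Empirical-Bayes site-effect model for a (subjects x features) matrix.

    Parameters
    ----------
    features : (n, V) array
        Feature matrix (e.g. edgewise FC values). Columns containing NaN are
        excluded from fitting and passed through unharmonized with a warning.
    site : (n,) array of labels
        Site/batch membership; at least two sites, each with at least two
        subjects.
    covariates : (n, K) array, optional
        Biological covariates whose signal must be preserved (continuous
        columns unstandardized, binary indicators as single 0/1 columns).
    """

    def __init__(self, features, site, covariates=None, feature_names=None):
        self.features = np.asarray(features, dtype=float)
        if self.features.ndim != 2:
            raise CombatError("features must be a 2-D (subjects x features) matrix")
        self.site = np.asarray(site)
        if self.site.shape[0] != self.features.shape[0]:
            raise CombatError("site labels must align with feature rows")
        self.covariates = (
            None if covariates is None else np.atleast_2d(np.asarray(covariates, dtype=float))
        )
        if self.covariates is not None and self.covariates.shape[0] != self.features.shape[0]:
            self.covariates = self.covariates.T
        self.feature_names = feature_names
        self.sites = [str(s) for s in pd.unique(self.site)]
        if len(self.sites) < 2:
            raise CombatError("harmonization needs at least 2 sites; got 1")
        counts = pd.Series(self.site.astype(str)).value_counts()
        singletons = counts[counts < 2]
        if len(singletons):
            raise CombatError(
                f"site(s) with a single subject cannot be harmonized: "
                f"{singletons.index.tolist()}"
            )

    def fit(self, eb_tol: float = 1e-4, max_iter: int = 5000) -> "CombatResults":
        y = self.features
        site = self.site.astype(str)
        n, v_all = y.shape
        usable = ~np.isnan(y).any(axis=0)
        if not usable.all():
            warnings.warn(
                f"{int((~usable).sum())} feature(s) contain missing values; "
                "excluded from harmonization and passed through unchanged",
                stacklevel=2,
            )
        yv = y[:, usable]

        design = _design(site, self.covariates, self.sites)
        nb = len(self.sites)
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise CombatError(
                "design matrix (site indicators + covariates) is rank deficient; "
                "a covariate is confounded with site"
            )
        beta_hat, *_ = np.linalg.lstsq(design, yv, rcond=None)
        n_per_site = np.array([(site == s).sum() for s in self.sites], dtype=float)
        grand_mean = (n_per_site / n) @ beta_hat[:nb]
        resid = yv - design @ beta_hat
        var_pooled = (resid**2).mean(axis=0)
        if (var_pooled <= 0).any():
            raise CombatError("feature(s) with zero pooled variance cannot be scaled")

        beta_cov = beta_hat[nb:]
        stand_mean = grand_mean[None, :] + (
            design[:, nb:] @ beta_cov if beta_cov.size else 0.0
        )
        z = (yv - stand_mean) / np.sqrt(var_pooled)

        gamma_hat = np.vstack([z[site == s].mean(axis=0) for s in self.sites])
        delta_hat = np.vstack([z[site == s].var(axis=0, ddof=1) for s in self.sites])

        gamma_bar = gamma_hat.mean(axis=1)
        tau2 = gamma_hat.var(axis=1, ddof=1)
        # inverse-gamma hyperparameters moment-matched across features
        m = delta_hat.mean(axis=1)
        s2 = delta_hat.var(axis=1, ddof=1)
        lam = (2 * s2 + m**2) / s2
        theta = (m * s2 + m**3) / s2

        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        for i, s in enumerate(self.sites):
            zi = z[site == s]
            ni = zi.shape[0]
            g, d = gamma_hat[i].copy(), delta_hat[i].copy()
            for _ in range(max_iter):
                g_new = (ni * tau2[i] * gamma_hat[i] + d * gamma_bar[i]) / (
                    ni * tau2[i] + d
                )
                sum2 = ((zi - g_new[None, :]) ** 2).sum(axis=0)
                d_new = (theta[i] + 0.5 * sum2) / (ni / 2 + lam[i] - 1)
                change = max(
                    np.max(np.abs(g_new - g) / np.maximum(np.abs(g), 1e-12)),
                    np.max(np.abs(d_new - d) / np.maximum(np.abs(d), 1e-12)),
                )
                g, d = g_new, d_new
                if change < eb_tol:
                    break
            gamma_star[i], delta_star[i] = g, d

        return CombatResults(
            model=self,
            sites=self.sites,
            usable=usable,
            grand_mean=grand_mean,
            beta_cov=beta_cov,
            var_pooled=var_pooled,
            gamma_star=gamma_star,
            delta_star=delta_star,
            gamma_hat=gamma_hat,
            delta_hat=delta_hat,
        )


@dataclass
class CombatResults:
    """Fitted ComBat parameters plus the transform that removes site effects.

    ``gamma_star`` / ``delta_star`` are the shrunken per-site location and
    scale estimates on the standardized scale (site x usable-feature arrays);
    ``delta_star`` is strictly positive.
    """

    model: CombatModel
    sites: list
    usable: np.ndarray
    grand_mean: np.ndarray
    beta_cov: np.ndarray
    var_pooled: np.ndarray
    gamma_star: np.ndarray
    delta_star: np.ndarray
    gamma_hat: np.ndarray
    delta_hat: np.ndarray

    def transform(self, features=None, site=None, covariates=None) -> np.ndarray:
        """Harmonized copy of ``features`` (training data by default).

        Unseen site labels are rejected: the model has no location/scale
        estimate to extrapolate from.
        """
        if features is None:
            features, site, covariates = (
                self.model.features, self.model.site, self.model.covariates,
            )
        features = np.asarray(features, dtype=float)
        site = np.asarray(site).astype(str)
        unseen = sorted(set(site) - set(self.sites))
        if unseen:
            raise CombatError(f"site(s) not in the fitted model: {unseen}")
        if covariates is not None:
            covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
            if covariates.shape[0] != features.shape[0]:
                covariates = covariates.T
        if self.beta_cov.size and covariates is None:
            raise CombatError("model was fitted with covariates; none supplied")
        yv = features[:, self.usable]
        stand_mean = self.grand_mean[None, :] + (
            covariates @ self.beta_cov if self.beta_cov.size else 0.0
        )
        z = (yv - stand_mean) / np.sqrt(self.var_pooled)
        site_idx = np.array([self.sites.index(s) for s in site])
        adj = (z - self.gamma_star[site_idx]) / np.sqrt(self.delta_star[site_idx])
        out = features.copy()
        out[:, self.usable] = adj * np.sqrt(self.var_pooled) + stand_mean
        return out

    def summary(self) -> pd.DataFrame:
        """Per-site shrinkage diagnostics: mean |gamma*| and mean delta*."""
        return pd.DataFrame(
            {
                "site": self.sites,
                "n_subjects": [(self.model.site.astype(str) == s).sum() for s in self.sites],
                "mean_abs_gamma_star": np.abs(self.gamma_star).mean(axis=1),
                "mean_delta_star": self.delta_star.mean(axis=1),
                "mean_abs_gamma_hat": np.abs(self.gamma_hat).mean(axis=1),
            }
        )

    def to_json(self, path) -> None:
        """Serialize the fitted parameters to a structured text file."""
        payload = {
            "sites": self.sites,
            "usable": self.usable.tolist(),
            "grand_mean": self.grand_mean.tolist(),
            "beta_cov": self.beta_cov.tolist(),
            "var_pooled": self.var_pooled.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta_star": self.delta_star.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def fit_combat(features, site, covariates=None) -> CombatResults:
    """Fit the parametric EB ComBat model; see :class:`CombatModel`."""
    return CombatModel(features, site, covariates).fit()


def apply_combat(results: CombatResults, features=None, site=None, covariates=None) -> np.ndarray:
    """Remove fitted site effects from ``features`` (training data by default)."""
    return results.transform(features, site, covariates)
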