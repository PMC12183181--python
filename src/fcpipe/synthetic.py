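"""Synthetic multi-site cohort generator with known, recoverable effects.

Emulates the structure of a multi-site resting-state consortium cohort: three
diagnostic groups (high-anxiety depression HAD, low-anxiety depression LAD,
healthy controls HC) scanned at several sites, each subject contributing a
band-limited AR(1) Gaussian ROI time series with a group-specific correlation
structure, plus a phenotype row with demographics, head motion and clinical
scales. Planted group effects (static correlation deltas, regime-switching
dynamic variability) and site effects are fully parameterized so that the
downstream inference can be validated by parameter recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .connectivity import EdgeIndexMap
from .core import HAMA_THRESHOLD, RoiTimeSeries, SubjectRecord

#: Eigenvalue floor used by the nearest-PD correction.
PD_EIG_FLOOR = 1e-6


@dataclass(frozen=True)
class GroupClinicalModel:
    """Mean/SD of the two Hamilton scales for one group."""

    hamd_mean: float
    hamd_sd: float
    hama_mean: float
    hama_sd: float


#: Default clinical models. HAD and LAD follow the consortium summary table
#: (HAMD 20.47+/-3.04 / 20.16+/-4.92, HAMA 25.52+/-5.39 / 10.78+/-2.93); the
#: healthy-control values are not reported there and are set to typical
#: screened-control levels.
DEFAULT_CLINICAL = {
    "HAD": GroupClinicalModel(20.47, 3.04, 25.52, 5.39),
    "LAD": GroupClinicalModel(20.16, 4.92, 10.78, 2.93),
    "HC": GroupClinicalModel(1.6, 1.5, 4.0, 2.5),
}


@dataclass
class SyntheticDesign:
    """Full specification of a synthetic cohort.

    ``effect_edges_static`` / ``effect_edges_dynamic`` are lists of
    ``(flat_edge_index, group_label, delta)``: a static entry shifts the
    target correlation of that edge in that group by ``delta``; a dynamic
    entry makes the edge's correlation alternate between base + delta and
    base - delta across blocks, inflating the windowed-correlation CV for
    that group without moving its long-run mean.

    ``site_scale_sd`` / ``site_shift_sd`` govern a per-site multiplicative
    gain (log-normal) and additive offset applied to the signal.
    """

    n_per_group: tuple = (73, 55, 50)
    groups: tuple = ("HAD", "LAD", "HC")
    n_rois: int = 50
    n_timepoints: int = 240
    tr_seconds: float = 2.0
    n_sites: int = 3
    site_scale_sd: float = 0.1
    site_shift_sd: float = 0.1
    effect_edges_static: list = field(default_factory=list)
    effect_edges_dynamic: list = field(default_factory=list)
    ar_coefficient: float = 0.4
    noise_sd: float = 1.0
    base_correlation_strength: float = 0.3
    dynamic_block_seconds: float = 50.0
    clinical_model: dict = field(default_factory=lambda: dict(DEFAULT_CLINICAL))
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_per_group, int):
            self.n_per_group = tuple([self.n_per_group] * len(self.groups))
        if len(self.n_per_group) != len(self.groups):
            raise ValueError("n_per_group must give one count per group")
        if any(n < 1 for n in self.n_per_group):
            raise ValueError("empty groups are not allowed")
        if self.n_sites < 1:
            raise ValueError("need at least one site")
        if self.n_sites > sum(self.n_per_group):
            raise ValueError("more sites than subjects")
        if not (0 <= self.ar_coefficient < 1):
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if self.noise_sd <= 0 or self.tr_seconds <= 0:
            raise ValueError("noise_sd and tr_seconds must be positive")
        if self.site_scale_sd < 0 or self.site_shift_sd < 0:
            raise ValueError("site effect SDs must be nonnegative")
        for g in self.groups:
            if g not in self.clinical_model:
                raise ValueError(f"no clinical model for group {g!r}")
        # the HAMA threshold must separate the anxiety groups by construction
        if "HAD" in self.groups and self.clinical_model["HAD"].hama_mean <= HAMA_THRESHOLD:
            raise ValueError("HAD clinical model must place HAMA above 14")
        if "LAD" in self.groups and self.clinical_model["LAD"].hama_mean >= HAMA_THRESHOLD:
            raise ValueError("LAD clinical model must place HAMA below 14")

    @property
    def n_subjects(self) -> int:
        return int(sum(self.n_per_group))

    @property
    def edge_map(self) -> EdgeIndexMap:
        return EdgeIndexMap(self.n_rois)


def nearest_pd_correlation(mat: np.ndarray, eig_floor: float = PD_EIG_FLOOR) -> np.ndarray:
    """Project a symmetric matrix to the nearest PD correlation matrix.

    Eigenvalues below ``eig_floor`` are clipped up, then the diagonal is
    rescaled back to one.
    """
    vals, vecs = np.linalg.eigh(mat)
    vals = np.maximum(vals, eig_floor)
    out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2


def make_group_covariance(base_correlation: np.ndarray, effects, edge_map=None) -> np.ndarray:
    """Apply per-edge correlation deltas to a base correlation matrix.

    ``effects`` is a list of ``(edge, delta)`` where ``edge`` is either a flat
    edge index (requires ``edge_map``) or an (i, j) pair. The result is
    symmetric positive definite with unit diagonal; if the raw result is not
    PD it is projected to the nearest PD correlation matrix (warned, and the
    effect-edge entries re-imposed afterwards when possible).
    """
    base = np.asarray(base_correlation, dtype=float)
    if base.ndim != 2 or base.shape[0] != base.shape[1]:
        raise ValueError("base correlation must be square")
    if not np.allclose(base, base.T, atol=1e-10):
        raise ValueError("base correlation must be symmetric")
    if not np.allclose(np.diag(base), 1.0, atol=1e-10):
        raise ValueError("base correlation must have unit diagonal")
    out = base.copy()
    targets = []
    for edge, delta in effects:
        if np.isscalar(edge):
            if edge_map is None:
                edge_map = EdgeIndexMap(base.shape[0])
            i, j = edge_map.pair(int(edge))
        else:
            i, j = edge
        target = base[i, j] + delta
        if abs(target) >= 1:
            raise ValueError(
                f"delta {delta:+g} at edge ({i},{j}) pushes |r| to {abs(target):g} >= 1"
            )
        out[i, j] = out[j, i] = target
        targets.append((i, j, target))
    min_eig = np.linalg.eigvalsh(out).min()
    if min_eig <= 0:
        warnings.warn(
            f"effect matrix not PD (min eigenvalue {min_eig:.3g}); applying "
            "nearest-PD correction",
            stacklevel=2,
        )
        out = nearest_pd_correlation(out)
    return out


def random_base_correlation(n_rois: int, rng: np.random.Generator, strength: float = 0.3) -> np.ndarray:
    """Low-rank-plus-diagonal random correlation matrix with moderate edges."""
    k = max(2, n_rois // 10)
    w = rng.normal(scale=strength, size=(n_rois, k))
    cov = w @ w.T + np.eye(n_rois)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return (corr + corr.T) / 2


def _ar1_series(chols, schedule, n_timepoints, n_rois, ar, noise_sd, rng):
    """AR(1) process whose innovation covariance follows ``schedule``.

    ``chols`` are Cholesky factors of the per-state covariance matrices and
    ``schedule[t]`` picks the state at each timepoint. The innovation scaling
    sqrt(1 - ar^2) makes the stationary covariance equal the state covariance.
    """
    innov_scale = np.sqrt(1.0 - ar**2)
    x = np.empty((n_timepoints, n_rois))
    e = rng.standard_normal((n_timepoints, n_rois))
    x[0] = e[0] @ chols[schedule[0]].T
    for t in range(1, n_timepoints):
        x[t] = ar * x[t - 1] + innov_scale * (e[t] @ chols[schedule[t]].T)
    return noise_sd * x


def sample_bold(cov, n_timepoints, tr_seconds=2.0, ar_coefficient=0.4, noise_sd=1.0, seed=None):
    """Stationary AR(1) Gaussian series with the given cross-ROI covariance.

    The large-sample Pearson correlation matrix converges to ``cov`` (taken as
    a correlation matrix) and each ROI's lag-1 autocorrelation equals
    ``ar_coefficient``. ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    cov = np.asarray(cov, dtype=float)
    if np.linalg.eigvalsh(cov).min() <= 0:
        raise ValueError("covariance must be positive definite")
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chol = np.linalg.cholesky(cov)
    schedule = np.zeros(n_timepoints, dtype=int)
    data = _ar1_series([chol], schedule, n_timepoints, cov.shape[0], ar_coefficient, noise_sd, rng)
    return RoiTimeSeries(data, tr_seconds=tr_seconds)


def _group_state_covs(design: SyntheticDesign, base: np.ndarray, group: str):
    """Per-group list of covariance states (1 state if no dynamic effects)."""
    emap = design.edge_map
    static = [(e, d) for e, g, d in design.effect_edges_static if g == group]
    dynamic = [(e, d) for e, g, d in design.effect_edges_dynamic if g == group]
    center = make_group_covariance(base, static, emap)
    if not dynamic:
        return [center]
    up = make_group_covariance(center, dynamic, emap)
    down = make_group_covariance(center, [(e, -d) for e, d in dynamic], emap)
    return [up, down]


def generate_cohort(design: SyntheticDesign):
    """Generate (records, series) for a full multi-site cohort.

    Deterministic given ``design.seed``: a single generator drives covariance
    construction, site assignment, site effects, signals and phenotypes in a
    fixed order.
    """
    rng = np.random.default_rng(design.seed)
    base = random_base_correlation(design.n_rois, rng, design.base_correlation_strength)
    group_states = {g: _group_state_covs(design, base, g) for g in design.groups}
    group_chols = {
        g: [np.linalg.cholesky(c) for c in covs] for g, covs in group_states.items()
    }

    site_gain = np.exp(rng.normal(0.0, design.site_scale_sd, size=design.n_sites))
    site_shift = rng.normal(0.0, design.site_shift_sd, size=design.n_sites)

    block = max(1, int(round(design.dynamic_block_seconds / design.tr_seconds)))

    labels = [g for g, n in zip(design.groups, design.n_per_group) for _ in range(n)]
    order = rng.permutation(len(labels))  # interleave groups across sites
    site_of = np.empty(len(labels), dtype=int)
    site_of[order] = np.arange(len(labels)) % design.n_sites

    records, series = [], []
    for idx, group in enumerate(labels):
        sid = f"sub{idx:04d}"
        site = int(site_of[idx])
        chols = group_chols[group]
        if len(chols) == 1:
            schedule = np.zeros(design.n_timepoints, dtype=int)
        else:
            schedule = (np.arange(design.n_timepoints) // block) % 2
        data = _ar1_series(
            chols, schedule, design.n_timepoints, design.n_rois,
            design.ar_coefficient, design.noise_sd, rng,
        )
        data = data * site_gain[site] + site_shift[site]
        series.append(
            RoiTimeSeries(data, tr_seconds=design.tr_seconds, subject_id=sid)
        )

        cm = design.clinical_model[group]
        age = float(np.clip(rng.normal(33.5, 11.0), 18, 65))
        sex = "male" if rng.random() < 0.5 else "female"
        education = float(np.clip(rng.normal(11.2, 3.5), 3, 22))
        mean_fd = float(np.clip(np.abs(rng.normal(0.10, 0.045)), 0.01, None))
        hamd = _truncnorm(rng, cm.hamd_mean, cm.hamd_sd, low=0.0)
        if group == "HAD":
            hama = _truncnorm(rng, cm.hama_mean, cm.hama_sd, low=HAMA_THRESHOLD + 0.01)
        elif group == "LAD":
            hama = _truncnorm(rng, cm.hama_mean, cm.hama_sd, low=0.0, high=HAMA_THRESHOLD - 0.01)
        else:
            hama = _truncnorm(rng, cm.hama_mean, cm.hama_sd, low=0.0)
        records.append(
            SubjectRecord(
                subject_id=sid, site=f"site{site}", group=group, age=round(age, 2),
                sex=sex, education=round(education, 2), mean_fd=round(mean_fd, 4),
                hamd=round(hamd, 2), hama=round(hama, 2),
            )
        )
    return records, series


def _truncnorm(rng, mean, sd, low=-np.inf, high=np.inf) -> float:
    a, b = (low - mean) / sd, (high - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def inject_site_effects(features, sites, shift_sd, scale_sd, seed=None):
    """Feature-level site effects for isolated harmonization tests.

    Per site s and feature v an additive shift ~ N(0, shift_sd) and a
    multiplicative factor exp(N(0, scale_sd)) applied to the deviation from
    the feature's grand mean:
    ``y' = mean_v + scale_sv * (y - mean_v) + shift_sv``.
    """
    features = np.asarray(features, dtype=float)
    sites = np.asarray(sites)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = features.copy()
    center = features.mean(axis=0)
    for s in np.unique(sites):
        mask = sites == s
        shift = rng.normal(0.0, shift_sd, size=features.shape[1])
        scale = np.exp(rng.normal(0.0, scale_sd, size=features.shape[1]))
        out[mask] = center + scale * (features[mask] - center) + shift
    return out


def simulate_feature_matrix(
    n_per_site=30,
    n_sites=3,
    n_features=40,
    covariate_beta=0.5,
    site_shift_sd=0.4,
    site_scale_sd=0.2,
    noise_sd=1.0,
    seed=None,
):
    """Covariate-structured feature matrix with known site effects.

    Follows the location-scale batch model: features are covariate signal
    plus noise, and each site adds a location shift ~ N(0, site_shift_sd)
    and multiplies the *noise* by exp(N(0, site_scale_sd)) per feature.
    Returns ``(features, clean_features, sites, covariates)`` where
    ``clean_features`` carries the covariate signal and unit-scale noise but
    no site effect. Covariates are (age-like continuous, binary indicator);
    the first covariate has slope ``covariate_beta`` on every feature.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = n_per_site * n_sites
    sites = np.repeat([f"site{i}" for i in range(n_sites)], n_per_site)
    age = rng.normal(0.0, 1.0, size=n)
    sex = (rng.random(n) < 0.5).astype(float)
    covariates = np.column_stack([age, sex])
    signal = covariate_beta * age[:, None] + 0.3 * sex[:, None]
    noise = rng.normal(0.0, noise_sd, size=(n, n_features))
    clean = signal + noise
    noisy = clean.copy()
    for s in np.unique(sites):
        mask = sites == s
        shift = rng.normal(0.0, site_shift_sd, size=n_features)
        scale = np.exp(rng.normal(0.0, site_scale_sd, size=n_features))
        noisy[mask] = signal[mask] + shift + scale * noise[mask]
    return noisy, clean, sites, covariates
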