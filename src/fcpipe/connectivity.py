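"""Static and dynamic functional connectivity at the edge level.

An *edge* is an unordered pair of ROIs. Static FC is the Fisher z-transformed
Pearson correlation over the whole time course. Dynamic FC is the coefficient
of variation (SD/mean) of the windowed Pearson correlations across a
rectangular sliding window, quantifying how much an edge's coupling fluctuates
over the scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: Clipping distance from |r| = 1 before the Fisher transform.
FISHER_EPS = 1e-7

#: Floor applied to |mean windowed r| in the CV denominator.
CV_MEAN_FLOOR = 1e-6


@dataclass(frozen=True)
class EdgeIndexMap:
    """Bijection between upper-triangle ROI pairs (i < j) and flat edge indices.

    Edges are ordered row-major over the strict upper triangle, i.e.
    (0,1), (0,2), ..., (0,R-1), (1,2), ... — the order ``np.triu_indices``
    yields. For the 264-ROI functional parcellation this gives 34,716 edges.
    """

    n_rois: int

    def __post_init__(self) -> None:
        if self.n_rois < 2:
            raise ValueError(f"need at least 2 ROIs, got {self.n_rois}")

    @property
    def n_edges(self) -> int:
        return self.n_rois * (self.n_rois - 1) // 2

    @property
    def rows(self) -> np.ndarray:
        return np.triu_indices(self.n_rois, k=1)[0]

    @property
    def cols(self) -> np.ndarray:
        return np.triu_indices(self.n_rois, k=1)[1]

    def flat_index(self, i: int, j: int) -> int:
        """Flat edge index for ROI pair (i, j); order of i and j is ignored."""
        if i == j:
            raise ValueError("self-pairs are not edges")
        if i > j:
            i, j = j, i
        if not (0 <= i < j < self.n_rois):
            raise ValueError(f"pair ({i}, {j}) out of range for {self.n_rois} ROIs")
        return i * (2 * self.n_rois - i - 1) // 2 + (j - i - 1)

    def pair(self, k: int) -> tuple[int, int]:
        """ROI pair for flat edge index k."""
        if not (0 <= k < self.n_edges):
            raise ValueError(f"edge index {k} out of range")
        # invert the row-major triangular numbering
        i = int(
            self.n_rois
            - 2
            - math.floor(
                (math.sqrt(4 * self.n_rois * (self.n_rois - 1) - 8 * k - 7) - 1) / 2
            )
        )
        j = k - i * (2 * self.n_rois - i - 1) // 2 + i + 1
        return i, j

    def pairs(self) -> np.ndarray:
        """(n_edges, 2) array of (i, j) pairs in flat order."""
        r, c = np.triu_indices(self.n_rois, k=1)
        return np.column_stack([r, c])


@dataclass
class EdgeVector:
    """Per-subject edge-wise feature vector aligned to an :class:`EdgeIndexMap`.

    ``kind`` is ``"static-z"`` (Fisher-z correlations) or ``"dynamic-cv"``
    (windowed-correlation coefficient of variation). Edges that could not be
    computed (zero-variance ROI) carry NaN and are listed in ``missing_edges``;
    dynamic edges whose mean windowed correlation hit the denominator floor are
    listed in ``floor_edges``.
    """

    values: np.ndarray
    kind: str
    subject_id: str = ""
    missing_edges: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    floor_edges: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("static-z", "dynamic-cv"):
            raise ValueError(f"unknown edge-vector kind {self.kind!r}")
        valid = self.values[np.isfinite(self.values)]
        if self.kind == "dynamic-cv" and valid.size and (valid < 0).any():
            raise ValueError("dynamic-cv values must be nonnegative")


@dataclass(frozen=True)
class SlidingWindowSpec:
    """Rectangular sliding-window specification in seconds.

    The window must span at least one period of the slowest passband frequency
    (1/f_min = 100 s for a 0.01 Hz high-pass), which motivates the 100 s
    default. Sample counts are derived per subject from the repetition time:
    window length by floor, step by round with a minimum of one sample.
    """

    window_seconds: float = 100.0
    step_seconds: float = 2.0

    def __post_init__(self) -> None:
        if self.window_seconds <= 0 or self.step_seconds <= 0:
            raise ValueError("window and step must be positive")

    def window_samples(self, tr_seconds: float) -> int:
        w = int(math.floor(self.window_seconds / tr_seconds))
        if w < 3:
            raise ValueError(
                f"window of {self.window_seconds}s at TR={tr_seconds}s gives "
                f"{w} samples; need >= 3"
            )
        return w

    def step_samples(self, tr_seconds: float) -> int:
        return max(1, int(round(self.step_seconds / tr_seconds)))


def fisher_z(r):
    """Fisher r-to-z transform with clipping at |r| = 1 - 1e-7.

    Perfect correlations map to a large finite value (atanh(1 - 1e-7) ~ 8.4)
    rather than infinity, keeping downstream statistics finite. Odd function;
    values with |r| > 1 are rejected.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r[np.isfinite(r)]) > 1):
        raise ValueError("correlations must satisfy |r| <= 1")
    z = np.arctanh(np.clip(r, -1 + FISHER_EPS, 1 - FISHER_EPS))
    return z if z.ndim else float(z)


def _correlation_matrix(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation matrix with zero-variance columns flagged.

    Returns (R x R correlation matrix with NaN rows/cols for degenerate ROIs,
    boolean mask of degenerate columns).
    """
    t = x.shape[0]
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0, ddof=1)
    degenerate = sd == 0
    cov = (xc.T @ xc) / (t - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(sd, sd)
    corr = np.clip(corr, -1.0, 1.0)
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    np.fill_diagonal(corr, 1.0)
    return corr, degenerate


def static_fc(ts, edge_map: EdgeIndexMap) -> EdgeVector:
    """Whole-scan static FC: per-edge Fisher-z Pearson correlation.

    Zero-variance ROIs yield NaN at all of their edges, recorded in the
    returned vector's ``missing_edges`` rather than silently zeroed.
    """
    if ts.n_rois != edge_map.n_rois:
        raise ValueError(
            f"series has {ts.n_rois} ROIs but edge map expects {edge_map.n_rois}"
        )
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints for static FC")
    corr, degenerate = _correlation_matrix(ts.data)
    r = corr[edge_map.rows, edge_map.cols]
    missing = np.flatnonzero(~np.isfinite(r))
    z = np.full(r.shape, np.nan)
    ok = np.isfinite(r)
    z[ok] = np.arctanh(np.clip(r[ok], -1 + FISHER_EPS, 1 - FISHER_EPS))
    if degenerate.any():
        import warnings

        warnings.warn(
            f"subject {ts.subject_id!r}: zero-variance ROIs "
            f"{np.flatnonzero(degenerate).tolist()}; their edges set to NaN",
            stacklevel=2,
        )
    return EdgeVector(z, kind="static-z", subject_id=ts.subject_id, missing_edges=missing)


def make_windows(n_timepoints: int, spec: SlidingWindowSpec, tr_seconds: float):
    """Half-open [start, end) sample ranges of full-length sliding windows.

    Windows start every ``step`` samples; a trailing window that would be
    truncated is dropped.
    """
    w = spec.window_samples(tr_seconds)
    s = spec.step_samples(tr_seconds)
    if n_timepoints < w:
        raise ValueError(
            f"series of {n_timepoints} samples shorter than window of {w} samples"
        )
    n_win = (n_timepoints - w) // s + 1
    return [(k * s, k * s + w) for k in range(n_win)]


def windowed_correlations(ts, edge_map: EdgeIndexMap, spec: SlidingWindowSpec) -> np.ndarray:
    """(n_windows, n_edges) matrix of within-window Pearson r values.

    Windows in which an ROI has zero variance contribute NaN at that ROI's
    edges.
    """
    windows = make_windows(ts.n_timepoints, spec, ts.tr_seconds)
    rows, cols = edge_map.rows, edge_map.cols
    out = np.empty((len(windows), edge_map.n_edges))
    for w, (a, b) in enumerate(windows):
        corr, _ = _correlation_matrix(ts.data[a:b])
        out[w] = corr[rows, cols]
    return out


def dynamic_fc_cv(
    ts,
    edge_map: EdgeIndexMap,
    spec: SlidingWindowSpec | None = None,
    use_fisher_z: bool = False,
) -> EdgeVector:
    """Dynamic FC as the coefficient of variation of windowed correlations.

    Per edge: Pearson r within each sliding window, then
    CV = SD(r) / max(|mean(r)|, 1e-6) with the sample (n-1) standard
    deviation. Edges whose mean hit the floor are flagged (``floor_edges``);
    edges with fewer than two valid windows are missing. ``use_fisher_z``
    computes the CV on Fisher-z windowed values instead of raw r (sensitivity
    switch; default follows the raw-r convention).
    """
    spec = spec or SlidingWindowSpec()
    r = windowed_correlations(ts, edge_map, spec)
    if r.shape[0] < 2:
        raise ValueError(
            "dynamic FC needs at least 2 windows; lengthen the scan or shorten "
            "the window"
        )
    if use_fisher_z:
        with np.errstate(invalid="ignore"):
            r = np.arctanh(np.clip(r, -1 + FISHER_EPS, 1 - FISHER_EPS))
    n_valid = np.isfinite(r).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(r, axis=0)
        sd = np.nanstd(r, axis=0, ddof=1)
    denom = np.maximum(np.abs(mean), CV_MEAN_FLOOR)
    cv = sd / denom
    missing = np.flatnonzero(n_valid < 2)
    cv[missing] = np.nan
    floor = np.flatnonzero((np.abs(mean) < CV_MEAN_FLOOR) & (n_valid >= 2))
    return EdgeVector(
        cv,
        kind="dynamic-cv",
        subject_id=ts.subject_id,
        missing_edges=missing,
        floor_edges=floor,
    )


def cohort_feature_matrix(series, edge_map, kind="static-z", spec=None, use_fisher_z=False):
    """Stack per-subject edge vectors into a (subjects x edges) matrix.

    Returns (subject_ids, matrix). ``kind`` selects static-z or dynamic-cv.
    """
    vectors = []
    ids = []
    for ts in series:
        if kind == "static-z":
            ev = static_fc(ts, edge_map)
        elif kind == "dynamic-cv":
            ev = dynamic_fc_cv(ts, edge_map, spec, use_fisher_z=use_fisher_z)
        else:
            raise ValueError(f"unknown feature kind {kind!r}")
        vectors.append(ev.values)
        ids.append(ts.subject_id)
    return ids, np.vstack(vectors)
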