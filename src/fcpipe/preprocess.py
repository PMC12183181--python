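"""ROI time-series cleaning: volume discard, detrend, nuisance regression,
band-pass, and motion-based subject exclusion.

The fixed stage order used by the pipeline is
drop_initial_volumes -> linear_detrend -> regress_nuisance -> bandpass_filter;
every stage except the volume discard preserves the T x R shape.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

from .core import RoiTimeSeries

#: Default number of initial volumes discarded for magnetization equilibration.
DEFAULT_DROP_VOLUMES = 10

#: Default band edges (Hz) of the resting-state fluctuation band.
DEFAULT_LOW_HZ = 0.01
DEFAULT_HIGH_HZ = 0.1

#: Default mean-FD exclusion threshold (mm); "larger than" read strictly, so a
#: subject at exactly the threshold is kept.
DEFAULT_FD_THRESHOLD = 0.2


def drop_initial_volumes(ts: RoiTimeSeries, n: int = DEFAULT_DROP_VOLUMES) -> RoiTimeSeries:
    """Discard the first ``n`` volumes (T -> T - n)."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    if ts.n_timepoints <= n:
        raise ValueError(
            f"cannot drop {n} volumes from a series of {ts.n_timepoints}"
        )
    return ts.with_data(ts.data[n:])


def linear_detrend(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Remove each column's least-squares line (slope and intercept)."""
    if ts.n_timepoints < 3:
        raise ValueError("detrending needs at least 3 timepoints")
    return ts.with_data(signal.detrend(ts.data, axis=0, type="linear"))


def bandpass_filter(
    ts: RoiTimeSeries,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
    order: int = 2,
) -> RoiTimeSeries:
    """Zero-phase Butterworth band-pass.

    Forward-backward (``sosfiltfilt``) application of a second-order
    Butterworth, the de facto resting-state standard: passband amplitudes are
    preserved, frequencies at twice the upper cutoff are attenuated by more
    than 90%, and no temporal shift is introduced.
    """
    nyquist = 0.5 / ts.tr_seconds
    if not (0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"high cutoff {high_hz} Hz must be below Nyquist {nyquist} Hz "
            f"(TR = {ts.tr_seconds}s)"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr_seconds, output="sos")
    return ts.with_data(signal.sosfiltfilt(sos, ts.data, axis=0))


def regress_nuisance(ts: RoiTimeSeries, regressors=None) -> RoiTimeSeries:
    """Residualize each ROI column on [intercept | regressors].

    ``regressors`` is a T x K matrix (e.g. Friston-24 motion expansion, white
    matter and CSF signals, already assembled by the caller). Constant
    regressor columns duplicate the intercept and are dropped with a warning;
    with no regressors the output is simply demeaned.
    """
    t = ts.n_timepoints
    if regressors is None or (hasattr(regressors, "shape") and np.size(regressors) == 0):
        x = np.ones((t, 1))
    else:
        regressors = np.atleast_2d(np.asarray(regressors, dtype=float))
        if regressors.shape[0] != t:
            if regressors.shape[1] == t:
                regressors = regressors.T
            else:
                raise ValueError(
                    f"regressor matrix has {regressors.shape[0]} rows, series has {t}"
                )
        constant = np.ptp(regressors, axis=0) == 0
        if constant.any():
            warnings.warn(
                f"dropping {int(constant.sum())} constant nuisance regressor(s) "
                "that duplicate the intercept",
                stacklevel=2,
            )
            regressors = regressors[:, ~constant]
        x = np.column_stack([np.ones(t), regressors])
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError("nuisance regressor matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(x, ts.data, rcond=None)
    return ts.with_data(ts.data - x @ beta)


def preprocess(
    ts: RoiTimeSeries,
    n_drop: int = DEFAULT_DROP_VOLUMES,
    regressors=None,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
) -> RoiTimeSeries:
    """Apply the full cleaning chain in the fixed documented order."""
    ts = drop_initial_volumes(ts, n_drop)
    ts = linear_detrend(ts)
    ts = regress_nuisance(ts, regressors)
    return bandpass_filter(ts, low_hz, high_hz)


def exclude_by_fd(records, threshold: float = DEFAULT_FD_THRESHOLD):
    """Partition records into (kept, excluded) by mean framewise displacement.

    Subjects with ``mean_fd`` strictly larger than the threshold are excluded;
    a subject exactly at the threshold is kept.
    """
    kept = [r for r in records if r.mean_fd <= threshold]
    excluded = [r for r in records if r.mean_fd > threshold]
    return kept, excluded
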