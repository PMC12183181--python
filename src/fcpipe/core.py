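"""Core containers shared across the pipeline: subject phenotypes and ROI time series."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Phenotype columns every cohort table must carry, in canonical order.
PHENOTYPE_COLUMNS = (
    "subject_id",
    "site",
    "group",
    "age",
    "sex",
    "education",
    "mean_fd",
    "hamd",
    "hama",
)

#: HAMA cut-off separating high-anxiety from low-anxiety depression.
HAMA_THRESHOLD = 14.0


@dataclass(frozen=True)
class SubjectRecord:
    """One participant's phenotype row.

    ``group`` is a free label; in the three-group depression design it is one of
    ``HAD`` (high-anxiety depression, HAMA > 14), ``LAD`` (low-anxiety
    depression, HAMA < 14) or ``HC`` (healthy control). ``mean_fd`` is the mean
    framewise displacement in millimetres, the scalar head-motion summary used
    for subject exclusion.
    """

    subject_id: str
    site: str
    group: str
    age: float
    sex: str
    education: float
    mean_fd: float
    hamd: float
    hama: float

    def __post_init__(self) -> None:
        if self.mean_fd < 0:
            raise ValueError(
                f"subject {self.subject_id}: mean_fd must be >= 0, got {self.mean_fd}"
            )

    def as_dict(self) -> dict:
        return {c: getattr(self, c) for c in PHENOTYPE_COLUMNS}


@dataclass
class RoiTimeSeries:
    """A T x R matrix of ROI-averaged BOLD signal for one subject.

    Rows are volumes sampled every ``tr_seconds``; columns are regions of
    interest. All preprocessing stages map RoiTimeSeries -> RoiTimeSeries and
    preserve the column count.
    """

    data: np.ndarray
    tr_seconds: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"time series must be 2-D, got shape {self.data.shape}")
        if self.data.shape[0] < 2 or self.data.shape[1] < 2:
            raise ValueError(
                f"time series needs T >= 2 and R >= 2, got {self.data.shape}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError(f"subject {self.subject_id!r}: non-finite values in series")
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "RoiTimeSeries":
        return replace(self, data=np.asarray(data, dtype=float))
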