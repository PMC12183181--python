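"""Reading and writing cohort files: ROI time series, phenotypes, feature matrices.

All on-disk formats are delimited text. Time series are one CSV per subject
(T rows x R columns, optional ``roi_*`` header); phenotypes are one CSV with
the canonical column set; cohort feature matrices are TSV (subjects x edges)
with a sidecar edge-map file listing ``flat_index, i, j``.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import EdgeIndexMap
from .core import PHENOTYPE_COLUMNS, RoiTimeSeries, SubjectRecord


class CohortIOError(ValueError):
    """Raised for malformed or inconsistent cohort files."""


def read_timeseries(path, tr_seconds, subject_id=None, expected_rois=None) -> RoiTimeSeries:
    """Load one subject's T x R series from delimited text.

    Non-numeric cells are rejected with the offending row and column; a
    header row of ``roi_*`` labels is detected and skipped.
    """
    path = Path(path)
    if subject_id is None:
        subject_id = path.stem
    try:
        df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    except Exception as exc:  # ragged rows, empty file, ...
        raise CohortIOError(f"{path}: could not parse delimited text ({exc})") from exc
    first = df.iloc[0].astype(str)
    if not first.str.fullmatch(r"[-+0-9.eE naN]+").all():
        df = df.iloc[1:].reset_index(drop=True)
    values = np.empty(df.shape, dtype=float)
    for c in range(df.shape[1]):
        col = pd.to_numeric(df.iloc[:, c], errors="coerce")
        bad = col.isna() & df.iloc[:, c].notna()
        if bad.any() or col.isna().any():
            row = int(np.flatnonzero(col.isna())[0])
            raise CohortIOError(
                f"{path}: non-numeric or missing value at row {row}, column {c}"
            )
        values[:, c] = col.to_numpy()
    if expected_rois is not None and values.shape[1] != expected_rois:
        raise CohortIOError(
            f"{path}: {values.shape[1]} ROI columns, cohort expects {expected_rois}"
        )
    return RoiTimeSeries(values, tr_seconds=tr_seconds, subject_id=subject_id)


def write_timeseries(path, ts: RoiTimeSeries) -> None:
    header = ",".join(f"roi_{i}" for i in range(ts.n_rois))
    np.savetxt(path, ts.data, delimiter=",", header=header, comments="", fmt="%.8g")


def read_phenotypes(path):
    """Load the phenotype CSV into a list of SubjectRecord (file order)."""
    df = pd.read_csv(path)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise CohortIOError(f"{path}: phenotype table missing columns {missing}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise CohortIOError(f"{path}: duplicate subject ids {dupes}")
    records = []
    for _, row in df.iterrows():
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]), site=str(row["site"]),
                group=str(row["group"]), age=float(row["age"]), sex=str(row["sex"]),
                education=float(row["education"]), mean_fd=float(row["mean_fd"]),
                hamd=float(row["hamd"]), hama=float(row["hama"]),
            )
        )
    return records


def write_phenotypes(path, records) -> None:
    pd.DataFrame([r.as_dict() for r in records]).to_csv(path, index=False)


def records_frame(records) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in records])


def load_cohort(timeseries_paths, phenotype_path, tr_seconds):
    """Load an aligned cohort: (records, series), ordered as the phenotype file.

    ``timeseries_paths`` is either a directory containing ``<subject_id>.csv``
    files or a mapping from subject id to path. Every phenotype row must have
    a series file; all series must share one ROI count.
    """
    records = read_phenotypes(phenotype_path)
    if isinstance(timeseries_paths, (str, os.PathLike)):
        root = Path(timeseries_paths)
        paths = {r.subject_id: root / f"{r.subject_id}.csv" for r in records}
    else:
        paths = {str(k): Path(v) for k, v in timeseries_paths.items()}
    series = []
    n_rois = None
    for rec in records:
        p = paths.get(rec.subject_id)
        if p is None or not p.exists():
            raise CohortIOError(
                f"no time-series file for subject {rec.subject_id!r}"
                + (f" (expected {p})" if p is not None else "")
            )
        ts = read_timeseries(p, tr_seconds, subject_id=rec.subject_id, expected_rois=n_rois)
        n_rois = ts.n_rois
        series.append(ts)
    return records, series


def write_cohort(outdir, records, series) -> None:
    """Write one series CSV per subject plus the phenotype table."""
    outdir = Path(outdir)
    tsdir = outdir / "timeseries"
    tsdir.mkdir(parents=True, exist_ok=True)
    for rec, ts in zip(records, series):
        write_timeseries(tsdir / f"{rec.subject_id}.csv", ts)
    write_phenotypes(outdir / "phenotypes.csv", records)


def write_feature_matrix(path, subject_ids, features, edge_map: EdgeIndexMap) -> None:
    """Write a subjects x edges matrix as TSV plus a ``.edges.tsv`` sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        features,
        index=pd.Index(subject_ids, name="subject_id"),
        columns=[f"e{k}" for k in range(edge_map.n_edges)],
    )
    df.to_csv(path, sep="\t", float_format="%.10g")
    pairs = edge_map.pairs()
    side = pd.DataFrame(
        {"flat_index": np.arange(edge_map.n_edges), "i": pairs[:, 0], "j": pairs[:, 1]}
    )
    side.to_csv(path.with_suffix(path.suffix + ".edges.tsv"), sep="\t", index=False)


def read_feature_matrix(path):
    """Read a feature TSV: (subject_ids, matrix, edge_map)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="subject_id")
    side_path = path.with_suffix(path.suffix + ".edges.tsv")
    if side_path.exists():
        side = pd.read_csv(side_path, sep="\t")
        n_rois = int(side[["i", "j"]].to_numpy().max()) + 1
    else:
        # invert E = R(R-1)/2
        e = df.shape[1]
        n_rois = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
    emap = EdgeIndexMap(n_rois)
    if emap.n_edges != df.shape[1]:
        raise CohortIOError(f"{path}: {df.shape[1]} edges inconsistent with edge map")
    return list(df.index.astype(str)), df.to_numpy(dtype=float), emap
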