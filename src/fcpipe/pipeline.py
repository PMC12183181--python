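"""End-to-end orchestration: load -> preprocess -> connectivity -> harmonize ->
edgewise inference -> clinical association, from one config.

Outputs are delimited-text tables plus a plain-text run manifest (config,
seed, versions, exclusions, flagged edges), and the whole chain is
deterministic given config + inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import coupling_associations, edge_edge_correlation
from .combat import fit_combat
from .connectivity import EdgeIndexMap, SlidingWindowSpec, dynamic_fc_cv, static_fc
from .inference import EdgewiseGroupModel
from .io import load_cohort, records_frame, write_feature_matrix
from .preprocess import exclude_by_fd, preprocess

log = logging.getLogger("fcpipe")

#: Phenotype columns used as harmonization / clinical covariates by default.
DEFAULT_COVARIATES = ("age", "sex", "education", "mean_fd")


@dataclass
class PipelineConfig:
    """All pipeline settings; defaults reproduce the study protocol:

    drop 10 volumes, band 0.01-0.1 Hz, mean-FD exclusion at 0.2 mm, 100 s
    windows sliding by 2 s, FDR q < 0.05, post-hoc alpha 0.05, covariates
    age/sex/education/mean FD.
    """

    timeseries_dir: str = ""
    phenotype_path: str = ""
    output_dir: str = "fcpipe_out"
    tr_seconds: float = 2.0
    drop_volumes: int = 10
    low_hz: float = 0.01
    high_hz: float = 0.1
    fd_threshold: float = 0.2
    window_seconds: float = 100.0
    step_seconds: float = 2.0
    cv_on_z: bool = False
    harmonize: bool = True
    covariates: tuple = DEFAULT_COVARIATES
    fdr_q: float = 0.05
    posthoc_alpha: float = 0.05
    clinical_covariates: tuple = DEFAULT_COVARIATES
    max_edge_pairs: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("covariates", "clinical_covariates"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["covariates"] = list(self.covariates)
        d["clinical_covariates"] = list(self.clinical_covariates)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _covariate_matrix(pheno: pd.DataFrame, columns) -> np.ndarray | None:
    cols = []
    for c in columns:
        v = pheno[c]
        if v.dtype == object:
            v = (v == sorted(v.unique())[0]).astype(float)
        cols.append(v.to_numpy(dtype=float))
    return np.column_stack(cols) if cols else None


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig, records=None, series=None) -> dict:
    """Run the full analysis; returns a dict of output paths and key results.

    ``records`` / ``series`` may be passed directly (e.g. from the synthetic
    generator); otherwise they are loaded from the configured paths.
    """
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.as_dict(),
        "config_digest": config.digest(),
        "fcpipe_version": __version__,
        "stages": {},
    }

    if records is None or series is None:
        log.info("loading cohort from %s", config.timeseries_dir)
        records, series = load_cohort(
            config.timeseries_dir, config.phenotype_path, config.tr_seconds
        )
    manifest["n_subjects_loaded"] = len(records)

    # --- subject exclusion -------------------------------------------------
    kept, excluded = exclude_by_fd(records, config.fd_threshold)
    keep_ids = {r.subject_id for r in kept}
    series = [ts for ts in series if ts.subject_id in keep_ids]
    manifest["excluded_subjects"] = [
        {"subject_id": r.subject_id, "reason": f"mean_fd {r.mean_fd} > {config.fd_threshold}"}
        for r in excluded
    ]
    log.info("excluded %d/%d subjects by mean FD", len(excluded), len(records))
    records = kept
    pheno = records_frame(records)
    groups = pheno["group"].to_numpy()
    if min((groups == g).sum() for g in pd.unique(groups)) < 2:
        raise ValueError("a group has fewer than 2 subjects after FD exclusion")

    # --- preprocessing -----------------------------------------------------
    t = time.time()
    clean = [
        preprocess(ts, config.drop_volumes, None, config.low_hz, config.high_hz)
        for ts in series
    ]
    manifest["stages"]["preprocess"] = {"seconds": round(time.time() - t, 2)}

    # --- connectivity ------------------------------------------------------
    t = time.time()
    emap = EdgeIndexMap(clean[0].n_rois)
    spec = SlidingWindowSpec(config.window_seconds, config.step_seconds)
    static = np.vstack([static_fc(ts, emap).values for ts in clean])
    dyn_vectors = [dynamic_fc_cv(ts, emap, spec, config.cv_on_z) for ts in clean]
    dynamic = np.vstack([ev.values for ev in dyn_vectors])
    flagged = sorted({int(e) for ev in dyn_vectors for e in ev.floor_edges})
    manifest["stages"]["connectivity"] = {
        "seconds": round(time.time() - t, 2),
        "n_edges": emap.n_edges,
        "cv_floor_edges": flagged[:200],
    }
    ids = [ts.subject_id for ts in clean]
    write_feature_matrix(outdir / "static_fc.tsv", ids, static, emap)
    write_feature_matrix(outdir / "dynamic_fc.tsv", ids, dynamic, emap)

    # --- harmonization (per feature kind, separately) ----------------------
    features = {"static": static, "dynamic": dynamic}
    if config.harmonize:
        t = time.time()
        cov = _covariate_matrix(pheno, config.covariates)
        sites = pheno["site"].to_numpy()
        for kind in features:
            res = fit_combat(features[kind], sites, cov)
            features[kind] = res.transform()
            res.to_json(outdir / f"combat_{kind}.json")
        manifest["stages"]["harmonize"] = {"seconds": round(time.time() - t, 2)}
        write_feature_matrix(outdir / "static_fc_harmonized.tsv", ids, features["static"], emap)
        write_feature_matrix(outdir / "dynamic_fc_harmonized.tsv", ids, features["dynamic"], emap)

    # --- edgewise inference (separate FDR family per kind) ------------------
    results = {}
    sig_counts = {}
    for kind, mat in features.items():
        t = time.time()
        res = EdgewiseGroupModel(mat, groups, emap, kind=kind).fit(
            config.fdr_q, config.posthoc_alpha
        )
        results[kind] = res
        _write_tsv(res.to_frame(), outdir / f"edgewise_{kind}.tsv")
        sig = res.significant_edges
        sig_counts[kind] = int(sig.size)
        manifest["stages"][f"inference_{kind}"] = {
            "seconds": round(time.time() - t, 2),
            "n_significant": int(sig.size),
        }
        # group-mean bar data for the significant edges
        if sig.size:
            bars = []
            for e in sig:
                for g in pd.unique(groups):
                    bars.append(
                        {
                            "edge": int(e), "group": g,
                            "mean": res.group_means[g][e],
                            "sem": res.group_sems[g][e],
                        }
                    )
            _write_tsv(pd.DataFrame(bars), outdir / f"group_means_{kind}.tsv")

    # --- clinical association ----------------------------------------------
    assoc_frames = []
    for kind, res in results.items():
        sig = res.significant_edges
        if not sig.size:
            continue
        ca = coupling_associations(
            features[kind], records, sig, config.clinical_covariates
        )
        ca.insert(0, "kind", kind)
        assoc_frames.append(ca)
        top = sig[: config.max_edge_pairs]
        for a_i in range(len(top)):
            for b_i in range(a_i + 1, len(top)):
                ee = edge_edge_correlation(features[kind], int(top[a_i]), int(top[b_i]), groups)
                ee.insert(0, "kind", kind)
                ee.insert(1, "edge_a", int(top[a_i]))
                ee.insert(2, "edge_b", int(top[b_i]))
                assoc_frames.append(ee)
    assoc = (
        pd.concat(assoc_frames, ignore_index=True)
        if assoc_frames
        else pd.DataFrame(columns=["kind", "group", "edge", "r", "p", "n"])
    )
    _write_tsv(assoc, outdir / "clinical_associations.tsv")

    manifest["significant_edges"] = sig_counts
    manifest["total_seconds"] = round(time.time() - t0, 2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    log.info("pipeline finished in %.1fs; outputs in %s", time.time() - t0, outdir)
    return {
        "output_dir": str(outdir),
        "manifest": manifest,
        "results": results,
        "features": features,
        "edge_map": emap,
        "records": records,
    }
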