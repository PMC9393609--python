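"""End-to-end study orchestration: simulate -> fit -> ALPS -> statistics.

A :class:`StudyConfig` fixes every degree of freedom of a run (cohort
sizes, glymphatic coefficient distributions, phantom, acquisition, noise,
seed, analysis options); :func:`run_study` executes the full chain and
emits the study's result tables:

* a per-subject table with the nine fiber-axis diffusivities and the ALPS
  index,
* a two-group diffusivity comparison table (patients vs controls) with
  Bonferroni-corrected flags,
* subgroup comparison tables within the patient group by diabetes and by
  hypertension status,
* a correlation table of the ALPS index against clinical covariates within
  the patient group,
* a manifest recording the seed, config hash and package versions.

:func:`audit_printed_tables` recomputes pooled t-tests from a published
table's printed (mean, SD, n) cells, for checking reported p-values when
raw data are unavailable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as apio
from .alps import FiberROISet, alps_from_maps
from .schemes import default_scheme
from .stats import (
    build_comparison_table,
    comparison_rows_to_frame,
    pearson_correlation,
    summary_table,
)
from .synthcohort import (
    CohortSubject,
    DiffusivityProfile,
    PhantomGeometry,
    cohort_covariates,
    generate_cohort,
)
from .tensorfit import axis_diffusivities, fit_tensor_lls

__all__ = [
    "StudyConfig",
    "StudyResults",
    "PipelineError",
    "run_study",
    "analyze_subjects",
    "stats_tables",
    "subject_alps",
    "simulate_group_alps",
    "audit_printed_tables",
    "DIFFUSIVITY_MEASURES",
    "CORRELATION_COVARIATES",
]

logger = logging.getLogger("alpspipe")

DIFFUSIVITY_MEASURES = [
    f"{axis}_{fiber}"
    for fiber in ("projection", "association", "subcortical")
    for axis in ("Dxx", "Dyy", "Dzz")
]
ALL_MEASURES = DIFFUSIVITY_MEASURES + ["alps_index"]

CORRELATION_COVARIATES = [
    "age", "ckd_stage_ordinal", "hemoglobin", "hematocrit", "egfr",
    "albumin", "protein", "ast", "alt", "bun", "creatinine", "sodium",
    "potassium", "chloride", "calcium", "phosphate", "total_co2",
]
STAGE_ORDINAL = {"3a": 1, "3b": 2, "4": 3}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class StudyConfig:
    """All parameters of one synthetic ALPS study run."""

    n_ckd: int = 18
    n_ctrl: int = 18
    g_ckd: tuple[float, float] = (0.3, 0.1)
    g_ctrl: tuple[float, float] = (0.7, 0.1)
    noise_sigma: float = 20.0
    s0: float = 1000.0
    noise_model: str = "rician"
    seed: int = 0
    alpha: float = 0.05
    n_bonferroni: int = 9
    welch: bool = False      # Welch instead of pooled t in the tables
    wls_fit: bool = False    # iteratively reweighted tensor fit
    correlation_method: str = "pearson"
    correlate_patients_only: bool = True
    geometry: PhantomGeometry = field(default_factory=PhantomGeometry)
    profile: DiffusivityProfile = field(default_factory=DiffusivityProfile)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "geometry" in kwargs:
            geo = dict(kwargs["geometry"])
            if "shape" in geo:
                geo["shape"] = tuple(geo["shape"])
            if "boxes" in geo:
                geo["boxes"] = {
                    k: tuple(tuple(r) for r in v) for k, v in geo["boxes"].items()
                }
            kwargs["geometry"] = PhantomGeometry(**geo)
        if "profile" in kwargs:
            kwargs["profile"] = DiffusivityProfile(**kwargs["profile"])
        for key in ("g_ckd", "g_ctrl"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["geometry"]["boxes"] = {
            k: [list(r) for r in v] for k, v in d["geometry"]["boxes"].items()
        }
        d["geometry"]["shape"] = list(d["geometry"]["shape"])
        d["g_ckd"] = list(d["g_ckd"])
        d["g_ctrl"] = list(d["g_ctrl"])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class StudyResults:
    per_subject: pd.DataFrame
    table_diffusivities: pd.DataFrame
    table_dm: pd.DataFrame
    table_htn: pd.DataFrame
    correlations: pd.DataFrame
    manifest: dict

    FILES = {
        "per_subject": "alps_per_subject.csv",
        "table_diffusivities": "table2_diffusivities.csv",
        "table_dm": "table3_dm.csv",
        "table_htn": "table3_htn.csv",
        "correlations": "correlations.csv",
    }

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for attr, fname in self.FILES.items():
            getattr(self, attr).to_csv(out_dir / fname, index=False)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def subject_alps(dwi, roi_labels, weighted: bool = False):
    """Fit tensors, extract axis maps, and compute one subject's ALPS.

    Returns ``(fiber_axis_diffusivities, alps_index_value)``.
    """
    field_ = fit_tensor_lls(dwi, weighted=weighted)
    maps = axis_diffusivities(field_)
    rois = FiberROISet.from_labels(roi_labels)
    fad, idx = alps_from_maps(maps, rois)
    return fad, idx.value


def analyze_subjects(
    subjects: list[CohortSubject], weighted: bool = False
) -> pd.DataFrame:
    """Per-subject table: covariates + nine diffusivity cells + ALPS index."""
    cov = cohort_covariates(subjects)
    rows = []
    for s in subjects:
        fad, value = subject_alps(s.dwi, s.roi_labels, weighted=weighted)
        row = {"subject_id": s.record.subject_id}
        row.update(fad.flat())
        row["alps_index"] = value
        rows.append(row)
    return cov.merge(pd.DataFrame(rows), on="subject_id", validate="1:1")


def stats_tables(
    per_subject: pd.DataFrame,
    alpha: float = 0.05,
    n_bonferroni: int = 9,
    correlation_method: str = "pearson",
    correlate_patients_only: bool = True,
    welch: bool = False,
) -> dict[str, pd.DataFrame]:
    """All group-comparison and correlation tables from the subject table.

    Subgroup (diabetes, hypertension) comparisons and the correlation
    analysis are restricted to the patient group.
    """
    def compare(df, group_col, groups):
        rows = build_comparison_table(
            df, ALL_MEASURES, group_col=group_col, groups=groups,
            alpha=alpha, m=n_bonferroni, welch=welch,
        )
        return comparison_rows_to_frame(rows)

    main = compare(per_subject, "group", ("early_ckd", "control"))

    patients = per_subject[per_subject["group"] == "early_ckd"].copy()
    patients["dm_label"] = np.where(patients["dm"], "dm", "no_dm")
    patients["htn_label"] = np.where(patients["htn"], "htn", "no_htn")
    table_dm = compare(patients, "dm_label", ("dm", "no_dm"))
    table_htn = compare(patients, "htn_label", ("htn", "no_htn"))

    corr_df = patients if correlate_patients_only else per_subject.copy()
    corr_df = corr_df.copy()
    corr_df["ckd_stage_ordinal"] = corr_df["ckd_stage"].map(STAGE_ORDINAL)
    corr_rows = []
    for cov in CORRELATION_COVARIATES:
        if cov not in corr_df.columns:
            continue
        sub = corr_df[["alps_index", cov]].dropna()
        if (len(sub) < 3 or np.ptp(sub[cov].to_numpy()) == 0
                or np.ptp(sub["alps_index"].to_numpy()) == 0):
            corr_rows.append({"covariate": cov, "r": np.nan, "p": np.nan,
                              "n": len(sub)})
            continue
        res = pearson_correlation(
            sub[cov], sub["alps_index"], method=correlation_method
        )
        corr_rows.append({"covariate": cov, "r": res.r, "p": res.p, "n": res.n})

    return {
        "table_diffusivities": main,
        "table_dm": table_dm,
        "table_htn": table_htn,
        "correlations": pd.DataFrame(corr_rows),
    }


def _stage(name: str):
    class _StageTimer:
        def __init__(self) -> None:
            self.elapsed = 0.0

        def __enter__(self):
            self._t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            self.elapsed = time.perf_counter() - self._t0
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s finished in %.2f s", name, self.elapsed)

    return _StageTimer()


def run_study(
    config: StudyConfig,
    out_dir: str | Path | None = None,
    write_volumes: bool = True,
) -> StudyResults:
    """Execute the full study defined by ``config``.

    With ``out_dir`` set, result CSVs and a manifest are written there and
    (if ``write_volumes``) each subject's DWI, gradient table and ROI
    labels are retained under ``out_dir/work/``.  Identical config + seed
    gives byte-identical outputs; on error, partial outputs are removed.
    """
    logger.info("run_study seed=%d config_hash=%s", config.seed,
                config.config_hash())
    timings: dict[str, float] = {}

    with _stage("simulate") as t:
        subjects = generate_cohort(
            n_ckd=config.n_ckd, n_ctrl=config.n_ctrl,
            g_ckd=config.g_ckd, g_ctrl=config.g_ctrl,
            profile=config.profile, geometry=config.geometry,
            noise_sigma=config.noise_sigma, s0=config.s0,
            seed=config.seed, noise_model=config.noise_model,
        )
    timings["simulate"] = t.elapsed

    with _stage("fit+alps") as t:
        per_subject = analyze_subjects(subjects, weighted=config.wls_fit)
    timings["fit+alps"] = t.elapsed

    with _stage("stats") as t:
        tables = stats_tables(
            per_subject,
            alpha=config.alpha,
            n_bonferroni=config.n_bonferroni,
            correlation_method=config.correlation_method,
            correlate_patients_only=config.correlate_patients_only,
            welch=config.welch,
        )
    timings["stats"] = t.elapsed

    import alpspipe

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "subject_ids": per_subject["subject_id"].tolist(),
        "versions": {
            "alpspipe": getattr(alpspipe, "__version__", "unknown"),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stage_seconds": timings,
    }
    results = StudyResults(per_subject=per_subject, manifest=manifest, **tables)

    if out_dir is not None:
        out_dir = Path(out_dir)
        created = not out_dir.exists()
        try:
            with _stage("write") as t:
                results.write(out_dir)
                if write_volumes:
                    work = out_dir / "work"
                    for s in subjects:
                        sid = s.record.subject_id
                        apio.save_dwi(s.dwi, work / sid, prefix="dwi")
                        apio.save_roi_labels(
                            s.roi_labels, work / sid / "roi.nii.gz",
                            config.geometry.voxel_size_mm,
                        )
        except PipelineError:
            if created and out_dir.exists():
                shutil.rmtree(out_dir)
            raise
    return results


def simulate_group_alps(
    seed: int,
    n_ckd: int = 18,
    n_ctrl: int = 18,
    g_ckd: tuple[float, float] = (0.3, 0.1),
    g_ctrl: tuple[float, float] = (0.7, 0.1),
    noise_sigma: float = 20.0,
    s0: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fast in-memory replicate: per-group arrays of subject ALPS indices.

    Used for Monte-Carlo calibration checks (group separation, type-I
    error) without touching the filesystem.
    """
    subjects = generate_cohort(
        n_ckd=n_ckd, n_ctrl=n_ctrl, g_ckd=g_ckd, g_ctrl=g_ctrl,
        noise_sigma=noise_sigma, s0=s0, seed=seed,
    )
    values = {"early_ckd": [], "control": []}
    for s in subjects:
        _, v = subject_alps(s.dwi, s.roi_labels)
        values[s.record.group].append(v)
    return np.asarray(values["early_ckd"]), np.asarray(values["control"])


def audit_printed_tables(summaries: pd.DataFrame) -> pd.DataFrame:
    """Recompute pooled t-tests from a table's printed summary cells.

    Input columns: measure, mean1, sd1, n1, mean2, sd2, n2, optionally
    p_printed.  Output adds the recomputed t, df, p (and, where a printed
    p is given, the absolute difference |p - p_printed|).  Malformed rows
    are reported together by row number.
    """
    required = ["measure", "mean1", "sd1", "n1", "mean2", "sd2", "n2"]
    missing_cols = [c for c in required if c not in summaries.columns]
    if missing_cols:
        raise ValueError(f"summary table missing columns {missing_cols}")
    bad_rows = [
        int(i) for i, row in summaries.iterrows()
        if row[required[1:]].isna().any()
        or row["n1"] < 2 or row["n2"] < 2 or row["sd1"] < 0 or row["sd2"] < 0
    ]
    if bad_rows:
        raise ValueError(f"malformed summary rows: {bad_rows}")
    out = summary_table(summaries[required])
    if "p_printed" in summaries.columns:
        out["p_printed"] = summaries["p_printed"].to_numpy()
        out["abs_diff"] = (out["p"] - out["p_printed"]).abs()
    return out
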