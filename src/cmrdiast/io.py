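"""File formats and the cohort analysis pipeline.

Formats (all plain text):

* curve CSV: ``time_ms,volume_ml`` (header required), one file per
  subject per cycle; the R-R interval is given on the command line or, by
  convention, as a ``# rr_ms=`` comment on the first line.
* track CSV: ``time_ms,distance_mm,site`` or 3-D guide points
  ``time_ms,x_mm,y_mm,z_mm,label`` with labels apex/septal/lateral.
* subject table CSV: one row per subject, columns named after the
  record fields (``echo_E``, ``cmr_DT``, ...); missing values empty.
* mask stacks: a directory of per-frame/per-slice ``.npy`` arrays named
  ``frame<i>_slice<j>.npy`` plus ``geometry.json`` holding
  ``pixel_area_mm2``, ``slice_thickness_mm``, ``slice_gap_mm``, ``rr_ms``.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .annulus_kinematics import AnnulusTrack, apex_annulus_distance_series
from .config import AnalysisConfig
from .echo_grading import (
    DysfunctionGrade,
    EchoDiastolicMeasures,
    SubjectRecord,
    ase_criteria,
    grade_diastolic_function,
    heart_rate_compatible,
    lv_hypertrophy,
)
from .errors import DegenerateLabelsError, StructuralInputError, UndefinedStatisticError
from .validation_stats import (
    anova_oneway,
    bland_altman,
    fisher_exact_rxc,
    paired_mean_comparison,
    pearson_linear,
    roc_auc_with_band,
)
from .volume_curves import MaskStack, VolumeCurve

__all__ = [
    "read_curve_csv", "write_curve_csv",
    "read_track_csv", "write_track_csv", "read_guide_points_csv",
    "load_mask_stack",
    "read_subject_table", "write_subject_table",
    "run_pipeline",
]


# ------------------------------------------------------------ curve CSV


def write_curve_csv(path, curve: VolumeCurve) -> None:
    with open(path, "w") as fh:
        fh.write(f"# rr_ms={curve.rr_interval:.10g}\n")
        fh.write("time_ms,volume_ml\n")
        for t, v in zip(curve.times, curve.volumes):
            fh.write(f"{t:.10g},{v:.10g}\n")


def read_curve_csv(path, rr_interval: Optional[float] = None) -> VolumeCurve:
    rr = rr_interval
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "rr_ms=" in first:
                rr = float(first.split("rr_ms=")[1])
            header = fh.readline()
        else:
            header = first
        cols = [c.strip() for c in header.strip().split(",")]
        if cols[:2] != ["time_ms", "volume_ml"]:
            raise StructuralInputError(
                f"curve CSV must have header 'time_ms,volume_ml', got {header!r}"
            )
        df = pd.read_csv(fh, names=cols)
    if rr is None:
        raise StructuralInputError("R-R interval not given and not in the file")
    return VolumeCurve(df["time_ms"].to_numpy(), df["volume_ml"].to_numpy(), rr)


# ------------------------------------------------------------ track CSV


def write_track_csv(path, track: AnnulusTrack) -> None:
    with open(path, "w") as fh:
        fh.write(f"# rr_ms={track.rr_interval:.10g}\n")
        fh.write("time_ms,distance_mm,site\n")
        for t, d in zip(track.times, track.distances):
            fh.write(f"{t:.10g},{d:.10g},{track.site}\n")


def read_track_csv(path, rr_interval: float = 0.0) -> AnnulusTrack:
    rr = rr_interval
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "rr_ms=" in first:
                rr = float(first.split("rr_ms=")[1])
            first = fh.readline()
        cols = [c.strip() for c in first.strip().split(",")]
        df = pd.read_csv(fh, names=cols)
    if cols[:3] != ["time_ms", "distance_mm", "site"]:
        raise StructuralInputError(
            "track CSV must have header 'time_ms,distance_mm,site'"
        )
    sites = df["site"].unique()
    if len(sites) != 1:
        raise StructuralInputError("track CSV must contain a single site")
    return AnnulusTrack(
        df["time_ms"].to_numpy(), df["distance_mm"].to_numpy(), str(sites[0]), rr
    )


def read_guide_points_csv(path, rr_interval: float = 0.0) -> dict:
    """3-D guide-point CSV → {'septal': AnnulusTrack, 'lateral': AnnulusTrack}.

    Columns ``time_ms,x_mm,y_mm,z_mm,label`` with labels apex / septal /
    lateral; the apex trajectory is paired frame-by-frame with each
    annulus site.
    """
    df = pd.read_csv(path)
    required = {"time_ms", "x_mm", "y_mm", "z_mm", "label"}
    if not required.issubset(df.columns):
        raise StructuralInputError(f"guide-point CSV needs columns {sorted(required)}")
    out = {}
    apex = df[df["label"] == "apex"].sort_values("time_ms")
    if apex.empty:
        raise StructuralInputError("guide-point CSV has no apex trajectory")
    apex_xyz = apex[["x_mm", "y_mm", "z_mm"]].to_numpy()
    for site in ("septal", "lateral"):
        pts = df[df["label"] == site].sort_values("time_ms")
        if pts.empty:
            continue
        out[site] = apex_annulus_distance_series(
            pts["time_ms"].to_numpy(), apex_xyz,
            pts[["x_mm", "y_mm", "z_mm"]].to_numpy(), site, rr_interval,
        )
    return out


# ----------------------------------------------------------- mask stack


def load_mask_stack(directory) -> MaskStack:
    directory = Path(directory)
    geom_path = directory / "geometry.json"
    if not geom_path.exists():
        raise StructuralInputError(f"missing {geom_path}")
    geom = json.loads(geom_path.read_text())
    files = sorted(directory.glob("frame*_slice*.npy"))
    if not files:
        raise StructuralInputError(f"no frame*_slice*.npy files in {directory}")
    frames: dict[int, dict[int, np.ndarray]] = {}
    for f in files:
        stem = f.stem  # frame<i>_slice<j>
        fi = int(stem.split("_")[0].removeprefix("frame"))
        si = int(stem.split("_")[1].removeprefix("slice"))
        frames.setdefault(fi, {})[si] = np.load(f)
    masks = [
        [frames[fi][si] for si in sorted(frames[fi])] for fi in sorted(frames)
    ]
    return MaskStack(
        masks=masks,
        pixel_area_mm2=geom["pixel_area_mm2"],
        slice_thickness_mm=geom["slice_thickness_mm"],
        slice_gap_mm=geom["slice_gap_mm"],
        rr_interval=geom["rr_ms"],
    )


# -------------------------------------------------------- subject table

_ECHO_COLS = {
    "echo_E": "E", "echo_A": "A", "echo_DT": "DT",
    "echo_eprime_septal": "e_prime_septal",
    "echo_eprime_lateral": "e_prime_lateral",
    "echo_eprime_mean": "e_prime_mean",
    "echo_E_over_e_septal": "E_over_e_septal",
    "echo_E_over_e_lateral": "E_over_e_lateral",
    "echo_E_over_e_mean": "E_over_e_mean",
    "echo_TPE": "relative_TPE", "echo_RTPA": "relative_TPA",
    "echo_rr": "rr_interval",
}


def _get(row, col):
    v = row.get(col)
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return v


def read_subject_table(path) -> tuple[list[SubjectRecord], list[dict]]:
    """Read a subject CSV; returns (records, row_issues).

    Rows violating the ≤15 bpm heart-rate comparability rule are kept but
    flagged in ``row_issues`` (exclusion is a report, never a silent
    drop); structurally broken rows are collected there too.
    """
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise StructuralInputError("subject table needs an 'id' column")
    records, issues = [], []
    for _, raw in df.iterrows():
        row = raw.to_dict()
        try:
            echo_kwargs = {
                field: _get(row, col) for col, field in _ECHO_COLS.items()
            }
            echo = EchoDiastolicMeasures(**echo_kwargs)
            cmr = {
                col.removeprefix("cmr_"): _get(row, col)
                for col in df.columns if col.startswith("cmr_")
            }
            grade_val = _get(row, "grade")
            rec = SubjectRecord(
                id=str(row["id"]), echo=echo, cmr=cmr or None,
                age=_get(row, "age"), sex=_get(row, "sex"),
                lvmi=_get(row, "lvmi"),
                heart_rate_echo=_get(row, "heart_rate_echo"),
                heart_rate_cmr=_get(row, "heart_rate_cmr"),
                grade=DysfunctionGrade(grade_val) if grade_val else None,
                covariates={
                    k: _get(row, k)
                    for k in ("race", "hypertension", "diabetes", "lvh",
                              "lv_mass", "bsa")
                    if k in df.columns
                },
            )
        except Exception as exc:  # row-level problems are collected, not fatal
            issues.append({"id": str(row.get("id")), "error": str(exc)})
            continue
        if not heart_rate_compatible(rec):
            issues.append({
                "id": rec.id,
                "error": "heart-rate difference between modalities exceeds 15 bpm",
                "excluded": True,
            })
        records.append(rec)
    return records, issues


def write_subject_table(path, records: list[SubjectRecord]) -> None:
    from .synthetic_cohort import cohort_to_dataframe

    cohort_to_dataframe(records).to_csv(path, index=False)


# -------------------------------------------------------------- report


_ROC_DIRECTIONS = {
    "E": "higher", "NE": "higher", "DT": "higher", "A": "higher",
    "NA": "higher", "DVR": "higher", "EA_ratio": "higher",
    "Eprime_septal": "lower", "Eprime_lateral": "lower", "Eprime_mean": "lower",
    "E_over_Eprime_septal": "higher", "E_over_Eprime_lateral": "higher",
    "E_over_Eprime_mean": "higher",
}

_ASSOCIATION_PAIRS = [
    ("echo_E", "E"), ("echo_E", "NE"), ("echo_A", "A"), ("echo_A", "NA"),
    ("echo_EA", "EA_ratio"),
    ("echo_eprime_septal", "Eprime_septal"),
    ("echo_eprime_lateral", "Eprime_lateral"),
    ("echo_eprime_mean", "Eprime_mean"),
    ("echo_E_over_e_septal", "E_over_Eprime_septal"),
    ("echo_E_over_e_lateral", "E_over_Eprime_lateral"),
    ("echo_E_over_e_mean", "E_over_Eprime_mean"),
]


def _cmr_value(rec: SubjectRecord, key: str):
    if rec.cmr is None:
        return None
    if isinstance(rec.cmr, dict):
        return rec.cmr.get(key)
    return getattr(rec.cmr, key, None)


def _echo_value(rec: SubjectRecord, col: str):
    e = rec.echo
    if e is None:
        return None
    if col == "echo_EA":
        return (e.E / e.A) if (e.E and e.A) else None
    if col == "echo_eprime_mean":
        return e.e_prime_mean
    if col == "echo_E_over_e_mean":
        return e.mean_ratio()
    return getattr(e, _ECHO_COLS.get(col, ""), None)


def run_pipeline(
    config: AnalysisConfig, records: list[SubjectRecord]
) -> dict:
    """Grade every subject from echo and compute the full cohort report.

    Returns a JSON-serializable dict: exclusions, grade counts,
    per-grade descriptives with omnibus ANOVA / Fisher p-values,
    echo-vs-CMR Pearson associations, normal-vs-reduced ROC for every CMR
    index, Bland–Altman for the same-unit E/A ratio, and paired
    comparisons of the diastolic time intervals.  Stage failures are
    reported in-place, never raised, so a degenerate cohort still yields
    a partial report.
    """
    cfg = config
    report: dict = {
        "software_version": _pkg_version,
        "config_hash": cfg.config_hash(),
        "n_input": len(records),
    }

    kept, excluded = [], []
    for rec in records:
        if heart_rate_compatible(rec):
            kept.append(rec)
        else:
            excluded.append(rec.id)
    report["excluded_heart_rate"] = excluded
    report["n_analyzed"] = len(kept)

    # --- grading (echo reference standard)
    grades: dict[str, DysfunctionGrade] = {}
    grading_issues = []
    for rec in kept:
        try:
            lvh = bool(rec.covariates.get("lvh")) if rec.covariates.get("lvh") is not None \
                else (lv_hypertrophy(rec.lvmi, rec.sex, cfg.thresholds)
                      if rec.lvmi and rec.sex else False)
            crit = ase_criteria(rec.echo, lvh, cfg.thresholds, cfg.echo_ratio_mode)
            grades[rec.id] = grade_diastolic_function(crit)
        except Exception as exc:
            if rec.grade is not None:
                grades[rec.id] = rec.grade
            else:
                grading_issues.append({"id": rec.id, "error": str(exc)})
    report["grading_issues"] = grading_issues
    counts = {g.value: 0 for g in DysfunctionGrade}
    for g in grades.values():
        counts[g.value] += 1
    report["grade_counts"] = counts

    by_grade = {g: [r for r in kept if grades.get(r.id) == g] for g in DysfunctionGrade}

    # --- grade-conditional descriptives with omnibus tests
    def groups_of(getter):
        out = []
        for g in DysfunctionGrade:
            vals = [getter(r) for r in by_grade[g]]
            out.append(np.array([v for v in vals if v is not None], float))
        return out

    measures = {}
    continuous = (
        [("age", lambda r: r.age), ("lvmi", lambda r: r.lvmi),
         ("heart_rate_echo", lambda r: r.heart_rate_echo),
         ("heart_rate_cmr", lambda r: r.heart_rate_cmr)]
        + [(col, (lambda c: lambda r: _echo_value(r, c))(col))
           for col, _ in _ASSOCIATION_PAIRS[:5] if col.startswith("echo")]
        + [("echo_DT", lambda r: _echo_value(r, "echo_DT")),
           ("echo_eprime_septal", lambda r: _echo_value(r, "echo_eprime_septal")),
           ("echo_eprime_lateral", lambda r: _echo_value(r, "echo_eprime_lateral"))]
        + [(f"cmr_{k}", (lambda kk: lambda r: _cmr_value(r, kk))(k))
           for k in ("E", "NE", "DT", "A", "NA", "EA_ratio", "DVR",
                     "Eprime_septal", "Eprime_lateral",
                     "E_over_Eprime_septal", "E_over_Eprime_lateral")]
    )
    for name, getter in continuous:
        gs = groups_of(getter)
        entry = {
            "per_grade": [
                {"n": int(a.size), "mean": float(a.mean()) if a.size else None,
                 "sd": float(a.std(ddof=1)) if a.size > 1 else None}
                for a in gs
            ]
        }
        try:
            if all(a.size >= 2 for a in gs):
                F, p = anova_oneway(gs)
                entry["anova_F"], entry["anova_p"] = F, p
            else:
                entry["anova_p"] = None
        except UndefinedStatisticError as exc:
            entry["anova_error"] = str(exc)
        measures[name] = entry
    report["measures_by_grade"] = measures

    categorical = {}
    for name, getter in [
        ("sex_male", lambda r: r.sex == "male" if r.sex else None),
        ("race_black", lambda r: r.covariates.get("race") == "black"
         if r.covariates.get("race") is not None else None),
        ("hypertension", lambda r: r.covariates.get("hypertension")),
        ("diabetes", lambda r: r.covariates.get("diabetes")),
    ]:
        table = []
        for g in DysfunctionGrade:
            vals = [getter(r) for r in by_grade[g]]
            vals = [bool(v) for v in vals if v is not None]
            table.append([sum(vals), len(vals) - sum(vals)])
        arr = np.array(table).T  # 2 x 3: yes/no by grade
        entry = {"counts": arr.tolist()}
        try:
            if arr.sum() > 0 and arr.sum(axis=0).min() > 0:
                entry["fisher_p"] = fisher_exact_rxc(arr)
        except Exception as exc:
            entry["fisher_error"] = str(exc)
        categorical[name] = entry
    report["categorical_by_grade"] = categorical

    # --- echo-vs-CMR associations (echo is the predictor)
    associations = {}
    for echo_col, cmr_key in _ASSOCIATION_PAIRS:
        pairs = [
            (_echo_value(r, echo_col), _cmr_value(r, cmr_key)) for r in kept
        ]
        pairs = [(x, y) for x, y in pairs if x is not None and y is not None]
        if len(pairs) < 3:
            continue
        x, y = map(np.array, zip(*pairs))
        try:
            r_val, p, slope, intercept = pearson_linear(x, y)
            associations[f"{echo_col}~cmr_{cmr_key}"] = {
                "r": r_val, "p": p, "slope": slope, "intercept": intercept,
                "n": len(pairs),
            }
        except UndefinedStatisticError as exc:
            associations[f"{echo_col}~cmr_{cmr_key}"] = {"error": str(exc)}
    report["associations"] = associations

    # --- Bland–Altman on the only same-unit volumetric-vs-Doppler pair
    ba_pairs = [
        (_echo_value(r, "echo_EA"), _cmr_value(r, "EA_ratio")) for r in kept
    ]
    ba_pairs = [(x, y) for x, y in ba_pairs if x is not None and y is not None]
    if len(ba_pairs) >= 2:
        x, y = map(np.array, zip(*ba_pairs))
        bias, lo, hi = bland_altman(x, y)
        report["bland_altman_EA"] = {
            "bias": bias, "loa_low": lo, "loa_high": hi, "n": len(ba_pairs)
        }

    # --- ROC: reduced (positive) vs normal (negative); impaired excluded
    roc = {}
    pos = by_grade[DysfunctionGrade.TYPE_II]
    neg = by_grade[DysfunctionGrade.NORMAL]
    for key, direction in _ROC_DIRECTIONS.items():
        scores, labels = [], []
        for r, lab in [(r, 1) for r in pos] + [(r, 0) for r in neg]:
            v = _cmr_value(r, key)
            if v is not None:
                scores.append(v)
                labels.append(lab)
        try:
            res = roc_auc_with_band(scores, labels, direction)
            roc[f"cmr_{key}"] = {
                "auc": res.auc, "band": res.band, "p": res.p,
                "n": res.n_positive + res.n_negative,
            }
        except (DegenerateLabelsError, Exception) as exc:  # partial report
            roc[f"cmr_{key}"] = {"error": str(exc)}
    report["roc_reduced_vs_normal"] = roc

    # --- paired diastolic time intervals, echo vs CMR
    paired = {}
    for name, echo_col, cmr_key in [
        ("TPE", "echo_TPE", "TPE"),
        ("RTPA", "echo_RTPA", "RTPA"),
        ("RR", "echo_rr", "rr_interval"),
    ]:
        pairs = [
            (_echo_value(r, echo_col), _cmr_value(r, cmr_key)) for r in kept
        ]
        pairs = [(x, y) for x, y in pairs if x is not None and y is not None]
        if len(pairs) < 2:
            continue
        x, y = map(np.array, zip(*pairs))
        t, p = paired_mean_comparison(x, y)
        paired[name] = {
            "mean_echo": float(x.mean()), "mean_cmr": float(y.mean()),
            "t": t, "p": p, "n": len(pairs),
        }
    report["paired_time_intervals"] = paired
    return report
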