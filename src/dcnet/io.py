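"""Readers and writers for the pipeline's plain-text formats.

Per-subject ROI time series are tab-separated T x g matrices without header;
realignment traces use the 6-column SPM rp-file dialect (x y z translations
in mm, then pitch/roll/yaw rotations in radians, whitespace-separated); the
phenotype table is a CSV with header
``subject_id,group,age,sex,education,bdi,hamd``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import SubjectRecord
from .network import DCTable

PHENO_COLUMNS = ["subject_id", "group", "age", "sex", "education", "bdi", "hamd"]
_FLOAT_FMT = "%.17g"  # full double precision: write->read round-trips are exact


def read_series(path: str | Path, expected_g: int | None = None) -> np.ndarray:
    path = Path(path)
    try:
        arr = np.loadtxt(path, delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell in time-series file ({exc})") from exc
    if expected_g is not None and arr.shape[1] != expected_g:
        raise ValueError(
            f"{path}: expected {expected_g} ROI columns, found {arr.shape[1]}"
        )
    return arr


def read_rp(path: str | Path) -> np.ndarray:
    path = Path(path)
    try:
        arr = np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell in realignment file ({exc})") from exc
    if arr.shape[1] != 6:
        raise ValueError(
            f"{path}: realignment files use the 6-column rp dialect "
            f"(3 translations mm, 3 rotations rad); found {arr.shape[1]} columns"
        )
    return arr


def read_phenotype(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    pheno = pd.read_csv(path)
    missing = [c for c in PHENO_COLUMNS[:5] if c not in pheno.columns]
    if missing:
        raise ValueError(f"{path}: phenotype table missing columns {missing}")
    if pheno["subject_id"].duplicated().any():
        dup = pheno.loc[pheno["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"{path}: duplicated subject ids {dup}")
    return pheno


def write_cohort(records: list[SubjectRecord], truth: dict | None, out_dir: str | Path) -> None:
    """Write one series TSV and one rp file per subject, the phenotype CSV,
    and (if given) the ground-truth sidecar JSON."""
    out_dir = Path(out_dir)
    (out_dir / "timeseries").mkdir(parents=True, exist_ok=True)
    (out_dir / "rp").mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        np.savetxt(
            out_dir / "timeseries" / f"{rec.subject_id}.tsv",
            rec.series,
            fmt=_FLOAT_FMT,
            delimiter="\t",
        )
        np.savetxt(out_dir / "rp" / f"rp_{rec.subject_id}.txt", rec.realignment, fmt=_FLOAT_FMT)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "age": rec.age,
                "sex": rec.sex,
                "education": rec.education,
                "bdi": rec.bdi,
                "hamd": rec.hamd,
            }
        )
    pd.DataFrame(rows, columns=PHENO_COLUMNS).to_csv(
        out_dir / "phenotype.csv", index=False, float_format=_FLOAT_FMT
    )
    if truth is not None:
        with open(out_dir / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)


def load_cohort(data_dir: str | Path, expected_g: int | None = None) -> list[SubjectRecord]:
    """Read a cohort written by :func:`write_cohort` (or user data in the
    same layout) back into SubjectRecords."""
    data_dir = Path(data_dir)
    pheno = read_phenotype(data_dir / "phenotype.csv")
    records = []
    for row in pheno.itertuples(index=False):
        series_path = data_dir / "timeseries" / f"{row.subject_id}.tsv"
        rp_path = data_dir / "rp" / f"rp_{row.subject_id}.txt"
        if not series_path.exists():
            raise FileNotFoundError(
                f"phenotype lists subject {row.subject_id} but {series_path} is missing"
            )
        records.append(
            SubjectRecord(
                subject_id=row.subject_id,
                group=row.group,
                age=float(row.age),
                sex=row.sex,
                education=float(row.education),
                series=read_series(series_path, expected_g),
                realignment=read_rp(rp_path),
                bdi=None if pd.isna(row.bdi) else float(row.bdi),
                hamd=None if pd.isna(row.hamd) else float(row.hamd),
            )
        )
    return records


def write_dc_table(dc: DCTable, path: str | Path) -> None:
    df = dc.to_frame()
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t")


def read_dc_table(path: str | Path, sparsity: float) -> DCTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DCTable(
        values=df.to_numpy(dtype=int),
        sparsity=sparsity,
        subject_ids=list(df.index.astype(str)),
        node_labels=list(df.columns.astype(str)),
    )


def write_motion_qc(summaries: dict[str, object], path: str | Path) -> pd.DataFrame:
    rows = []
    for sid, summ in summaries.items():
        rows.append(
            {
                "subject_id": sid,
                "mean_fd": summ.mean_fd,
                "retained_volumes": summ.retained_volumes,
                "excluded": summ.excluded,
                "reason": summ.exclusion_reason.value,
            }
        )
    qc = pd.DataFrame(rows)
    qc.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return qc
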