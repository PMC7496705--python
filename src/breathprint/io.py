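"""Cohort and report file I/O.

On disk a cohort is a directory with ``manifest.json`` plus one long-format
CSV per measurement (columns temp_index, cycle_index, sensor_index,
conductivity; 0-based indices). Readers validate shape, finiteness and
positivity and name the offending subject in every error. All writes are
atomic (temp file + rename) so interrupted runs never leave corrupt files.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import Cohort, Measurement, N_CYCLES, N_SENSORS, N_TEMP

MANIFEST_NAME = "manifest.json"


def atomic_write_text(path: Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """Write manifest.json plus one CSV per measurement; returns the directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for m in cohort:
        fname = f"{m.subject_id}.csv"
        t, c, s = np.indices(m.tensor.shape)
        df = pd.DataFrame(
            {
                "temp_index": t.ravel(),
                "cycle_index": c.ravel(),
                "sensor_index": s.ravel(),
                "conductivity": m.tensor.ravel(),
            }
        )
        atomic_write_text(directory / fname, df.to_csv(index=False))
        entries.append(
            {
                "subject_id": m.subject_id,
                "device_id": int(m.device_id),
                "label": m.label,
                "subsite": m.subsite,
                "smoking": bool(m.smoking),
                "file": fname,
            }
        )
    atomic_write_text(
        directory / MANIFEST_NAME, json.dumps({"measurements": entries}, indent=1)
    )
    return directory


def read_cohort(directory: str | Path) -> Cohort:
    """Read and validate a cohort directory written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest_path = directory / MANIFEST_NAME
    if not manifest_path.exists():
        raise FileNotFoundError(f"no {MANIFEST_NAME} in {directory}")
    manifest = json.loads(manifest_path.read_text())
    measurements = []
    for entry in manifest["measurements"]:
        sid = entry["subject_id"]
        path = directory / entry["file"]
        if not path.exists():
            raise FileNotFoundError(
                f"measurement file for subject {sid} missing: {path}"
            )
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ValueError(f"subject {sid}: cannot parse {path}: {exc}") from exc
        required = {"temp_index", "cycle_index", "sensor_index", "conductivity"}
        if not required <= set(df.columns):
            raise ValueError(f"subject {sid}: missing columns {required - set(df.columns)}")
        bad = df.index[~np.isfinite(df["conductivity"]) | (df["conductivity"] <= 0)]
        if len(bad):
            # +2: header line plus 0-based index
            raise ValueError(
                f"subject {sid}: non-positive or non-finite conductivity at "
                f"line {int(bad[0]) + 2} of {path.name} (invariant: entries > 0)"
            )
        tensor = np.full((N_TEMP, N_CYCLES, N_SENSORS), np.nan)
        try:
            tensor[
                df["temp_index"].to_numpy(),
                df["cycle_index"].to_numpy(),
                df["sensor_index"].to_numpy(),
            ] = df["conductivity"].to_numpy()
        except IndexError as exc:
            raise ValueError(f"subject {sid}: index out of range in {path.name}") from exc
        if np.isnan(tensor).any():
            raise ValueError(f"subject {sid}: incomplete tensor in {path.name}")
        m = Measurement(
            subject_id=sid,
            device_id=int(entry["device_id"]),
            label=entry["label"],
            subsite=entry["subsite"],
            smoking=bool(entry["smoking"]),
            tensor=tensor,
        )
        m.validate()
        measurements.append(m)
    return Cohort(measurements)


def write_reports(reports, directory: str | Path) -> None:
    """Emit per-model JSON reports, a combined text table and ROC CSVs."""
    from .validate import metrics_table

    directory = Path(directory)
    combined = {r.model_id: r.to_dict() for r in reports}
    atomic_write_text(directory / "reports.json", json.dumps(combined, indent=1, sort_keys=True))
    atomic_write_text(directory / "metrics_table.txt", metrics_table(reports) + "\n")
    for r in reports:
        roc_df = pd.DataFrame(
            {"threshold": r.roc.thresholds, "fpr": r.roc.fpr, "tpr": r.roc.tpr}
        )
        atomic_write_text(directory / f"roc_{r.model_id}.csv", roc_df.to_csv(index=False))
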