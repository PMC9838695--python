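"""Plain-text readers and writers: TSV time series, label files, manifests, reports."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .estimation import TimeSeriesData
from .exceptions import SchemaError
from .reports import CostReport, InputMap
from .synthetic import SubjectData

__all__ = [
    "write_series_tsv",
    "read_series_tsv",
    "write_cohort",
    "read_cohort",
    "write_cost_report",
    "write_input_maps",
]


def write_series_tsv(series: TimeSeriesData, values_path: str | Path,
                     labels_path: str | Path | None = None) -> None:
    """Rows = timepoints, columns = ROIs, header of ROI names; labels as a
    two-column TSV (timepoint_index, label)."""
    names = series.roi_names or [f"roi_{k:03d}" for k in range(series.n)]
    pd.DataFrame(series.values, columns=list(names)).to_csv(
        values_path, sep="\t", index=False
    )
    if labels_path is not None and series.labels is not None:
        pd.DataFrame(
            {"timepoint_index": np.arange(series.n_timepoints), "label": series.labels}
        ).to_csv(labels_path, sep="\t", index=False)


def read_series_tsv(values_path: str | Path, dt: float,
                    labels_path: str | Path | None = None,
                    subject_id: str = "") -> TimeSeriesData:
    df = pd.read_csv(values_path, sep="\t")
    labels = None
    if labels_path is not None and Path(labels_path).exists():
        lab = pd.read_csv(labels_path, sep="\t")
        if not {"timepoint_index", "label"} <= set(lab.columns):
            raise SchemaError("labels file needs columns (timepoint_index, label)")
        labels = lab.sort_values("timepoint_index")["label"].to_numpy(dtype=str)
    return TimeSeriesData(
        df.to_numpy(dtype=float), dt, labels, subject_id, tuple(df.columns)
    )


def write_cohort(cohort: Sequence[SubjectData], outdir: str | Path, dt: float) -> Path:
    """Write each subject's runs as TSV + labels and a JSON manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"dt": dt, "subjects": []}
    for subj in cohort:
        entry = {"subject_id": subj.subject_id, "tasks": {}}
        rest_file = f"{subj.subject_id}_rest.tsv"
        write_series_tsv(subj.rest, outdir / rest_file)
        entry["rest"] = rest_file
        for task, ts in subj.tasks.items():
            vfile = f"{subj.subject_id}_{task}.tsv"
            lfile = f"{subj.subject_id}_{task}_labels.tsv"
            write_series_tsv(ts, outdir / vfile, outdir / lfile)
            entry["tasks"][task] = {"values": vfile, "labels": lfile}
        manifest["subjects"].append(entry)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def read_cohort(manifest_path: str | Path) -> list[SubjectData]:
    manifest_path = Path(manifest_path)
    d = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    dt = float(d["dt"])
    cohort = []
    for entry in d["subjects"]:
        sid = entry["subject_id"]
        rest = read_series_tsv(base / entry["rest"], dt, subject_id=sid)
        tasks = {
            task: read_series_tsv(base / spec["values"], dt, base / spec["labels"], sid)
            for task, spec in entry["tasks"].items()
        }
        cohort.append(SubjectData(sid, rest, tasks))
    return cohort


def write_cost_report(report: CostReport, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.records.to_csv(outdir / "costs.tsv", sep="\t", index=False)
    summary = report.summary()
    payload = {
        row["task"]: {k: (None if pd.isna(v) else float(v))
                      for k, v in row.items() if k != "task"}
        for row in summary.to_dict("records")
    }
    (outdir / "summary.json").write_text(json.dumps(payload, indent=1))


def write_input_maps(maps: dict[str, InputMap], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = []
    for task in sorted(maps):
        frame = maps[task].to_frame()
        frame.insert(0, "task", task)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(outdir / "input_maps.tsv", sep="\t", index=False)
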