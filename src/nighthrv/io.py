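"""On-disk formats: per-segment PPG CSVs, covariates, and a JSON manifest.

Each recording is one CSV with columns ``timestamp`` (ISO-8601) and ``ppg``
(a.u.); the manifest ties subjects to their segment files and, for synthetic
cohorts, to the generator's quality labels.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import PpgRecording


def write_recording(rec: PpgRecording, path: str | Path) -> None:
    rec.to_frame().to_csv(path, index=False)


def read_recording(path: str | Path, subject_id: str = "",
                   quality_label: str | None = None) -> PpgRecording:
    df = pd.read_csv(path)
    ts = pd.to_datetime(df["timestamp"])
    dt = (ts.iloc[1] - ts.iloc[0]).total_seconds()
    return PpgRecording(subject_id=subject_id, start_time=ts.iloc[0],
                        fs=1.0 / dt, samples=df["ppg"].to_numpy(),
                        quality_label=quality_label)


def write_cohort(recordings: list[PpgRecording], covariates: pd.DataFrame,
                 outdir: str | Path, *,
                 labels: list[str] | None = None) -> Path:
    """Write recordings, covariates and a manifest; returns manifest path."""
    outdir = Path(outdir)
    (outdir / "recordings").mkdir(parents=True, exist_ok=True)
    entries = []
    for i, rec in enumerate(recordings):
        fname = f"recordings/{rec.subject_id}_{i:05d}.csv"
        write_recording(rec, outdir / fname)
        entries.append({"subject_id": rec.subject_id, "file": fname,
                        "start_time": rec.start_time.isoformat(),
                        "fs": rec.fs,
                        "quality_label": labels[i] if labels
                        else rec.quality_label})
    covariates.to_csv(outdir / "covariates.csv", index=False)
    manifest = {"n_recordings": len(entries),
                "covariates": "covariates.csv", "segments": entries}
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=str))
    return mpath


def load_cohort(manifest_path: str | Path
                ) -> tuple[list[PpgRecording], pd.DataFrame, list[str | None]]:
    """Load recordings, covariates, and per-segment labels from a manifest."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    recordings, labels = [], []
    for e in manifest["segments"]:
        recordings.append(read_recording(base / e["file"], e["subject_id"],
                                         e.get("quality_label")))
        labels.append(e.get("quality_label"))
    covariates = pd.read_csv(base / manifest["covariates"],
                             parse_dates=["enrolment_date"])
    return recordings, covariates, labels
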