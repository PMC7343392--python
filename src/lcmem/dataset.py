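"""StudyDataset container and its on-disk TSV layout.

A study directory holds::

    trials.tsv                     long-format behavioral trial table
    beats_<subject>_<stage>.tsv    pulse-oximeter beat timestamps (s)
    roi_<subject>_<stage>.tsv      equidistant ROI BOLD series (time + channels)
    saa.tsv                        serial saliva alpha-amylase samples
    ground_truth.json              generator ground truth (synthetic data only)
    config.yaml                    cohort configuration + provenance

All files are UTF-8, tab-delimited with a header row.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from lcmem.config import CohortConfig, SAA_SCHEDULE
from lcmem.physio_hrv import BeatTimeline

TRIAL_COLUMNS = [
    "subject",
    "valence",
    "is_old",
    "recognized",
    "recollected",
    "rt_recognition",
    "rt_recollection",
]

ROI_CHANNELS = ["lc", "reference", "amygdala", "hippocampus", "entorhinal"]


@dataclass
class StudyDataset:
    """In-memory bundle of everything one cohort produced."""

    config: CohortConfig
    trials: pd.DataFrame
    beats: dict[tuple[int, str], BeatTimeline]
    roi: dict[tuple[int, str], pd.DataFrame]
    saa: pd.DataFrame
    ground_truth: dict = field(default_factory=dict)

    @property
    def subjects(self) -> list[int]:
        return sorted(self.trials["subject"].unique().tolist())

    def content_hash(self) -> str:
        """Stable digest of all tabular content (used in determinism checks)."""
        h = hashlib.sha256()
        h.update(self.trials.round(12).to_csv(sep="\t", index=False).encode())
        for key in sorted(self.beats):
            h.update(np.round(self.beats[key].times, 9).tobytes())
        for key in sorted(self.roi):
            h.update(self.roi[key].round(9).to_csv(sep="\t", index=False).encode())
        h.update(self.saa.round(9).to_csv(sep="\t", index=False).encode())
        return h.hexdigest()

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(path / "trials.tsv", sep="\t", index=False)
        for (subject, stage), timeline in self.beats.items():
            pd.DataFrame({"time": timeline.times}).to_csv(
                path / f"beats_{subject}_{stage}.tsv", sep="\t", index=False
            )
        for (subject, stage), frame in self.roi.items():
            frame.to_csv(path / f"roi_{subject}_{stage}.tsv", sep="\t", index=False)
        self.saa.to_csv(path / "saa.tsv", sep="\t", index=False)
        with open(path / "ground_truth.json", "w") as fh:
            json.dump(_jsonable(self.ground_truth), fh, indent=1)
        with open(path / "config.yaml", "w") as fh:
            yaml.safe_dump(
                {"cohort": asdict(self.config) | {"stages": list(self.config.stages)}},
                fh,
                sort_keys=True,
            )
        return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    return obj


class DatasetError(ValueError):
    """Raised when a study directory violates the documented layout."""


def load_study(path: str | Path) -> StudyDataset:
    """Load and validate a study directory (see module docstring for layout)."""
    path = Path(path)
    if not (path / "config.yaml").exists():
        raise DatasetError(f"{path}: missing mandatory file config.yaml")
    with open(path / "config.yaml") as fh:
        raw = yaml.safe_load(fh)["cohort"]
    raw["stages"] = tuple(raw["stages"])
    config = CohortConfig(**raw)

    if not (path / "trials.tsv").exists():
        raise DatasetError(f"{path}: missing mandatory file trials.tsv")
    trials = pd.read_csv(path / "trials.tsv", sep="\t")
    missing_cols = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing_cols:
        raise DatasetError(f"trials.tsv: missing columns {sorted(missing_cols)}")
    bad = trials.index[(trials["recollected"].notna()) & (~trials["recognized"].astype(bool))]
    if len(bad):
        raise DatasetError(
            f"trials.tsv row {int(bad[0]) + 2}: recollection response without endorsement"
        )
    new_with_recollection = trials.index[
        trials["recollected"].notna() & ~trials["is_old"].astype(bool)
    ]
    if len(new_with_recollection):
        raise DatasetError(
            f"trials.tsv row {int(new_with_recollection[0]) + 2}: recollection scored on a new face"
        )

    beats: dict[tuple[int, str], BeatTimeline] = {}
    roi: dict[tuple[int, str], pd.DataFrame] = {}
    subjects = sorted(trials["subject"].unique().tolist())
    for subject in subjects:
        for stage in config.stages:
            bpath = path / f"beats_{subject}_{stage}.tsv"
            rpath = path / f"roi_{subject}_{stage}.tsv"
            if bpath.exists():
                times = pd.read_csv(bpath, sep="\t")["time"].to_numpy(float)
                if np.any(np.diff(times) <= 0):
                    k = int(np.argmax(np.diff(times) <= 0))
                    raise DatasetError(f"{bpath.name} row {k + 3}: non-monotone beat timestamps")
                beats[(subject, stage)] = BeatTimeline(times=times, stage=stage)
            if rpath.exists():
                frame = pd.read_csv(rpath, sep="\t")
                if "time" not in frame.columns:
                    raise DatasetError(f"{rpath.name}: missing 'time' column")
                dt = np.diff(frame["time"].to_numpy(float))
                if len(dt) and not np.allclose(dt, dt[0], rtol=0, atol=1e-6):
                    raise DatasetError(f"{rpath.name}: ROI samples are not equidistant")
                roi[(subject, stage)] = frame

    if not (path / "saa.tsv").exists():
        raise DatasetError(f"{path}: missing mandatory file saa.tsv")
    saa = pd.read_csv(path / "saa.tsv", sep="\t")
    unknown = set(saa["label"]) - set(SAA_SCHEDULE)
    if unknown:
        raise DatasetError(f"saa.tsv: unknown schedule labels {sorted(unknown)}")

    ground_truth = {}
    if (path / "ground_truth.json").exists():
        with open(path / "ground_truth.json") as fh:
            ground_truth = json.load(fh)

    return StudyDataset(
        config=config, trials=trials, beats=beats, roi=roi, saa=saa, ground_truth=ground_truth
    )
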