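"""Dataset container and plain-text I/O.

A tracer-study dataset is a long-format table of observed series:
``series_id, time_h, value[, sd]``, together with subject metadata (id,
body weight, protocol).  Files are UTF-8 CSV, dot decimal, header row
mandatory, with metadata carried in ``# key=value`` comment lines;
values are written with 17 significant digits so that a write/read
round trip is bit-exact.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ConfigurationError

__all__ = [
    "TracerStudyDataset",
    "FED_SERIES",
    "FASTED_SERIES",
    "read_dataset",
    "write_dataset",
    "DatasetValidationError",
]


class DatasetValidationError(ValueError):
    """Raised with a listing of offending rows when a dataset is invalid."""


#: the 19 series of a fed-protocol study (panel-by-panel observables)
FED_SERIES: tuple[str, ...] = (
    "plasma_leucine_enr",
    "ttr_apob48_plasma", "ttr_apob48_cm", "ttr_apob48_vldl1", "ttr_apob48_vldl2",
    "ttr_apob100_vldl1", "ttr_apob100_vldl2",
    "ttr_tg_glycerol_vldl1", "ttr_tg_glycerol_vldl2",
    "tg_plasma", "apob48_plasma",
    "tg_cm", "tg_vldl1", "tg_vldl2",
    "apob100_vldl1", "apob100_vldl2",
    "apob48_cm", "apob48_vldl1", "apob48_vldl2",
)

#: fasted-protocol studies measure total plasma apoB48 mass and enrichment
#: (fraction-level data are not collected) plus plasma leucine
FASTED_SERIES: tuple[str, ...] = (
    "plasma_leucine_enr", "apob48_plasma", "ttr_apob48_plasma",
)

SERIES_VOCABULARY = frozenset(FED_SERIES)


@dataclass
class TracerStudyDataset:
    """Observed (or synthetic) time series for one subject and protocol."""

    subject_id: str
    body_weight: float
    protocol: str  # fed | fasted
    table: pd.DataFrame  # columns: series_id, time_h, value [, sd]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        required = {"series_id", "time_h", "value"}
        if not required <= set(self.table.columns):
            raise DatasetValidationError(
                f"table must have columns {sorted(required)}")
        if self.protocol not in ("fed", "fasted"):
            raise ConfigurationError(f"unknown protocol {self.protocol!r}")
        bad_series = sorted(set(self.table.series_id) - SERIES_VOCABULARY)
        if bad_series:
            raise DatasetValidationError(f"unknown series ids: {bad_series}")
        problems = []
        t = self.table
        neg = t[t.value < 0]
        if len(neg):
            problems.append(f"negative values in rows {list(neg.index)}")
        out = t[(t.time_h < 0) | (t.time_h > 24)]
        if len(out):
            problems.append(f"times outside [0, 24] h in rows {list(out.index)}")
        for sid, grp in t.groupby("series_id"):
            times = grp.time_h.to_numpy()
            if np.any(np.diff(times) <= 0):
                problems.append(f"non-monotone times in series {sid}")
        if problems:
            raise DatasetValidationError("; ".join(problems))

    @property
    def series_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table.series_id))

    def series(self, series_id: str) -> tuple[np.ndarray, np.ndarray]:
        grp = self.table[self.table.series_id == series_id]
        if grp.empty:
            raise KeyError(series_id)
        return grp.time_h.to_numpy(float), grp.value.to_numpy(float)

    def times(self) -> np.ndarray:
        """Sorted union of all observation times."""
        return np.unique(self.table.time_h.to_numpy(float))


def write_dataset(dataset: TracerStudyDataset, path: str | Path) -> None:
    buf = _io.StringIO()
    buf.write(f"# subject_id={dataset.subject_id}\n")
    buf.write(f"# body_weight={dataset.body_weight!r}\n")
    buf.write(f"# protocol={dataset.protocol}\n")
    cols = ["series_id", "time_h", "value"] + (
        ["sd"] if "sd" in dataset.table.columns else [])
    buf.write(",".join(cols) + "\n")
    for _, row in dataset.table.iterrows():
        vals = [str(row.series_id)] + [repr(float(row[c])) for c in cols[1:]]
        buf.write(",".join(vals) + "\n")
    Path(path).write_text(buf.getvalue())


def read_dataset(path: str | Path) -> TracerStudyDataset:
    meta: dict[str, str] = {}
    rows: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition("=")
            meta[key.strip()] = val.strip()
        elif line.strip():
            rows.append(line)
    if not rows:
        raise DatasetValidationError(f"{path}: no table rows")
    table = pd.read_csv(_io.StringIO("\n".join(rows)),
                        float_precision="round_trip")
    missing = {"subject_id", "body_weight", "protocol"} - set(meta)
    if missing:
        raise DatasetValidationError(f"{path}: missing metadata {sorted(missing)}")
    return TracerStudyDataset(
        subject_id=meta["subject_id"],
        body_weight=float(meta["body_weight"]),
        protocol=meta["protocol"],
        table=table,
    )
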