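"""Cohort summaries and diagnostic figures.

The cohort table mirrors the per-subject kinetic-parameter layout:
one row per derived parameter, one column per subject, plus mean and SD
columns.  The SD uses the population convention (divisor n), which is
what the published cohort summaries follow; a sample-SD (n-1) column can
be requested for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import KineticSummary
from .io import FASTED_SERIES, FED_SERIES, TracerStudyDataset
from .params import ConfigurationError

__all__ = ["CohortTable", "cohort_summary", "plot_dataset_fit"]


@dataclass
class CohortTable:
    """Per-subject kinetic parameters with cohort mean and SD columns."""

    table: pd.DataFrame

    def row(self, name: str) -> pd.Series:
        return self.table.loc[name]

    def recompute_consistent(self) -> bool:
        """Mean/SD columns match a recomputation from the subject columns."""
        subj = self.table.drop(columns=["mean", "sd"])
        mean = subj.mean(axis=1)
        sd = subj.std(axis=1, ddof=0)
        return bool(np.allclose(mean, self.table["mean"])
                    and np.allclose(sd, self.table["sd"]))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, float_format="%.17g")


def cohort_summary(summaries, subject_ids=None, sample_sd: bool = False) -> CohortTable:
    """Summarize per-subject kinetic parameters in a cohort table.

    ``summaries`` is a list of :class:`KineticSummary` or of plain
    ``row -> value`` dicts.  Mean is the arithmetic mean; SD uses the
    population divisor n (add a sample-SD column with ``sample_sd``).
    """
    if not summaries:
        raise ConfigurationError("cohort_summary needs at least one subject")
    dicts = [s.as_dict() if isinstance(s, KineticSummary) else dict(s)
             for s in summaries]
    if subject_ids is None:
        subject_ids = [f"S{i + 1}" for i in range(len(dicts))]
    rows = list(dicts[0])
    data = {sid: [d[r] for r in rows] for sid, d in zip(subject_ids, dicts)}
    table = pd.DataFrame(data, index=rows)
    table["mean"] = table.mean(axis=1)
    table["sd"] = table[list(subject_ids)].std(axis=1, ddof=0)
    if sample_sd:
        table["sd_n1"] = table[list(subject_ids)].std(axis=1, ddof=1)
    return CohortTable(table)


def plot_dataset_fit(
    dataset: TracerStudyDataset,
    model_series: dict[str, np.ndarray] | None = None,
    model_times: np.ndarray | None = None,
    path: str | Path = "fit.png",
) -> Path:
    """Panel grid of observed series with optional model curves.

    Fed datasets get the full observable grid (enrichments first, then
    concentrations); fasted datasets the two-panel layout.  Written to
    file, never shown interactively.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    series_ids = [s for s in (FED_SERIES if dataset.protocol == "fed"
                              else FASTED_SERIES) if s in dataset.series_ids]
    ncols = 4 if dataset.protocol == "fed" else len(series_ids)
    nrows = int(np.ceil(len(series_ids) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 2.8 * nrows),
                             squeeze=False)
    for ax in axes.flat[len(series_ids):]:
        ax.set_axis_off()
    for ax, sid in zip(axes.flat, series_ids):
        t, v = dataset.series(sid)
        ax.plot(t, v, "o", ms=3, label="data")
        if model_series is not None and sid in model_series:
            mt = t if model_times is None else model_times
            ax.plot(mt, model_series[sid], "-", lw=1, label="model")
        ax.set_title(sid, fontsize=8)
        if sid == "plasma_leucine_enr":
            ax.set_yscale("log")
        ax.set_xlabel("h")
    fig.suptitle(f"{dataset.subject_id} ({dataset.protocol})")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
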