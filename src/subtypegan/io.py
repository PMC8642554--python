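"""Tabular ROI-volume container and CSV/TSV round-trip.

One row per scan: subject identifier, visit time in years since baseline,
diagnosis, age, sex, then one column per regional volume. ROI columns are
recognised by the ``ROI_`` prefix; all remaining schema columns are fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROI_PREFIX = "ROI_"
META_COLUMNS = ["participant_id", "visit_time", "diagnosis", "age", "sex"]
DIAGNOSES = ("CN", "MCI", "Dementia")


@dataclass
class ROITable:
    """A validated table of regional brain volumes plus scan metadata.

    Parameters
    ----------
    data
        DataFrame with the columns in :data:`META_COLUMNS` followed by
        ``ROI_``-prefixed volume columns. ``diagnosis`` may contain empty
        strings / NA for prediction-only inputs.
    """

    data: pd.DataFrame
    roi_names: list[str] = field(init=False)

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        self.roi_names = [c for c in self.data.columns if c.startswith(ROI_PREFIX)]
        if len(self.roi_names) < 2:
            raise ValueError("an ROITable needs at least 2 ROI columns")
        vals = self.data[self.roi_names].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("ROI values contain NaN/inf")
        if not np.all(np.isfinite(self.data["age"].to_numpy(dtype=float))):
            raise ValueError("age contains NaN/inf")
        vt = self.data["visit_time"].to_numpy(dtype=float)
        if np.any(vt < 0):
            raise ValueError("visit_time must be non-negative")
        # visit_time non-decreasing within subject, in file order
        for pid, grp in self.data.groupby("participant_id", sort=False):
            t = grp["visit_time"].to_numpy(dtype=float)
            if np.any(np.diff(t) < 0):
                raise ValueError(f"visit_time not monotone for participant {pid!r}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    @property
    def values(self) -> np.ndarray:
        """The (n, R) matrix of ROI volumes."""
        return self.data[self.roi_names].to_numpy(dtype=float)

    def with_values(self, values: np.ndarray) -> "ROITable":
        """Copy of the table with ROI columns replaced (same shape)."""
        if values.shape != (len(self), self.n_rois):
            raise ValueError("replacement values have the wrong shape")
        out = self.data.copy()
        out[self.roi_names] = values
        return ROITable(out)

    def select_diagnosis(self, *labels: str) -> "ROITable":
        mask = self.data["diagnosis"].isin(labels)
        return ROITable(self.data.loc[mask].reset_index(drop=True))

    def subset(self, idx) -> "ROITable":
        return ROITable(self.data.iloc[np.asarray(idx)].reset_index(drop=True))

    @classmethod
    def from_csv(cls, path, sep: str | None = None) -> "ROITable":
        if sep is None:
            sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(path, sep=sep, encoding="utf-8")
        return cls(df)

    def to_csv(self, path, sep: str = ",") -> None:
        self.data.to_csv(path, sep=sep, index=False, encoding="utf-8")


def concat(tables: list[ROITable]) -> ROITable:
    names = tables[0].roi_names
    for t in tables[1:]:
        if t.roi_names != names:
            raise ValueError("ROI names differ between tables")
    return ROITable(pd.concat([t.data for t in tables], ignore_index=True))
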