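"""Expression-matrix container for two-group microarray-style intensity data.

One :class:`ExpressionMatrix` holds the normalized intensities of a single RNA
layer (circRNA, miRNA or mRNA) for all case and control samples at one time
point.  Values are linear-scale (not log) intensities and must be strictly
positive; features are rows, samples are columns.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

LAYERS = ("circRNA", "miRNA", "mRNA")
GROUPS = ("case", "control")


@dataclasses.dataclass
class ExpressionMatrix:
    """Normalized intensities for one RNA layer at one time point.

    Parameters
    ----------
    layer
        One of ``"circRNA"``, ``"miRNA"``, ``"mRNA"``.
    time_label
        Free-text time-point label, e.g. ``"7M"``.
    values
        Features x samples DataFrame of strictly positive linear intensities.
        The index holds unique feature ids, the columns unique sample ids.
    groups
        Mapping ``sample_id -> "case" | "control"`` covering every column,
        with at least two samples per group.
    """

    layer: str
    time_label: str
    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if not isinstance(self.groups, pd.Series):
            self.groups = pd.Series(self.groups)
        if not self.values.index.is_unique:
            raise ValueError("feature ids must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("sample ids must be unique")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group assignment: {sorted(missing)}")
        self.groups = self.groups.loc[self.values.columns]
        bad = set(self.groups.unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")
        for g in GROUPS:
            if (self.groups == g).sum() < 2:
                raise ValueError(f"need at least 2 {g!r} samples")
        if not np.all(self.values.to_numpy() > 0):
            raise ValueError("all intensities must be > 0 after normalization")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def case_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == "case"])

    @property
    def control_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == "control"])

    def case_values(self) -> np.ndarray:
        return self.values[self.case_samples].to_numpy(dtype=float)

    def control_values(self) -> np.ndarray:
        return self.values[self.control_samples].to_numpy(dtype=float)

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        """Copy of this matrix with replaced values (same layer/labels/groups)."""
        return ExpressionMatrix(self.layer, self.time_label, values, self.groups.copy())

    # ------------------------------------------------------------------ I/O

    def to_tsv(self, matrix_path: str | Path, samples_path: str | Path) -> None:
        """Write values as TSV (feature rows) plus a sample-sheet TSV."""
        self.values.rename_axis("feature_id").to_csv(matrix_path, sep="\t")
        sheet = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "group": self.groups.loc[self.sample_ids].to_numpy(),
                "time": self.time_label,
                "layer": self.layer,
            }
        )
        sheet.to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls,
        matrix_path: str | Path,
        samples_path: str | Path,
        layer: str | None = None,
        time_label: str | None = None,
    ) -> "ExpressionMatrix":
        """Read a matrix TSV and its sample sheet.

        ``layer``/``time_label`` default to the values recorded in the sample
        sheet (which must then be uniform).
        """
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        sheet = pd.read_csv(samples_path, sep="\t", dtype=str)
        if "sample_id" not in sheet.columns or "group" not in sheet.columns:
            raise ValueError("sample sheet needs 'sample_id' and 'group' columns")
        groups = pd.Series(sheet["group"].to_numpy(), index=sheet["sample_id"])
        if layer is None:
            if "layer" not in sheet.columns or sheet["layer"].nunique() != 1:
                raise ValueError("layer not given and not uniform in sample sheet")
            layer = sheet["layer"].iloc[0]
        if time_label is None:
            time_label = sheet["time"].iloc[0] if "time" in sheet.columns else ""
        return cls(layer, time_label, values, groups)
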