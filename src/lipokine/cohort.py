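"""Cohort table container: subjects x {factors, covariates, clinical, lipid, cytokine}.

The on-disk representation is a plain CSV with subjects as rows.  Panel
membership is encoded in column-name prefixes: ``clin_`` for the clinical
panel, ``lip_`` for lipid species, ``cyt_`` for cytokine analytes.  Factor
columns (``race``, ``disease``, ``sex``) and covariates are unprefixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import CohortFormatError

RACES = ("White", "AA")
DISEASES = ("NoDx", "Dx")
#: Canonical group order used everywhere: disease label then race label.
GROUPS = ("NoDx-White", "Dx-White", "NoDx-AA", "Dx-AA")

FACTOR_COLUMNS = ("race", "disease", "sex")

PANEL_PREFIXES = {
    "clinical": "clin_",
    "lipid": "lip_",
    "cytokine": "cyt_",
}


@dataclass
class CohortTable:
    """Thin wrapper around a subjects-as-rows DataFrame with panel accessors."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("race", "disease") if c not in self.data.columns]
        if missing:
            raise CohortFormatError(f"cohort table lacks required columns: {missing}")
        bad_race = set(self.data["race"].unique()) - set(RACES)
        bad_dis = set(self.data["disease"].unique()) - set(DISEASES)
        if bad_race:
            raise CohortFormatError(f"unknown race levels: {sorted(bad_race)}")
        if bad_dis:
            raise CohortFormatError(f"unknown disease levels: {sorted(bad_dis)}")

    # -- panels ---------------------------------------------------------
    def panel(self, name: str) -> pd.DataFrame:
        """Return the sub-table of one panel (columns keep their prefixes)."""
        prefix = PANEL_PREFIXES[name]
        cols = [c for c in self.data.columns if c.startswith(prefix)]
        return self.data[cols]

    def analytes(self, name: str) -> list[str]:
        return list(self.panel(name).columns)

    def has_panel(self, name: str) -> bool:
        return len(self.analytes(name)) > 0

    # -- factors --------------------------------------------------------
    @property
    def race(self) -> pd.Series:
        return self.data["race"]

    @property
    def disease(self) -> pd.Series:
        return self.data["disease"]

    @property
    def group(self) -> pd.Series:
        """Four-level group label, e.g. ``Dx-AA``."""
        return (self.data["disease"].astype(str) + "-" + self.data["race"].astype(str)).rename("group")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def group_sizes(self) -> pd.Series:
        return self.group.value_counts().reindex(GROUPS, fill_value=0)

    # -- I/O ------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortTable":
        try:
            df = pd.read_csv(path)
        except pd.errors.ParserError as exc:  # pandas messages carry the line number
            raise CohortFormatError(f"malformed cohort CSV {path}: {exc}") from exc
        return cls(df)


def require_positive(panel_df: pd.DataFrame, panel_name: str) -> None:
    """Raise if any analyte value is non-positive (ratios/log steps need > 0)."""
    bad = panel_df.columns[(panel_df <= 0).any(axis=0)]
    if len(bad):
        raise CohortFormatError(
            f"non-positive values in {panel_name} panel columns: {list(bad[:5])}"
        )


def subset_columns(df: pd.DataFrame, names: Iterable[str]) -> pd.DataFrame:
    names = list(names)
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise KeyError(f"analytes not present in cohort: {missing[:5]}")
    return df[names]
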