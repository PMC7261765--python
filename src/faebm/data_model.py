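"""Domain types and IO for cross-sectional biomarker tables.

A :class:`BiomarkerTable` holds one row per subject: identifier, group
label (``patient``/``control``), optional age and site, and one numeric
column per white-matter region (mean fractional anisotropy, a scalar in
(0, 1)).  Canonical region sets — 11 combined-hemisphere regions or 19
hemisphere-split regions — ship as package data.

Age effects are removed at the region level: an ordinary least-squares
line of FA on age is fitted to controls only, and the fitted slope is
regressed out of every subject while anchoring values at the control mean
age so the FA scale is preserved.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    DegenerateDataError,
    SampleSizeError,
    SchemaError,
    ValidationError,
)

GROUP_LABELS = ("patient", "control")
METADATA_COLUMNS = ("subject_id", "group", "age", "site")


@dataclass(frozen=True)
class RegionInfo:
    """Anatomical metadata for one region label."""

    tract: str
    hemisphere: str  # "L", "R" or "both"
    mni_z: tuple[float, float] | None = None  # closed z-interval, MNI mm


@dataclass(frozen=True)
class RegionSet:
    """An ordered set of region labels with anatomical metadata.

    ``mode`` is ``"combined"`` (11 regions, hemispheres pooled),
    ``"split"`` (19 regions, all tracts except the corpus callosum split
    by hemisphere) or ``"custom"``.
    """

    labels: tuple[str, ...]
    mode: str = "custom"
    metadata: Mapping[str, RegionInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("region labels must be unique")
        if any(not lbl for lbl in self.labels):
            raise ValidationError("region labels must be non-empty")
        if self.mode == "combined" and len(self.labels) != 11:
            raise ValidationError("combined mode requires exactly 11 regions")
        if self.mode == "split" and len(self.labels) != 19:
            raise ValidationError("split mode requires exactly 19 regions")

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)


def canonical_region_set(mode: str) -> RegionSet:
    """Return the canonical region set for ``mode`` ("combined" or "split").

    Combined pools hemispheres into 11 regions (three corticospinal-tract
    segments, three corpus-callosum subdivisions, cingulum, SLF, ILF,
    IFOF, UF); split keeps the corpus callosum whole and splits every
    other tract by hemisphere, giving 19 regions.
    """
    if mode not in ("combined", "split"):
        raise ValidationError(f"unknown region-set mode {mode!r}")
    ref = importlib.resources.files("faebm") / "data" / "region_sets.yaml"
    catalog = yaml.safe_load(ref.read_text())
    entries = catalog[mode]
    labels = tuple(e["label"] for e in entries)
    metadata = {
        e["label"]: RegionInfo(
            tract=e["tract"],
            hemisphere=e["hemisphere"],
            mni_z=tuple(e["mni_z"]) if "mni_z" in e else None,
        )
        for e in entries
    }
    return RegionSet(labels=labels, mode=mode, metadata=metadata)


@dataclass
class BiomarkerTable:
    """Subjects-by-regions biomarker matrix plus subject metadata.

    ``subjects`` carries subject_id, group and (optionally) age and site;
    ``values`` is a float DataFrame with one column per region label, row
    aligned with ``subjects``.
    """

    subjects: pd.DataFrame
    values: pd.DataFrame
    region_set: RegionSet

    def __post_init__(self) -> None:
        self.subjects = self.subjects.reset_index(drop=True)
        self.values = self.values.reset_index(drop=True)
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self, mode: str = "basic") -> None:
        """Check structural invariants; ``mode="fa"`` additionally
        requires every value strictly inside (0, 1)."""
        if len(self.subjects) != len(self.values):
            raise SchemaError("subjects and values row counts differ")
        for col in ("subject_id", "group"):
            if col not in self.subjects.columns:
                raise SchemaError(f"missing metadata column {col!r}")
        bad = set(self.subjects["group"]) - set(GROUP_LABELS)
        if bad:
            raise ValidationError(f"unknown group label(s): {sorted(bad)}")
        if tuple(self.values.columns) != self.region_set.labels:
            raise SchemaError("value columns do not match region set order")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("biomarker values must be finite")
        if mode == "fa" and not (np.all(arr > 0.0) and np.all(arr < 1.0)):
            raise ValidationError("FA values must lie strictly in (0, 1)")

    # -- accessors -----------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def region_labels(self) -> tuple[str, ...]:
        return self.region_set.labels

    def mask(self, group: str) -> np.ndarray:
        return (self.subjects["group"] == group).to_numpy()

    def subset(self, mask: np.ndarray) -> "BiomarkerTable":
        return BiomarkerTable(
            subjects=self.subjects.loc[mask],
            values=self.values.loc[mask],
            region_set=self.region_set,
        )

    def patients(self) -> "BiomarkerTable":
        return self.subset(self.mask("patient"))

    def controls(self) -> "BiomarkerTable":
        return self.subset(self.mask("control"))

    def value_matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    # -- IO ------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.subjects, self.values], axis=1)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, region_set: RegionSet
    ) -> "BiomarkerTable":
        missing = [c for c in region_set.labels if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing region column(s): {missing}")
        meta_cols = [c for c in METADATA_COLUMNS if c in frame.columns]
        subjects = frame[meta_cols].copy()
        values = frame[list(region_set.labels)].copy()
        for col in region_set.labels:
            try:
                values[col] = pd.to_numeric(values[col], errors="raise")
            except (ValueError, TypeError) as exc:
                raise SchemaError(
                    f"non-numeric value in region column {col!r}: {exc}"
                ) from exc
        if values.isna().any().any():
            na = values.columns[values.isna().any()].tolist()
            raise ValidationError(f"missing values in region column(s) {na}")
        return cls(subjects=subjects, values=values, region_set=region_set)


def read_biomarker_table(
    path: str | Path, region_set: RegionSet
) -> BiomarkerTable:
    """Read a delimited-text biomarker table and validate it.

    The file must have a header row with ``subject_id`` and ``group``
    columns plus one column per region label (any order; columns are
    reordered to the region-set order). ``age`` and ``site`` are optional.
    """
    frame = pd.read_csv(path)
    for col in ("subject_id", "group"):
        if col not in frame.columns:
            raise SchemaError(f"missing metadata column {col!r}")
    return BiomarkerTable.from_frame(frame, region_set)


# ---------------------------------------------------------------------
# Age residualization
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class AgeModel:
    """Per-region linear age effect fitted on controls.

    ``slopes``/``intercepts`` are indexed by region label (FA units per
    year and FA units); ``reference_age`` is the control mean age used as
    the anchor when residualizing.
    """

    slopes: pd.Series
    intercepts: pd.Series
    reference_age: float


def fit_age_model(table: BiomarkerTable) -> AgeModel:
    """Fit an ordinary least-squares line of FA on age, per region,
    using controls only."""
    if "age" not in table.subjects.columns:
        raise ValidationError("table has no age column")
    controls = table.controls()
    age = pd.to_numeric(controls.subjects["age"], errors="coerce")
    keep = age.notna().to_numpy()
    if keep.sum() < 3:
        raise SampleSizeError(
            f"need >= 3 controls with age, got {int(keep.sum())}"
        )
    x = age.to_numpy(dtype=float)[keep]
    if np.ptp(x) == 0.0:
        raise DegenerateDataError("control age is constant; OLS is degenerate")
    y = controls.value_matrix()[keep]
    xc = x - x.mean()
    slopes = xc @ (y - y.mean(axis=0)) / (xc @ xc)
    intercepts = y.mean(axis=0) - slopes * x.mean()
    labels = list(table.region_labels)
    return AgeModel(
        slopes=pd.Series(slopes, index=labels),
        intercepts=pd.Series(intercepts, index=labels),
        reference_age=float(x.mean()),
    )


def residualize_age(table: BiomarkerTable, model: AgeModel) -> BiomarkerTable:
    """Regress the control-fitted age effect out of every subject.

    value' = value - slope * (age - reference_age); values stay on the FA
    scale because they are anchored at the control mean age.
    """
    if "age" not in table.subjects.columns:
        raise ValidationError("table has no age column")
    age = pd.to_numeric(table.subjects["age"], errors="coerce")
    if age.isna().any():
        raise ValidationError("age missing for some subjects")
    slopes = model.slopes.reindex(list(table.region_labels))
    if slopes.isna().any():
        raise SchemaError("age model does not cover all regions")
    shift = np.outer(
        age.to_numpy(dtype=float) - model.reference_age, slopes.to_numpy()
    )
    values = table.values - shift
    return BiomarkerTable(
        subjects=table.subjects.copy(),
        values=values,
        region_set=table.region_set,
    )
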