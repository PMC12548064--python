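"""Tabular IO for the pipeline: sample sheets, methylation matrices and
probe manifests.

All files are tab-delimited UTF-8 text with ``NA`` for missing values and
``.`` as the decimal mark.  Genomic coordinates are hg19, 1-based
inclusive (the Illumina manifest convention).  A 25-probe manifest for
the BRCA1/NBR2 bidirectional promoter (hg19 17:41,277,059-41,278,712)
ships with the package; see :func:`load_default_manifest`.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from methylong.errors import DataValidationError, SchemaError

logger = logging.getLogger(__name__)

TIMEPOINTS = ("birth", "postnatal")
CONCEPTIONS = ("natural", "ART")
SEXES = ("female", "male")
SMOKING_LEVELS = ("No", "Sometimes", "Daily")
BMI_CATEGORIES = ("Underweight", "Normal", "Overweight", "Obese")

_SHEET_COLUMNS = [
    "sample_id", "child_id", "timepoint", "conception", "sex", "child_age",
    "multiple_birth", "twin_pair_id", "maternal_age", "smoking",
    "bmi_category", "parity", "plate_id",
]

PathLike = Union[str, Path]


@dataclass(frozen=True)
class SampleRecord:
    """One blood sample (child x timepoint) with covariates and plate.

    ``child_age`` is present iff ``timepoint == "postnatal"``.
    ``bmi_category`` is ``None`` when the questionnaire value is missing.
    ``cell_fractions`` optionally carries estimated cell-type proportions
    (summing to ~1) used only in sensitivity analyses.
    """

    sample_id: str
    child_id: str
    timepoint: str
    conception: str
    sex: str
    maternal_age: float
    smoking: str
    parity: int
    plate_id: str
    child_age: Optional[float] = None
    multiple_birth: bool = False
    twin_pair_id: Optional[str] = None
    bmi_category: Optional[str] = None
    cell_fractions: Optional[dict[str, float]] = field(default=None)

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise DataValidationError(
                f"sample {self.sample_id}: unknown timepoint {self.timepoint!r}"
            )
        if self.conception not in CONCEPTIONS:
            raise DataValidationError(
                f"sample {self.sample_id}: unknown conception {self.conception!r}"
            )
        if self.sex not in SEXES:
            raise DataValidationError(
                f"sample {self.sample_id}: unknown sex {self.sex!r}"
            )
        if self.smoking not in SMOKING_LEVELS:
            raise DataValidationError(
                f"sample {self.sample_id}: unknown smoking level {self.smoking!r}"
            )
        if self.bmi_category is not None and self.bmi_category not in BMI_CATEGORIES:
            raise DataValidationError(
                f"sample {self.sample_id}: unknown BMI category {self.bmi_category!r}"
            )
        if (self.child_age is None) != (self.timepoint == "birth"):
            raise DataValidationError(
                f"sample {self.sample_id}: child_age must be present iff "
                f"timepoint is postnatal (got timepoint={self.timepoint}, "
                f"child_age={self.child_age})"
            )
        if self.parity < 0:
            raise DataValidationError(
                f"sample {self.sample_id}: parity must be >= 0"
            )
        if self.cell_fractions is not None:
            total = float(sum(self.cell_fractions.values()))
            if not 0.95 <= total <= 1.05 or min(self.cell_fractions.values()) < 0:
                raise DataValidationError(
                    f"sample {self.sample_id}: cell fractions must be "
                    f"nonnegative and sum to ~1 (got {total:.3f})"
                )


@dataclass(frozen=True)
class ProbeAnnotation:
    """Manifest row: probe ID, hg19 coordinate and Illumina annotations."""

    probe_id: str
    chromosome: str
    position: int
    regulatory_feature: str = ""
    island_relation: str = ""
    gene: str = ""

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise DataValidationError(
                f"probe {self.probe_id}: position must be positive"
            )


@dataclass
class MethylationMatrix:
    """Probes x samples methylation values with an explicit scale flag.

    ``scale`` is ``"beta"`` (fractions strictly in (0, 1)) or ``"M"``
    (log2 beta/(1-beta)).
    """

    values: pd.DataFrame  # index: probe_ids, columns: sample_ids
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in ("beta", "M"):
            raise DataValidationError(f"unknown scale {self.scale!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise DataValidationError(f"duplicated probe IDs: {sorted(dups)}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise DataValidationError(f"duplicated sample IDs: {sorted(dups)}")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise DataValidationError("matrix contains missing values")
        if self.scale == "beta" and ((arr <= 0) | (arr >= 1)).any():
            raise DataValidationError(
                "beta values must lie strictly in (0, 1); the M-value "
                "transform is undefined at 0 and 1"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset(
        self,
        probe_ids: Optional[Sequence[str]] = None,
        sample_ids: Optional[Sequence[str]] = None,
    ) -> "MethylationMatrix":
        values = self.values
        if probe_ids is not None:
            missing = sorted(set(probe_ids) - set(values.index))
            if missing:
                raise DataValidationError(f"probes absent from matrix: {missing}")
            values = values.loc[list(probe_ids)]
        if sample_ids is not None:
            missing = sorted(set(sample_ids) - set(values.columns))
            if missing:
                raise DataValidationError(f"samples absent from matrix: {missing}")
            values = values[list(sample_ids)]
        return MethylationMatrix(values=values.copy(), scale=self.scale)


def _validate_sheet(records: Sequence[SampleRecord]) -> None:
    seen: dict[tuple[str, str], str] = {}
    for rec in records:
        key = (rec.child_id, rec.timepoint)
        if key in seen:
            raise DataValidationError(
                f"duplicated (child_id, timepoint): {key} in samples "
                f"{seen[key]} and {rec.sample_id}"
            )
        seen[key] = rec.sample_id
    sample_ids = [r.sample_id for r in records]
    if len(set(sample_ids)) != len(sample_ids):
        raise DataValidationError("duplicated sample_id values in sheet")


def read_sample_sheet(path: PathLike) -> list[SampleRecord]:
    """Read and validate a tab-delimited sample sheet.

    Raises :class:`SchemaError` when a mandatory column is missing and
    :class:`DataValidationError` for bad labels or duplicate
    (child, timepoint) pairs, naming the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    missing = [c for c in _SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    cf_cols = [c for c in df.columns if c.startswith("cf_")]

    records: list[SampleRecord] = []
    for i, row in df.iterrows():
        rownum = i + 2  # 1-based, after header
        try:
            cf = None
            if cf_cols and all(row[c] != "NA" for c in cf_cols):
                cf = {c[3:]: float(row[c]) for c in cf_cols}
            records.append(SampleRecord(
                sample_id=row["sample_id"],
                child_id=row["child_id"],
                timepoint=row["timepoint"],
                conception=row["conception"],
                sex=row["sex"],
                child_age=None if row["child_age"] == "NA" else float(row["child_age"]),
                multiple_birth=_parse_bool(row["multiple_birth"]),
                twin_pair_id=None if row["twin_pair_id"] == "NA" else row["twin_pair_id"],
                maternal_age=float(row["maternal_age"]),
                smoking=row["smoking"],
                bmi_category=None if row["bmi_category"] == "NA" else row["bmi_category"],
                parity=int(row["parity"]),
                plate_id=row["plate_id"],
                cell_fractions=cf,
            ))
        except (DataValidationError, ValueError) as exc:
            raise DataValidationError(f"{path}, row {rownum}: {exc}") from exc
    _validate_sheet(records)
    logger.info("read %d sample records from %s", len(records), path)
    return records


def _parse_bool(text: str) -> bool:
    if text in ("True", "true", "1"):
        return True
    if text in ("False", "false", "0"):
        return False
    raise ValueError(f"cannot parse boolean from {text!r}")


def write_sample_sheet(records: Sequence[SampleRecord], path: PathLike) -> None:
    _validate_sheet(records)
    cf_names: list[str] = []
    for rec in records:
        if rec.cell_fractions:
            for name in rec.cell_fractions:
                if name not in cf_names:
                    cf_names.append(name)
    rows = []
    for rec in records:
        row = {
            "sample_id": rec.sample_id,
            "child_id": rec.child_id,
            "timepoint": rec.timepoint,
            "conception": rec.conception,
            "sex": rec.sex,
            "child_age": "NA" if rec.child_age is None else f"{rec.child_age:.4f}",
            "multiple_birth": str(rec.multiple_birth),
            "twin_pair_id": rec.twin_pair_id or "NA",
            "maternal_age": f"{rec.maternal_age:.4f}",
            "smoking": rec.smoking,
            "bmi_category": rec.bmi_category or "NA",
            "parity": str(rec.parity),
            "plate_id": rec.plate_id,
        }
        for name in cf_names:
            cf = rec.cell_fractions or {}
            row[f"cf_{name}"] = f"{cf[name]:.6f}" if name in cf else "NA"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_matrix(path: PathLike, scale: str) -> MethylationMatrix:
    """Read a probes x samples matrix (probe IDs in the first column).

    ``scale`` declares how the stored numbers are to be interpreted;
    beta values outside the open unit interval are rejected because the
    M-value transform is undefined there.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{path}: {exc}") from exc
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise SchemaError(f"{path}: ragged or non-numeric rows at probes {bad}")
    return MethylationMatrix(values=df.astype(float), scale=scale)


def write_matrix(matrix: MethylationMatrix, path: PathLike) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="probe_id",
                         float_format="%.12g")


def read_manifest(path: PathLike) -> list[ProbeAnnotation]:
    """Read a probe manifest, returning annotations sorted by position."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    required = ["probe_id", "chromosome", "position"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing manifest columns {missing}")
    if df.empty:
        logger.warning("manifest %s contains no probes", path)
        return []
    probes = []
    for i, row in df.iterrows():
        try:
            pos = int(row["position"])
        except ValueError as exc:
            raise SchemaError(
                f"{path}, row {i + 2}: non-integer position {row['position']!r}"
            ) from exc
        probes.append(ProbeAnnotation(
            probe_id=row["probe_id"],
            chromosome=row["chromosome"],
            position=pos,
            regulatory_feature="" if row.get("regulatory_feature", "") == "NA"
            else row.get("regulatory_feature", ""),
            island_relation=row.get("island_relation", ""),
            gene=row.get("gene", ""),
        ))
    probes.sort(key=lambda p: (p.chromosome, p.position))
    return probes


def write_manifest(probes: Sequence[ProbeAnnotation], path: PathLike) -> None:
    rows = [{
        "probe_id": p.probe_id,
        "chromosome": p.chromosome,
        "position": p.position,
        "regulatory_feature": p.regulatory_feature or "NA",
        "island_relation": p.island_relation,
        "gene": p.gene,
    } for p in probes]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_default_manifest() -> list[ProbeAnnotation]:
    """The bundled 25-probe BRCA1/NBR2 promoter manifest (hg19)."""
    text = resources.files("methylong.data").joinpath(
        "brca1_nbr2_manifest.tsv").read_text(encoding="utf-8")
    return read_manifest(io.StringIO(text))


def samples_at(records: Sequence[SampleRecord], timepoint: str) -> list[SampleRecord]:
    """Subset a sheet to one timepoint."""
    if timepoint not in TIMEPOINTS:
        raise DataValidationError(f"unknown timepoint {timepoint!r}")
    return [r for r in records if r.timepoint == timepoint]


__all__ = [
    "MethylationMatrix", "ProbeAnnotation", "SampleRecord",
    "load_default_manifest", "read_manifest", "read_matrix",
    "read_sample_sheet", "samples_at", "write_manifest", "write_matrix",
    "write_sample_sheet", "replace",
]
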