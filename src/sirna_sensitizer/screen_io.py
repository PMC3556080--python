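"""Reading, validation and writing of plate-screen measurement tables.

The canonical on-disk format is a long (tidy) CSV with one row per well:
``plate_id, well, gene, sirna_id, condition, drug, raw_value`` and an optional
``plate_pair`` column linking each drug plate to its vehicle plate.  Well
labels are normalized to zero-padded form (A1 -> A01) so they sort stably.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .synthetic import GL2_LABEL

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["plate_id", "well", "gene", "sirna_id", "condition", "drug", "raw_value"]
_WELL_RE = re.compile(r"^([A-Za-z]+)0*(\d+)$")


class ScreenFormatError(ValueError):
    """Fatal structural problem in a plate table or screen design."""


@dataclass
class ScreenDesign:
    """Declared layout of a screen: targets, their siRNAs, controls, drug arms."""

    genes: Sequence[str]
    sirnas_per_gene: Mapping[str, Sequence[str]] = field(default_factory=dict)
    control_label: str = GL2_LABEL
    drug_arms: Sequence[str] = ()

    def known_units(self) -> set[tuple[str, str]]:
        units = {(self.control_label, self.control_label)}
        for gene in self.genes:
            units.add((gene, "pooled"))
            for sirna in self.sirnas_per_gene.get(gene, ()):
                units.add((gene, sirna))
        return units


def normalize_well(label: str) -> str:
    """Zero-pad the column part of a well coordinate: ``A1`` -> ``A01``."""
    m = _WELL_RE.match(str(label).strip())
    if not m:
        raise ScreenFormatError(f"unparseable well label {label!r}")
    return f"{m.group(1).upper()}{int(m.group(2)):02d}"


def _validate_frame(df: pd.DataFrame, control_label: str) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ScreenFormatError(f"missing required columns: {missing}")
    df = df.copy()
    df["drug"] = df["drug"].fillna("").astype(str)
    df["well"] = df["well"].map(normalize_well)

    bad_value = ~(pd.to_numeric(df["raw_value"], errors="coerce") > 0)
    for _, row in df[bad_value].iterrows():
        logger.warning(
            "rejecting well %s/%s: non-positive raw_value %r",
            row["plate_id"], row["well"], row["raw_value"],
        )
    df = df[~bad_value].copy()
    df["raw_value"] = df["raw_value"].astype(float)

    dupes = df.duplicated(subset=["plate_id", "well"])
    if dupes.any():
        raise ScreenFormatError(
            f"duplicate (plate_id, well) rows: {df.loc[dupes, ['plate_id', 'well']].values.tolist()}"
        )
    bad_vehicle = (df["condition"] == "vehicle") & (df["drug"] != "")
    if bad_vehicle.any():
        raise ScreenFormatError("vehicle wells must have an empty drug field")

    gl2_per_plate = (
        df.assign(is_gl2=df["gene"] == control_label).groupby("plate_id")["is_gl2"].sum()
    )
    plates_without = gl2_per_plate[gl2_per_plate == 0].index.tolist()
    if plates_without:
        raise ScreenFormatError(f"plates with zero {control_label} wells: {plates_without}")
    return df.reset_index(drop=True)


def read_plate_table(
    path, design: ScreenDesign | None = None, control_label: str | None = None
) -> pd.DataFrame:
    """Read and validate a long-format plate CSV.

    Rows with non-positive raw values are rejected and logged; structural
    problems (missing columns, duplicate wells, plates without control wells)
    are fatal.
    """
    label = control_label or (design.control_label if design else GL2_LABEL)
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str, "gene": str,
                                  "sirna_id": str, "condition": str, "drug": str})
    df = _validate_frame(df, label)
    if design is not None:
        report = validate_design(df, design)
        if report.fatal:
            raise ScreenFormatError("; ".join(report.fatal))
    return df


def write_plate_table(df: pd.DataFrame, path) -> None:
    cols = REQUIRED_COLUMNS + (["plate_pair"] if "plate_pair" in df.columns else [])
    df.to_csv(path, index=False, columns=cols)


def plate_pairs(measurements: pd.DataFrame) -> dict[str, tuple[str | None, str | None]]:
    """Map pair id -> (vehicle plate, drug plate).

    Uses the explicit ``plate_pair`` column when present; otherwise vehicle and
    drug plates are paired in sorted plate order within each drug arm.
    """
    df = measurements
    pairs: dict[str, tuple[str | None, str | None]] = {}
    if "plate_pair" in df.columns:
        for pair_id, sub in df.groupby("plate_pair"):
            vehicle = sub.loc[sub["condition"] == "vehicle", "plate_id"].unique()
            drug = sub.loc[sub["condition"] == "drug", "plate_id"].unique()
            pairs[str(pair_id)] = (
                vehicle[0] if len(vehicle) else None,
                drug[0] if len(drug) else None,
            )
        return pairs
    for drug_label, sub in df[df["condition"] == "drug"].groupby("drug"):
        drug_plates = sorted(sub["plate_id"].unique())
        vehicle_plates = sorted(df.loc[df["condition"] == "vehicle", "plate_id"].unique())
        for i, dp in enumerate(drug_plates):
            vp = vehicle_plates[i] if i < len(vehicle_plates) else None
            pairs[f"{drug_label}_{i + 1}"] = (vp, dp)
    return pairs


@dataclass
class DesignReport:
    """Outcome of checking measurements against a declared design."""

    unmatched_units: list[tuple[str, str]]
    gl2_wells_per_plate: dict[str, int]
    pairing: dict[str, tuple[str | None, str | None]]
    fatal: list[str]
    warnings: list[str]

    @property
    def ok(self) -> bool:
        return not self.fatal


def validate_design(measurements: pd.DataFrame, design: ScreenDesign) -> DesignReport:
    """Check unit coverage, control-well counts and vehicle/drug plate pairing."""
    known = design.known_units()
    observed = set(map(tuple, measurements[["gene", "sirna_id"]].drop_duplicates().values))
    unmatched = sorted(u for u in observed if u not in known)

    gl2_counts = (
        measurements.assign(is_gl2=measurements["gene"] == design.control_label)
        .groupby("plate_id")["is_gl2"]
        .sum()
        .astype(int)
        .to_dict()
    )
    fatal: list[str] = []
    warnings: list[str] = []
    for plate, n in gl2_counts.items():
        if n == 0:
            fatal.append(f"plate {plate} has no {design.control_label} wells")

    pairing = plate_pairs(measurements)
    for pair_id, (vehicle, drug) in pairing.items():
        if drug is not None and vehicle is None:
            fatal.append(f"drug plate {drug} ({pair_id}) has no paired vehicle plate")
        elif vehicle is not None and drug is None:
            warnings.append(f"vehicle plate {vehicle} ({pair_id}) has no drug plate")
    if unmatched:
        warnings.append(f"{len(unmatched)} (gene, sirna) units not in the design")
    return DesignReport(
        unmatched_units=unmatched,
        gl2_wells_per_plate=gl2_counts,
        pairing=pairing,
        fatal=fatal,
        warnings=warnings,
    )
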