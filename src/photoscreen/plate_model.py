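"""Data model and I/O for 96-well microplate absorbance experiments.

Everything downstream (dosimetry checks, the DMA singlet-oxygen assay, the
photo-cytotoxicity fits) consumes the :class:`PlateDataset` built here.  The
on-disk representation is deliberately plain: two long-format CSVs, one row
per well role and one row per (well, wavelength, cumulative dose) reading,
so that fixtures stay diff-able and vendor-neutral.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from math import sqrt
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

ROWS = "ABCDEFGH"
N_COLS = 12

#: Assay arms a well can carry.  ``dma_probe`` is DMA + extract, the scoring
#: arm; the three companion arms are the absorption / quencher controls the
#: assay requires per extract.
ARMS = (
    "dma_probe",
    "extract_alone",
    "dma_plus_quencher",
    "extract_plus_quencher",
    "solvent_control",
    "reference_ps",
    "cytotox_dark",
    "cytotox_irradiated",
    "untreated_control",
    "blank",
)

_WELL_RE = re.compile(r"^([A-Ha-h])(\d{1,2})$")


class PlateParseError(ValueError):
    """Malformed plate file content (bad coordinate, missing column...)."""


class PlateValidationError(ValueError):
    """Structurally parseable input that violates a dataset invariant."""


def parse_well(coord: str) -> tuple[int, int]:
    """Parse ``"B7"`` into 0-based ``(row, col)``; raise on out-of-grid."""
    m = _WELL_RE.match(str(coord).strip())
    if not m:
        raise PlateParseError(f"malformed well coordinate {coord!r}")
    row = ROWS.index(m.group(1).upper())
    col = int(m.group(2))
    if not 1 <= col <= N_COLS:
        raise PlateParseError(f"well {coord!r}: column {col} outside 1..{N_COLS}")
    return row, col - 1


def format_well(row: int, col: int) -> str:
    """Inverse of :func:`parse_well` (0-based indices -> ``"A1"`` style)."""
    if not (0 <= row < len(ROWS) and 0 <= col < N_COLS):
        raise ValueError(f"indices ({row}, {col}) outside the 8x12 grid")
    return f"{ROWS[row]}{col + 1}"


def all_wells() -> list[str]:
    """All 96 coordinates in row-major order (A1..A12, B1..H12)."""
    return [format_well(r, c) for r in range(len(ROWS)) for c in range(N_COLS)]


@dataclass(frozen=True)
class WellRole:
    """What a single well contains and which assay arm it belongs to."""

    sample_id: str
    arm: str
    concentration: Optional[float] = None  # ug/mL, cytotox arms only
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise PlateValidationError(
                f"unknown arm {self.arm!r}; expected one of {ARMS}"
            )
        if self.replicate < 1:
            raise PlateValidationError("replicate must be >= 1")
        if self.arm in ("cytotox_dark", "cytotox_irradiated"):
            if self.concentration is None or self.concentration <= 0:
                raise PlateValidationError(
                    f"cytotox arm for {self.sample_id!r} requires a positive "
                    "concentration"
                )


@dataclass
class PlateLayout:
    """Map from well coordinate to :class:`WellRole` for one plate."""

    plate_id: str
    wells: dict[str, WellRole]

    def __post_init__(self) -> None:
        canonical: dict[str, WellRole] = {}
        for coord, role in self.wells.items():
            r, c = parse_well(coord)  # raises on bad coordinate
            key = format_well(r, c)
            if key in canonical:
                raise PlateValidationError(f"duplicate well {key} in layout")
            canonical[key] = role
        self.wells = canonical

    def wells_for(self, sample_id: str, arm: str) -> list[str]:
        return sorted(
            w
            for w, role in self.wells.items()
            if role.sample_id == sample_id and role.arm == arm
        )

    def wells_by_arm(self, arm: str) -> list[str]:
        return sorted(w for w, role in self.wells.items() if role.arm == arm)

    def sample_ids(self, arm: str = "dma_probe") -> list[str]:
        seen: list[str] = []
        for role in self.wells.values():
            if role.arm == arm and role.sample_id not in seen:
                seen.append(role.sample_id)
        return seen

    def require_dma_controls(self) -> None:
        """DMA scoring needs at least one solvent control and one reference PS."""
        missing = [
            arm
            for arm in ("solvent_control", "reference_ps")
            if not self.wells_by_arm(arm)
        ]
        if missing:
            raise PlateValidationError(
                "layout lacks required DMA control arm(s): " + ", ".join(missing)
            )


@dataclass(frozen=True)
class AbsorbanceRecord:
    """One plate-reader reading: OD of one well at one wavelength and dose."""

    well: str
    wavelength: float  # nm
    cumulative_dose: float  # J/cm^2
    od: float

    def __post_init__(self) -> None:
        if not 200 <= self.wavelength <= 1000:
            raise PlateValidationError(
                f"wavelength {self.wavelength} nm outside 200-1000 nm"
            )
        if self.cumulative_dose < 0:
            raise PlateValidationError("cumulative_dose must be >= 0")


_READING_COLS = ["well", "wavelength_nm", "cumulative_dose_J_cm2", "od"]
_LAYOUT_COLS = ["well", "sample_id", "arm", "concentration_ug_per_ml", "replicate"]


@dataclass
class PlateDataset:
    """A validated plate: layout + readings (+ optional irradiation schedule).

    ``records`` is held as a long-format DataFrame with columns
    ``well, wavelength_nm, cumulative_dose_J_cm2, od``.
    """

    layout: PlateLayout
    records: pd.DataFrame
    schedule: object | None = None  # dosimetry.IrradiationSchedule
    flagged_wells: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records, columns=_READING_COLS).copy()
        df["well"] = [format_well(*parse_well(w)) for w in df["well"]]
        for col in _READING_COLS[1:]:
            df[col] = pd.to_numeric(df[col])
        df = df.sort_values(_READING_COLS[:3], kind="stable").reset_index(drop=True)
        self.records = df
        self.validate()

    def validate(self) -> None:
        df = self.records
        unknown = set(df["well"]) - set(self.layout.wells)
        if unknown:
            raise PlateValidationError(
                f"records reference wells absent from layout: {sorted(unknown)}"
            )
        bad_wl = df[(df["wavelength_nm"] < 200) | (df["wavelength_nm"] > 1000)]
        if len(bad_wl):
            raise PlateValidationError(
                f"wavelengths outside 200-1000 nm in {sorted(set(bad_wl['well']))}"
            )
        if (df["cumulative_dose_J_cm2"] < 0).any():
            raise PlateValidationError("negative cumulative dose in records")
        dup = df.duplicated(subset=_READING_COLS[:3], keep=False)
        if dup.any():
            offenders = df.loc[dup, "well"].unique().tolist()
            raise PlateValidationError(
                f"duplicate (well, wavelength, dose) readings for wells {offenders}"
            )
        # each DMA-probe well must bracket the irradiation: 377 nm at dose 0
        # and at its final cumulative dose
        for well in self.layout.wells_by_arm("dma_probe"):
            sub = df[(df["well"] == well) & (df["wavelength_nm"] == 377)]
            if sub.empty or sub["cumulative_dose_J_cm2"].min() != 0:
                raise PlateValidationError(
                    f"dma_probe well {well} lacks a 377 nm reading at dose 0"
                )

    def trajectory(self, well: str, wavelength: float) -> pd.DataFrame:
        """Dose-ordered readings of one well at one wavelength."""
        sub = self.records[
            (self.records["well"] == well)
            & (self.records["wavelength_nm"] == wavelength)
        ]
        return sub.sort_values("cumulative_dose_J_cm2").reset_index(drop=True)


def aggregate_replicates(values: Iterable[float]) -> tuple[float, float, int]:
    """Mean, standard error (sd/sqrt(n)) and n of replicate measurements.

    A single replicate yields SE = 0 with a warning, so downstream error
    propagation degrades gracefully instead of emitting NaN.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("aggregate_replicates: empty value list")
    n = int(arr.size)
    if n == 1:
        warnings.warn("single replicate: standard error reported as 0", stacklevel=2)
        return float(arr[0]), 0.0, 1
    return float(arr.mean()), float(arr.std(ddof=1) / sqrt(n)), n


def read_layout(path: str | Path, plate_id: str | None = None) -> PlateLayout:
    df = _read_csv(path, _LAYOUT_COLS)
    wells: dict[str, WellRole] = {}
    for i, row in df.iterrows():
        conc = row["concentration_ug_per_ml"]
        conc = None if pd.isna(conc) or conc == "" else float(conc)
        try:
            role = WellRole(
                sample_id=str(row["sample_id"]),
                arm=str(row["arm"]),
                concentration=conc,
                replicate=int(row["replicate"]),
            )
            coord = format_well(*parse_well(row["well"]))
        except (PlateParseError, PlateValidationError) as exc:
            raise type(exc)(f"{Path(path).name}, data row {i + 1}: {exc}") from exc
        if coord in wells:
            raise PlateValidationError(
                f"{Path(path).name}, data row {i + 1}: duplicate well {coord}"
            )
        wells[coord] = role
    return PlateLayout(plate_id=plate_id or Path(path).stem, wells=wells)


def read_plate(
    layout_path: str | Path,
    readings_path: str | Path,
    schedule: object | None = None,
) -> PlateDataset:
    """Load and validate a plate from its layout and readings CSVs."""
    layout = read_layout(layout_path)
    records = _read_csv(readings_path, _READING_COLS)
    return PlateDataset(layout=layout, records=records, schedule=schedule)


def write_plate(
    ds: PlateDataset, layout_path: str | Path, readings_path: str | Path
) -> None:
    rows = []
    for well in sorted(ds.layout.wells, key=parse_well):
        role = ds.layout.wells[well]
        rows.append(
            {
                "well": well,
                "sample_id": role.sample_id,
                "arm": role.arm,
                "concentration_ug_per_ml": (
                    "" if role.concentration is None else role.concentration
                ),
                "replicate": role.replicate,
            }
        )
    pd.DataFrame(rows, columns=_LAYOUT_COLS).to_csv(layout_path, index=False)
    ds.records[_READING_COLS].to_csv(readings_path, index=False)


def blank_correct(ds: PlateDataset, negative_floor: float = -0.01) -> PlateDataset:
    """Subtract the mean blank OD (per wavelength and dose step); drop blanks.

    Wells whose corrected OD falls below ``negative_floor`` are flagged (not
    clamped): small negative ODs are kept as noise diagnostics.  Without any
    blank wells the dataset is returned unchanged with a warning.
    """
    blanks = ds.layout.wells_by_arm("blank")
    if not blanks:
        warnings.warn("no blank wells in layout: blank correction skipped")
        return ds
    df = ds.records.copy()
    is_blank = df["well"].isin(blanks)
    blank_df = df[is_blank]
    if blank_df.empty:
        warnings.warn("blank wells carry no readings: blank correction skipped")
        return ds
    by_step = blank_df.groupby(["wavelength_nm", "cumulative_dose_J_cm2"])["od"].mean()
    by_wl = blank_df.groupby("wavelength_nm")["od"].mean()

    def _blank_for(wl: float, dose: float) -> float:
        if (wl, dose) in by_step.index:
            return float(by_step.loc[(wl, dose)])
        if wl in by_wl.index:
            return float(by_wl.loc[wl])
        warnings.warn(f"no blank reading at {wl} nm: readings left uncorrected")
        return 0.0

    corrected = df[~is_blank].copy()
    corrected["od"] = [
        od - _blank_for(wl, dose)
        for od, wl, dose in zip(
            corrected["od"], corrected["wavelength_nm"], corrected["cumulative_dose_J_cm2"]
        )
    ]
    flagged = sorted(set(corrected.loc[corrected["od"] < negative_floor, "well"]))
    layout = PlateLayout(
        plate_id=ds.layout.plate_id,
        wells={w: r for w, r in ds.layout.wells.items() if w not in blanks},
    )
    return PlateDataset(
        layout=layout,
        records=corrected.reset_index(drop=True),
        schedule=ds.schedule,
        flagged_wells=flagged,
    )


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype={"well": str}, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise PlateParseError(f"{path.name}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PlateParseError(f"{path.name}: missing column(s) {missing}")
    return df
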