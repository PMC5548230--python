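"""Patient-visit data model and CSV cohort I/O.

A cohort is a list of :class:`PhenotypeRecord`, one per patient visit.
Records carry the echocardiographic measurements, binary clinical
features and family/genetic status needed by the Ghent-2 and Kid-SMS
scorers.  The CSV schema is fixed: one snake_case column per field,
header row mandatory, booleans serialized as ``true``/``false`` with the
empty string meaning *absent* (not assessed).  Absent is distinct from
false throughout: optional fields round-trip as absent, and scores that
need them fail loudly (see :mod:`kidsms.errors`).

Units are fixed: diameters in mm, body-surface area in m², age in years.
"""

from __future__ import annotations

import csv
import dataclasses
import math
from dataclasses import dataclass, fields
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Union

from .errors import RowParseError, SchemaError


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class FBN1Status(str, Enum):
    """FBN1 mutation status; ``NOT_TESTED`` is distinct from negative."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    NOT_TESTED = "not_tested"


class Visit(str, Enum):
    BASELINE = "baseline"
    FOLLOW_UP = "follow_up"


@dataclass(frozen=True)
class SystemicItems:
    """The 20-point systemic-score checklist, one boolean per scored row.

    The standard constructor requires every field to be stated
    explicitly; use :meth:`assume_absent` when you deliberately want
    unstated items treated as not present.
    """

    pectus_carinatum: bool
    pectus_excavatum_or_chest_asymmetry: bool
    reduced_us_ls_and_increased_armspan_no_scoliosis: bool
    characteristic_face: bool
    wrist_sign: bool
    thumb_sign: bool
    scoliosis_or_kyphosis: bool
    reduced_elbow_extension: bool
    pes_planus: bool
    hindfoot_deformity: bool
    protrusio_acetabulae: bool
    myopia_gt3_diopters: bool
    mitral_valve_prolapse: bool
    spontaneous_pneumothorax: bool
    striae_atrophicae: bool
    dural_ectasia: bool

    @classmethod
    def assume_absent(cls, **present: bool) -> "SystemicItems":
        """Build an item set with every unstated item explicitly absent."""
        values = {f.name: False for f in fields(cls)}
        for name, value in present.items():
            if name not in values:
                raise TypeError(f"unknown systemic item: {name}")
            values[name] = bool(value)
        return cls(**values)

    def as_dict(self) -> dict[str, bool]:
        return dataclasses.asdict(self)

    def replace(self, **changes: bool) -> "SystemicItems":
        return dataclasses.replace(self, **changes)


#: Field names of :class:`SystemicItems`, in schema order.
SYSTEMIC_ITEM_FIELDS: tuple[str, ...] = tuple(
    f.name for f in fields(SystemicItems)
)


@dataclass(frozen=True)
class PhenotypeRecord:
    """One patient-visit's full feature vector."""

    patient_id: str
    age_years: float
    sex: Sex
    aortic_dissection: bool
    ectopia_lentis: bool
    mitral_valve_prolapse: bool
    tricuspid_valve_prolapse: bool
    family_history_mfs: bool
    fbn1_status: FBN1Status
    systemic_items: SystemicItems
    visit: Visit
    bsa_m2: Optional[float] = None
    sv_diameter_mm: Optional[float] = None
    sv_dilated: Optional[bool] = None
    pa_diameter_mm: Optional[float] = None
    pa_dilated: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if not (math.isfinite(self.age_years) and self.age_years >= 0):
            raise ValueError(f"age_years must be finite and >= 0, got {self.age_years}")
        for name in ("bsa_m2", "sv_diameter_mm", "pa_diameter_mm"):
            value = getattr(self, name)
            if value is not None and not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be strictly positive when present, got {value}")

    def replace(self, **changes) -> "PhenotypeRecord":
        return dataclasses.replace(self, **changes)


_RECORD_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "age_years",
    "sex",
    "bsa_m2",
    "sv_diameter_mm",
    "sv_dilated",
    "aortic_dissection",
    "pa_diameter_mm",
    "pa_dilated",
    "ectopia_lentis",
    "mitral_valve_prolapse",
    "tricuspid_valve_prolapse",
    "family_history_mfs",
    "fbn1_status",
    "visit",
)

#: The full fixed CSV column schema, in order.
COLUMNS: tuple[str, ...] = _RECORD_COLUMNS + SYSTEMIC_ITEM_FIELDS

_BOOL_TOKENS = {"true": True, "false": False}


def _fmt_bool(value: Optional[bool]) -> str:
    if value is None:
        return ""
    return "true" if value else "false"


def _fmt_float(value: Optional[float]) -> str:
    if value is None:
        return ""
    return repr(float(value))


def _parse_bool(cell: str, column: str, row: int) -> bool:
    try:
        return _BOOL_TOKENS[cell.strip().lower()]
    except KeyError:
        raise RowParseError(row, f"column {column!r}: expected true/false, got {cell!r}") from None


def _parse_opt_bool(cell: str, column: str, row: int) -> Optional[bool]:
    if cell.strip() == "":
        return None
    return _parse_bool(cell, column, row)


def _parse_opt_float(cell: str, column: str, row: int) -> Optional[float]:
    if cell.strip() == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise RowParseError(row, f"column {column!r}: expected a number, got {cell!r}") from None


def _parse_enum(cell: str, enum_cls, column: str, row: int):
    try:
        return enum_cls(cell.strip())
    except ValueError:
        valid = ", ".join(e.value for e in enum_cls)
        raise RowParseError(
            row, f"column {column!r}: expected one of {{{valid}}}, got {cell!r}"
        ) from None


def read_cohort(
    path: Union[str, Path], *, allow_extra_columns: bool = False
) -> list[PhenotypeRecord]:
    """Read a cohort CSV into a list of :class:`PhenotypeRecord`.

    Every schema column must be present; unknown columns are rejected
    unless ``allow_extra_columns`` is set.  Empty cells in optional
    columns are preserved as absent (``None``), never coerced to false
    or zero.

    Raises
    ------
    SchemaError
        If the header is missing, lacks a mandatory column, or contains
        an unknown column.
    RowParseError
        If a cell cannot be parsed; the message names the data row.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header row required")
        header = list(reader.fieldnames)
        missing = [c for c in COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
        extra = [c for c in header if c not in COLUMNS]
        if extra and not allow_extra_columns:
            raise SchemaError(f"{path}: unknown column(s): {', '.join(extra)}")

        records: list[PhenotypeRecord] = []
        for row_no, row in enumerate(reader, start=1):
            records.append(_parse_row(row, row_no))
    return records


def _parse_row(row: dict[str, str], row_no: int) -> PhenotypeRecord:
    def cell(column: str) -> str:
        value = row.get(column)
        if value is None:
            raise RowParseError(row_no, f"column {column!r}: missing cell")
        return value

    patient_id = cell("patient_id").strip()
    if not patient_id:
        raise RowParseError(row_no, "column 'patient_id': must be non-empty")
    age = _parse_opt_float(cell("age_years"), "age_years", row_no)
    if age is None:
        raise RowParseError(row_no, "column 'age_years': value required")

    items = SystemicItems(
        **{name: _parse_bool(cell(name), name, row_no) for name in SYSTEMIC_ITEM_FIELDS}
    )
    try:
        return PhenotypeRecord(
            patient_id=patient_id,
            age_years=age,
            sex=_parse_enum(cell("sex"), Sex, "sex", row_no),
            bsa_m2=_parse_opt_float(cell("bsa_m2"), "bsa_m2", row_no),
            sv_diameter_mm=_parse_opt_float(cell("sv_diameter_mm"), "sv_diameter_mm", row_no),
            sv_dilated=_parse_opt_bool(cell("sv_dilated"), "sv_dilated", row_no),
            aortic_dissection=_parse_bool(cell("aortic_dissection"), "aortic_dissection", row_no),
            pa_diameter_mm=_parse_opt_float(cell("pa_diameter_mm"), "pa_diameter_mm", row_no),
            pa_dilated=_parse_opt_bool(cell("pa_dilated"), "pa_dilated", row_no),
            ectopia_lentis=_parse_bool(cell("ectopia_lentis"), "ectopia_lentis", row_no),
            mitral_valve_prolapse=_parse_bool(
                cell("mitral_valve_prolapse"), "mitral_valve_prolapse", row_no
            ),
            tricuspid_valve_prolapse=_parse_bool(
                cell("tricuspid_valve_prolapse"), "tricuspid_valve_prolapse", row_no
            ),
            family_history_mfs=_parse_bool(
                cell("family_history_mfs"), "family_history_mfs", row_no
            ),
            fbn1_status=_parse_enum(cell("fbn1_status"), FBN1Status, "fbn1_status", row_no),
            systemic_items=items,
            visit=_parse_enum(cell("visit"), Visit, "visit", row_no),
        )
    except ValueError as exc:
        raise RowParseError(row_no, str(exc)) from exc


def _record_to_row(record: PhenotypeRecord) -> list[str]:
    row = [
        record.patient_id,
        repr(float(record.age_years)),
        record.sex.value,
        _fmt_float(record.bsa_m2),
        _fmt_float(record.sv_diameter_mm),
        _fmt_bool(record.sv_dilated),
        _fmt_bool(record.aortic_dissection),
        _fmt_float(record.pa_diameter_mm),
        _fmt_bool(record.pa_dilated),
        _fmt_bool(record.ectopia_lentis),
        _fmt_bool(record.mitral_valve_prolapse),
        _fmt_bool(record.tricuspid_valve_prolapse),
        _fmt_bool(record.family_history_mfs),
        record.fbn1_status.value,
        record.visit.value,
    ]
    item_dict = record.systemic_items.as_dict()
    row.extend(_fmt_bool(item_dict[name]) for name in SYSTEMIC_ITEM_FIELDS)
    return row


def write_cohort(records: Iterable[PhenotypeRecord], path: Union[str, Path]) -> None:
    """Write records to ``path`` so that :func:`read_cohort` is lossless.

    The CSV round-trip is the identity on the record list: order
    preserved, every field compared equal, absent fields still absent.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot write an empty cohort")
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(COLUMNS)
        for record in records:
            writer.writerow(_record_to_row(record))
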