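"""User-editable radiobiological parameter / dose-volume constraint database.

The database is a single tab-separated text file (comment lines start
with ``#``) holding two record types in one table: ``parameter`` rows
(per-tissue radiobiology: alpha/beta, and either the tumor pair
(alpha, clonogen number) or the LKB triple (TD50(1), m, n)) and
``constraint`` rows (per-organ dose-volume limits expressed at 2 Gy per
fraction).  Unknown columns are preserved verbatim through a
load -> save round trip so users can annotate freely.

Constraint conversion to a new fraction count is BED-preserving and is
applied at the constraint's own dose level: the limit dose defines its
own dose per fraction at the new schedule (``d_c`` solving
``n*d_c*(1+d_c/ab) = BED(limit @ 2 Gy/fx)``), which is the only reading
under which each DV point converts independently of the prescription.

The shipped default database carries illustrative, literature-style
placeholder values for the usual pelvic / head & neck / thoracic organs.
They are NOT clinically validated — the file header says so — and exist
so the package is exercisable out of the box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import DBFormatError, ParameterError
from .io import _fmt
from .lqm import SIBPrescription, bed, isobed_dose_per_fraction

__all__ = [
    "ConstraintPoint",
    "ParameterRecord",
    "ConstraintDB",
    "load_db",
    "save_db",
    "default_db_path",
    "convert_constraint",
    "constraint_report",
]

_COLUMNS = [
    "record",
    "name",
    "kind",
    "alpha_beta_gy",
    "alpha_per_gy",
    "clonogen_number",
    "td50_whole_gy",
    "slope_m",
    "volume_exponent",
    "volume",
    "volume_unit",
    "limit_dose_2gy_gy",
    "endpoint",
    "citation",
]


@dataclass(frozen=True)
class ConstraintPoint:
    """An OAR dose-volume limit at 2 Gy per fraction.

    ``volume_value`` is a fraction of the organ in (0, 1] when
    ``volume_unit='fraction'``, or an absolute volume in cc.
    """

    organ: str
    volume_value: float
    volume_unit: str  # 'fraction' | 'cc'
    limit_dose_2gy: float
    endpoint: str = ""
    citation_tag: str = ""

    def __post_init__(self) -> None:
        if not self.limit_dose_2gy > 0:
            raise ParameterError(f"limit_dose_2gy must be > 0, got {self.limit_dose_2gy}")
        if self.volume_unit not in ("fraction", "cc"):
            raise ParameterError(f"volume_unit must be 'fraction' or 'cc', got {self.volume_unit!r}")
        if self.volume_unit == "fraction" and not 0 < self.volume_value <= 1:
            raise ParameterError(
                f"fractional volume must lie in (0, 1], got {self.volume_value}"
            )
        if self.volume_unit == "cc" and not self.volume_value > 0:
            raise ParameterError(f"absolute volume must be > 0, got {self.volume_value}")


@dataclass(frozen=True)
class ParameterRecord:
    """Radiobiological parameters for one tissue (tumor or OAR)."""

    tissue: str
    kind: str  # 'tumor' | 'oar'
    alpha_beta: float
    alpha: float | None = None
    clonogen_number: float | None = None
    td50_whole: float | None = None
    slope_m: float | None = None
    volume_exponent: float | None = None
    citation_tag: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("tumor", "oar"):
            raise ParameterError(f"kind must be 'tumor' or 'oar', got {self.kind!r}")
        if not (self.alpha_beta > 0 and math.isfinite(self.alpha_beta)):
            raise ParameterError(f"alpha_beta must be > 0, got {self.alpha_beta}")
        required = ("alpha", "clonogen_number") if self.kind == "tumor" else (
            "td50_whole", "slope_m", "volume_exponent"
        )
        for name in required:
            v = getattr(self, name)
            if v is not None and not (v > 0 and math.isfinite(v)):
                raise ParameterError(f"{name} must be > 0, got {v}")
        if self.kind == "oar" and self.volume_exponent is not None and self.volume_exponent > 1:
            raise ParameterError("volume_exponent must be in (0, 1]")


@dataclass
class ConstraintDB:
    """In-memory parameter + constraint database."""

    parameters: list[ParameterRecord] = field(default_factory=list)
    constraints: list[ConstraintPoint] = field(default_factory=list)
    #: extra (unknown) columns, preserved through save: column -> row values
    extra_columns: dict[str, list[str]] = field(default_factory=dict)
    #: per-row extras aligned with parameters + constraints order
    _extras: list[dict[str, str]] = field(default_factory=list)

    def parameter_for(self, tissue: str, kind: str | None = None) -> ParameterRecord | None:
        t = tissue.strip().lower()
        for rec in self.parameters:
            if rec.tissue.strip().lower() == t and (kind is None or rec.kind == kind):
                return rec
        return None

    def constraints_for(self, organ: str) -> list[ConstraintPoint]:
        o = organ.strip().lower()
        return [c for c in self.constraints if c.organ.strip().lower() == o]


def default_db_path() -> Path:
    """Path of the shipped (illustrative, non-clinical) default database."""
    return Path(str(resources.files("radbed").joinpath("data/default_db.tsv")))


def _opt(val: str, line_no: int, col: str) -> float | None:
    if val == "":
        return None
    try:
        return float(val)
    except ValueError:
        raise DBFormatError(f"line {line_no}: column {col!r} is not a number: {val!r}")


def load_db(path: str | Path) -> ConstraintDB:
    """Load a database file; malformed rows abort with line-numbered errors."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    header: list[str] | None = None
    db = ConstraintDB()
    errors: list[tuple[int, str]] = []
    rows: list[tuple[int, dict[str, str]]] = []
    for ln_no, raw in enumerate(lines, start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        cells = raw.split("\t")
        if header is None:
            header = [c.strip() for c in cells]
            missing = [c for c in ("record", "name") if c not in header]
            if missing:
                raise DBFormatError(f"line {ln_no}: header lacks columns {missing}")
            continue
        if len(cells) > len(header):
            errors.append((ln_no, f"expected <= {len(header)} columns, got {len(cells)}"))
            continue
        cells = cells + [""] * (len(header) - len(cells))  # trailing empties may be trimmed
        rows.append((ln_no, dict(zip(header, (c.strip() for c in cells)))))
    if header is None:
        raise DBFormatError(f"{path}: no header row")

    extra_cols = [c for c in header if c not in _COLUMNS]
    for ln_no, row in rows:
        try:
            record = row.get("record", "")
            if record == "parameter":
                db.parameters.append(
                    ParameterRecord(
                        tissue=row["name"],
                        kind=row.get("kind", ""),
                        alpha_beta=_opt(row.get("alpha_beta_gy", ""), ln_no, "alpha_beta_gy") or 0.0,
                        alpha=_opt(row.get("alpha_per_gy", ""), ln_no, "alpha_per_gy"),
                        clonogen_number=_opt(row.get("clonogen_number", ""), ln_no, "clonogen_number"),
                        td50_whole=_opt(row.get("td50_whole_gy", ""), ln_no, "td50_whole_gy"),
                        slope_m=_opt(row.get("slope_m", ""), ln_no, "slope_m"),
                        volume_exponent=_opt(row.get("volume_exponent", ""), ln_no, "volume_exponent"),
                        citation_tag=row.get("citation", ""),
                    )
                )
            elif record == "constraint":
                db.constraints.append(
                    ConstraintPoint(
                        organ=row["name"],
                        volume_value=_opt(row.get("volume", ""), ln_no, "volume") or 0.0,
                        volume_unit=row.get("volume_unit", "fraction"),
                        limit_dose_2gy=_opt(row.get("limit_dose_2gy_gy", ""), ln_no, "limit_dose_2gy_gy") or 0.0,
                        endpoint=row.get("endpoint", ""),
                        citation_tag=row.get("citation", ""),
                    )
                )
            else:
                raise DBFormatError(f"unknown record type {record!r}")
            db._extras.append({c: row.get(c, "") for c in extra_cols})
        except (DBFormatError, ParameterError, KeyError) as exc:
            errors.append((ln_no, str(exc)))
    if errors:
        detail = "; ".join(f"line {n}: {m}" for n, m in errors)
        raise DBFormatError(f"{path}: {len(errors)} malformed row(s): {detail}", errors)
    db.extra_columns = {c: [e[c] for e in db._extras] for c in extra_cols}
    return db


def _param_row(rec: ParameterRecord) -> dict[str, str]:
    def f(v: float | None) -> str:
        return "" if v is None else _fmt(v)

    return {
        "record": "parameter",
        "name": rec.tissue,
        "kind": rec.kind,
        "alpha_beta_gy": _fmt(rec.alpha_beta),
        "alpha_per_gy": f(rec.alpha),
        "clonogen_number": f(rec.clonogen_number),
        "td50_whole_gy": f(rec.td50_whole),
        "slope_m": f(rec.slope_m),
        "volume_exponent": f(rec.volume_exponent),
        "volume": "",
        "volume_unit": "",
        "limit_dose_2gy_gy": "",
        "endpoint": "",
        "citation": rec.citation_tag,
    }


def _constraint_row(c: ConstraintPoint) -> dict[str, str]:
    return {
        "record": "constraint",
        "name": c.organ,
        "kind": "oar",
        "alpha_beta_gy": "",
        "alpha_per_gy": "",
        "clonogen_number": "",
        "td50_whole_gy": "",
        "slope_m": "",
        "volume_exponent": "",
        "volume": _fmt(c.volume_value),
        "volume_unit": c.volume_unit,
        "limit_dose_2gy_gy": _fmt(c.limit_dose_2gy),
        "endpoint": c.endpoint,
        "citation": c.citation_tag,
    }


def save_db(db: ConstraintDB, path: str | Path) -> None:
    """Write a database file; save(load(f)) is byte-stable on the second pass."""
    extra_cols = list(db.extra_columns)
    header = _COLUMNS + extra_cols
    rows = [_param_row(r) for r in db.parameters] + [_constraint_row(c) for c in db.constraints]
    extras = db._extras if len(db._extras) == len(rows) else [{} for _ in rows]
    out = ["\t".join(header)]
    for row, ex in zip(rows, extras):
        out.append("\t".join([row[c] for c in _COLUMNS] + [ex.get(c, "") for c in extra_cols]))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def convert_constraint(
    c: ConstraintPoint, n_fractions_new: int, alpha_beta: float
) -> float:
    """Physical limit dose (Gy) equivalent to ``c`` at a new fraction count.

    BED-preserving: the 2 Gy/fx limit's BED is re-delivered in
    ``n_fractions_new`` fractions at the isoeffective dose per fraction.
    Converting back at the original count recovers the input exactly.
    """
    bed_c = bed(c.limit_dose_2gy, 2.0, alpha_beta)
    d_new = isobed_dose_per_fraction(bed_c, n_fractions_new, alpha_beta)
    return n_fractions_new * d_new


def constraint_report(prescription: SIBPrescription, db: ConstraintDB) -> pd.DataFrame:
    """Per-OAR constraint table converted to the prescription's fractionation.

    Columns: organ, volume, volume_unit, endpoint, alpha_beta_gy,
    limit_2gy_gy, limit_converted_gy, dose_per_fraction_gy, note.  OARs
    whose alpha/beta is missing from the database are flagged in
    ``note`` with NaN doses rather than dropped.
    """
    n_ref = prescription.reference.schedule.n_fractions
    rows = []
    for c in db.constraints:
        rec = db.parameter_for(c.organ, kind="oar")
        if rec is None:
            rows.append(
                dict(
                    organ=c.organ, volume=c.volume_value, volume_unit=c.volume_unit,
                    endpoint=c.endpoint, alpha_beta_gy=float("nan"),
                    limit_2gy_gy=c.limit_dose_2gy, limit_converted_gy=float("nan"),
                    dose_per_fraction_gy=float("nan"),
                    note="no alpha/beta in database",
                )
            )
            continue
        limit_new = convert_constraint(c, n_ref, rec.alpha_beta)
        rows.append(
            dict(
                organ=c.organ, volume=c.volume_value, volume_unit=c.volume_unit,
                endpoint=c.endpoint, alpha_beta_gy=rec.alpha_beta,
                limit_2gy_gy=c.limit_dose_2gy, limit_converted_gy=limit_new,
                dose_per_fraction_gy=limit_new / n_ref, note="",
            )
        )
    if not rows:
        import warnings

        warnings.warn("constraint database is empty", UserWarning, stacklevel=2)
    return pd.DataFrame(
        rows,
        columns=[
            "organ", "volume", "volume_unit", "endpoint", "alpha_beta_gy",
            "limit_2gy_gy", "limit_converted_gy", "dose_per_fraction_gy", "note",
        ],
    )
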