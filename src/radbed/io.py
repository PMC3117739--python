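"""DVH file I/O: a canonical tabular format plus pluggable TPS-style dialects.

Treatment-planning systems export dose-volume histograms in mutually
incompatible text layouts.  This module defines ONE canonical format
(``#radbed-dvh v1``, documented below) that round-trips losslessly, and
a registry of dialect parsers keyed by sniffed header signature.  The
three shipped non-canonical dialects (``eclipse_like``,
``pinnacle_like``, ``brainscan_like``) are synthetic emulations of
typical header-block TPS exports — a structure line, a volume line, a
column table — not byte-accurate grammars of any vendor's files; real
exports vary by version and locale and are out of scope.  New dialects
plug in via :func:`register_dialect`.

Canonical format (text, UTF-8)::

    #radbed-dvh v1
    plan: <label>
    patient: <id>
    n_fractions: <int>
    dose_per_fraction_gy: <float>

    structure: <name>
    volume_cc: <float|NA>
    kind: cumulative|differential
    dose_unit: Gy|cGy
    volume_unit: percent|cc
    <dose>\t<volume>
    ...
    <blank line terminates the block>

Dose axes are stored in Gy internally; cGy input columns are converted
at parse time (the ``source_dose_unit`` flag records the original
unit).  Files are read in place — nothing is copied or cached.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable

import numpy as np

from .errors import DVHFormatError, DVHShapeWarning
from .lqm import Schedule

__all__ = [
    "DVHCurve",
    "Plan",
    "sniff_dialect",
    "read_dvh",
    "write_dvh",
    "write_canonical",
    "import_patient_dir",
    "register_dialect",
    "DIALECTS",
]

CANONICAL_HEADER = "#radbed-dvh v1"

#: Cumulative curves whose first volume deviates from 100 % (or the
#: stated absolute volume) by no more than this relative amount are
#: renormalised; larger deviations are rejected as unsafe.
RENORM_TOLERANCE = 0.005

_VOLUME_MATCH_TOL = 1e-6


def _fmt(x: float) -> str:
    """Shortest exact float representation; parse(fmt(x)) == x, so
    write -> read -> write is a byte fixpoint."""
    return repr(float(x))


# ---------------------------------------------------------------------------
# In-memory model
# ---------------------------------------------------------------------------

@dataclass
class DVHCurve:
    """One structure's dose-volume histogram.

    ``kind='cumulative'``: ``volume[i]`` is the volume receiving at
    least ``dose_gy[i]`` (left-closed); non-increasing, starting at the
    full structure volume.  ``kind='differential'``: ``volume[i]`` is
    the volume in the dose bin centred at ``dose_gy[i]``; non-negative
    and summing to the full volume.  Volumes are either percent of the
    structure volume or absolute cc, per ``volume_unit``.
    """

    structure_name: str
    kind: str  # 'cumulative' | 'differential'
    dose_gy: np.ndarray
    volume: np.ndarray
    volume_unit: str = "percent"  # 'percent' | 'cc'
    total_volume_cc: float | None = None
    source_dose_unit: str = "Gy"  # 'Gy' | 'cGy'

    def __post_init__(self) -> None:
        self.dose_gy = np.asarray(self.dose_gy, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        self.validate()

    # -- derived quantities --------------------------------------------------

    @property
    def full_volume(self) -> float:
        """The structure volume in this curve's own volume unit."""
        if self.volume_unit == "percent":
            return 100.0
        if self.total_volume_cc is not None:
            return float(self.total_volume_cc)
        return float(self.volume[0] if self.kind == "cumulative" else self.volume.sum())

    def validate(self) -> None:
        d, v = self.dose_gy, self.volume
        if self.kind not in ("cumulative", "differential"):
            raise DVHFormatError(f"unknown DVH kind {self.kind!r}")
        if self.volume_unit not in ("percent", "cc"):
            raise DVHFormatError(f"unknown volume unit {self.volume_unit!r}")
        if d.ndim != 1 or v.ndim != 1 or d.shape != v.shape or d.size < 2:
            raise DVHFormatError(
                f"{self.structure_name}: dose and volume must be equal-length "
                f"1-D arrays with >= 2 points"
            )
        if not np.all(np.isfinite(d)) or not np.all(np.isfinite(v)):
            raise DVHFormatError(f"{self.structure_name}: non-finite values")
        if d[0] < 0 or np.any(np.diff(d) <= 0):
            raise DVHFormatError(
                f"{self.structure_name}: dose axis must be >= 0 and strictly increasing"
            )
        if self.total_volume_cc is not None and not self.total_volume_cc > 0:
            raise DVHFormatError(f"{self.structure_name}: total_volume_cc must be > 0")
        full = self.full_volume
        if self.kind == "cumulative":
            if np.any(np.diff(v) > _VOLUME_MATCH_TOL * max(1.0, full)):
                raise DVHFormatError(
                    f"{self.structure_name}: cumulative volumes must be non-increasing"
                )
            if abs(v[0] - full) > _VOLUME_MATCH_TOL * max(1.0, full):
                raise DVHFormatError(
                    f"{self.structure_name}: cumulative curve must start at the "
                    f"full volume ({full:g}), got {v[0]:g}"
                )
            if v[-1] < -_VOLUME_MATCH_TOL:
                raise DVHFormatError(f"{self.structure_name}: negative volume")
        else:
            if np.any(v < -_VOLUME_MATCH_TOL * max(1.0, full)):
                raise DVHFormatError(
                    f"{self.structure_name}: differential volumes must be >= 0"
                )
            if self.volume_unit == "percent" and abs(v.sum() - 100.0) > 0.1:
                raise DVHFormatError(
                    f"{self.structure_name}: differential percent volumes must "
                    f"sum to 100 within 0.1, got {v.sum():g}"
                )

    def copy(self) -> "DVHCurve":
        return replace(self, dose_gy=self.dose_gy.copy(), volume=self.volume.copy())


@dataclass
class Plan:
    """A named set of DVH curves sharing one fractionation schedule."""

    plan_label: str
    patient_id: str
    schedule: Schedule
    curves: dict[str, DVHCurve]
    source_dialect: str = "canonical"

    def __post_init__(self) -> None:
        if not self.curves:
            raise DVHFormatError(f"plan {self.plan_label!r} has no curves")
        for name, c in self.curves.items():
            if name != c.structure_name:
                raise DVHFormatError(
                    f"curve key {name!r} != structure_name {c.structure_name!r}"
                )

    def structures(self) -> list[str]:
        return list(self.curves)


# ---------------------------------------------------------------------------
# Dialect registry and sniffing
# ---------------------------------------------------------------------------

_PARSERS: dict[str, Callable[[str], Plan]] = {}
_WRITERS: dict[str, Callable[[Plan], str]] = {}
_SIGNATURES: dict[str, Callable[[str], bool]] = {}


def register_dialect(
    name: str,
    sniffer: Callable[[str], bool],
    parser: Callable[[str], Plan],
    writer: Callable[[Plan], str] | None = None,
) -> None:
    """Register a DVH dialect: a header sniffer, a parser, optionally a writer."""
    _SIGNATURES[name] = sniffer
    _PARSERS[name] = parser
    if writer is not None:
        _WRITERS[name] = writer


def DIALECTS() -> list[str]:
    return list(_PARSERS)


def sniff_dialect(file_path: str | Path) -> str:
    """Identify the dialect from header signature lines (never the extension)."""
    text = Path(file_path).read_text(encoding="utf-8")
    head = text.lstrip("﻿")
    for name, sig in _SIGNATURES.items():
        if sig(head):
            return name
    first = next((ln for ln in head.splitlines() if ln.strip()), "<empty file>")
    raise DVHFormatError(
        f"{file_path}: unrecognized DVH format (first line: {first!r})"
    )


def read_dvh(file_path: str | Path, dialect: str | None = None) -> Plan:
    """Read a DVH export file into a :class:`Plan` (doses in Gy)."""
    path = Path(file_path)
    if dialect is None:
        dialect = sniff_dialect(path)
    if dialect not in _PARSERS:
        raise DVHFormatError(f"unknown dialect {dialect!r}; known: {DIALECTS()}")
    plan = _PARSERS[dialect](path.read_text(encoding="utf-8"))
    plan.source_dialect = dialect
    if not plan.plan_label:
        plan.plan_label = path.stem
    return plan


def write_dvh(plan: Plan, file_path: str | Path, dialect: str = "canonical") -> None:
    """Write a plan in the given dialect (canonical by default)."""
    if dialect not in _WRITERS:
        raise DVHFormatError(f"no writer for dialect {dialect!r}")
    Path(file_path).write_text(_WRITERS[dialect](plan), encoding="utf-8")


def write_canonical(plan: Plan, file_path: str | Path) -> None:
    write_dvh(plan, file_path, "canonical")


def import_patient_dir(root_dir: str | Path, patient_name: str) -> list[Plan]:
    """Load every recognisable DVH file under ``root_dir/patient_name``.

    Unreadable or unrecognised files are reported via a warning and
    skipped; a missing directory is an error.  Plans come back sorted by
    filename.
    """
    folder = Path(root_dir) / patient_name
    if not folder.is_dir():
        raise FileNotFoundError(f"patient directory not found: {folder}")
    plans: list[Plan] = []
    for path in sorted(p for p in folder.iterdir() if p.is_file()):
        try:
            plans.append(read_dvh(path))
        except (DVHFormatError, UnicodeDecodeError, ValueError) as exc:
            warnings.warn(f"skipping {path.name}: {exc}", DVHShapeWarning, stacklevel=2)
    if not plans:
        warnings.warn(
            f"no readable DVH files under {folder}", DVHShapeWarning, stacklevel=2
        )
    return plans


# ---------------------------------------------------------------------------
# Shared parsing helpers
# ---------------------------------------------------------------------------

def _finalize_curve(
    name: str,
    kind: str,
    dose: list[float],
    volume: list[float],
    dose_unit: str,
    volume_unit: str,
    total_volume_cc: float | None,
) -> DVHCurve:
    """Apply unit conversion and the renormalisation policy, then validate."""
    d = np.asarray(dose, dtype=float)
    v = np.asarray(volume, dtype=float)
    if d.size < 2:
        raise DVHFormatError(f"{name}: fewer than 2 DVH points")
    if dose_unit == "cGy":
        d = d / 100.0
    elif dose_unit != "Gy":
        raise DVHFormatError(f"{name}: unknown dose unit {dose_unit!r}")
    if np.any(np.diff(d) <= 0):
        raise DVHFormatError(f"{name}: non-monotone dose axis")
    full = 100.0 if volume_unit == "percent" else (total_volume_cc or (v[0] if kind == "cumulative" else v.sum()))
    if full <= 0:
        raise DVHFormatError(f"{name}: cannot establish a positive structure volume")
    if kind == "cumulative":
        if v[0] <= 0:
            raise DVHFormatError(f"{name}: cumulative curve starts at volume {v[0]:g}")
        if abs(v[0] - full) > RENORM_TOLERANCE * full:
            raise DVHFormatError(
                f"{name}: first cumulative volume {v[0]:g} deviates from the "
                f"full volume {full:g} by more than {RENORM_TOLERANCE:.1%}"
            )
        if abs(v[0] - full) > 1e-9 * full:  # skip if already normalized (fixpoint)
            v = v * (full / v[0])
            v[0] = full
    else:
        s = v.sum()
        if s <= 0:
            raise DVHFormatError(f"{name}: differential volumes sum to {s:g}")
        if abs(s - full) > RENORM_TOLERANCE * full:
            raise DVHFormatError(
                f"{name}: differential volumes sum to {s:g}, expected {full:g}"
            )
        if abs(s - full) > 1e-9 * full:
            v = v * (full / s)
    return DVHCurve(
        structure_name=name,
        kind=kind,
        dose_gy=d,
        volume=v,
        volume_unit=volume_unit,
        total_volume_cc=total_volume_cc,
        source_dose_unit=dose_unit,
    )


def _parse_float(token: str, context: str) -> float:
    try:
        return float(token)
    except ValueError as exc:
        raise DVHFormatError(f"{context}: not a number: {token!r}") from exc


# ---------------------------------------------------------------------------
# Canonical dialect
# ---------------------------------------------------------------------------

def _parse_canonical(text: str) -> Plan:
    lines = text.splitlines()
    if not lines or lines[0].strip() != CANONICAL_HEADER:
        raise DVHFormatError(f"missing canonical header {CANONICAL_HEADER!r}")
    meta: dict[str, str] = {}
    i = 1
    # plan-level key: value lines until the first blank / structure block
    while i < len(lines):
        ln = lines[i].strip()
        if not ln:
            i += 1
            continue
        if ln.startswith("structure:"):
            break
        if ":" not in ln:
            raise DVHFormatError(f"line {i + 1}: expected 'key: value', got {ln!r}")
        key, _, val = ln.partition(":")
        meta[key.strip()] = val.strip()
        i += 1

    curves: dict[str, DVHCurve] = {}
    while i < len(lines):
        ln = lines[i].strip()
        if not ln:
            i += 1
            continue
        if not ln.startswith("structure:"):
            raise DVHFormatError(f"line {i + 1}: expected 'structure:', got {ln!r}")
        name = ln.partition(":")[2].strip()
        block: dict[str, str] = {}
        i += 1
        for key in ("volume_cc", "kind", "dose_unit", "volume_unit"):
            if i >= len(lines) or not lines[i].strip().startswith(f"{key}:"):
                raise DVHFormatError(f"line {i + 1}: expected '{key}:' in block {name!r}")
            block[key] = lines[i].strip().partition(":")[2].strip()
            i += 1
        dose: list[float] = []
        volume: list[float] = []
        while i < len(lines) and lines[i].strip():
            parts = lines[i].split("\t")
            if len(parts) != 2:
                raise DVHFormatError(f"line {i + 1}: expected two tab-separated columns")
            dose.append(_parse_float(parts[0], f"line {i + 1}"))
            volume.append(_parse_float(parts[1], f"line {i + 1}"))
            i += 1
        total_cc = None if block["volume_cc"] == "NA" else _parse_float(block["volume_cc"], name)
        curve = _finalize_curve(
            name, block["kind"], dose, volume, block["dose_unit"], block["volume_unit"], total_cc
        )
        if name in curves:
            raise DVHFormatError(f"duplicate structure {name!r}")
        curves[name] = curve

    n_fx = int(meta.get("n_fractions", "1"))
    dpf = float(meta.get("dose_per_fraction_gy", "2"))
    return Plan(
        plan_label=meta.get("plan", ""),
        patient_id=meta.get("patient", ""),
        schedule=Schedule.from_fractions(dpf, n_fx),
        curves=curves,
        source_dialect="canonical",
    )


def _write_canonical(plan: Plan) -> str:
    out = [CANONICAL_HEADER]
    out.append(f"plan: {plan.plan_label}")
    out.append(f"patient: {plan.patient_id}")
    out.append(f"n_fractions: {plan.schedule.n_fractions}")
    out.append(f"dose_per_fraction_gy: {_fmt(plan.schedule.dose_per_fraction)}")
    out.append("")
    for name, c in plan.curves.items():
        out.append(f"structure: {name}")
        vol = "NA" if c.total_volume_cc is None else _fmt(c.total_volume_cc)
        out.append(f"volume_cc: {vol}")
        out.append(f"kind: {c.kind}")
        out.append("dose_unit: Gy")  # internal representation is always Gy
        out.append(f"volume_unit: {c.volume_unit}")
        for d, v in zip(c.dose_gy, c.volume):
            out.append(f"{_fmt(d)}\t{_fmt(v)}")
        out.append("")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# eclipse_like dialect (synthetic emulation of a header-block export)
# ---------------------------------------------------------------------------

def _parse_eclipse_like(text: str) -> Plan:
    lines = text.splitlines()
    meta: dict[str, str] = {}
    i = 0
    while i < len(lines) and not lines[i].startswith("Structure:"):
        ln = lines[i].strip()
        if ln and ":" in ln:
            key, _, val = ln.partition(":")
            meta[key.strip()] = val.strip()
        i += 1
    kind = meta.get("DVH Type", "Cumulative").strip().lower()
    if kind not in ("cumulative", "differential"):
        raise DVHFormatError(f"eclipse_like: bad DVH Type {kind!r}")
    n_fx = int(meta.get("Number of Fractions", "1"))
    total = float(meta.get("Prescribed dose [Gy]", "0") or 0)
    dpf = total / n_fx if total > 0 else 2.0

    curves: dict[str, DVHCurve] = {}
    while i < len(lines):
        ln = lines[i].strip()
        if not ln:
            i += 1
            continue
        if not ln.startswith("Structure:"):
            raise DVHFormatError(f"eclipse_like line {i + 1}: expected 'Structure:'")
        name = ln.partition(":")[2].strip()
        i += 1
        total_cc: float | None = None
        if i < len(lines) and lines[i].strip().startswith("Volume [cm3]:"):
            tok = lines[i].strip().partition(":")[2].strip()
            total_cc = None if tok in ("", "NA") else _parse_float(tok, name)
            i += 1
        while i < len(lines) and not lines[i].strip():
            i += 1
        if i >= len(lines) or "Dose [" not in lines[i]:
            raise DVHFormatError(f"eclipse_like line {i + 1}: expected column header")
        header = lines[i]
        dose_unit = "cGy" if "Dose [cGy]" in header else "Gy"
        volume_unit = "percent" if "[%]" in header else "cc"
        i += 1
        dose: list[float] = []
        volume: list[float] = []
        while i < len(lines) and lines[i].strip() and not lines[i].startswith("Structure:"):
            parts = lines[i].split()
            if len(parts) != 2:
                raise DVHFormatError(f"eclipse_like line {i + 1}: expected two columns")
            dose.append(_parse_float(parts[0], f"line {i + 1}"))
            volume.append(_parse_float(parts[1], f"line {i + 1}"))
            i += 1
        curves[name] = _finalize_curve(
            name, kind, dose, volume, dose_unit, volume_unit, total_cc
        )

    return Plan(
        plan_label=meta.get("Plan", ""),
        patient_id=meta.get("Patient Name", ""),
        schedule=Schedule.from_fractions(dpf, n_fx),
        curves=curves,
        source_dialect="eclipse_like",
    )


def _write_eclipse_like(plan: Plan) -> str:
    s = plan.schedule
    kinds = {c.kind for c in plan.curves.values()}
    if len(kinds) != 1:
        raise DVHFormatError("eclipse_like writer needs a single DVH kind per file")
    out = [
        f"Patient Name         : {plan.patient_id}",
        f"Plan                 : {plan.plan_label}",
        f"Prescribed dose [Gy] : {_fmt(s.total_dose)}",
        f"Number of Fractions  : {s.n_fractions}",
        f"DVH Type             : {kinds.pop().capitalize()}",
        "",
    ]
    for name, c in plan.curves.items():
        out.append(f"Structure: {name}")
        if c.total_volume_cc is not None:
            out.append(f"Volume [cm3]: {_fmt(c.total_volume_cc)}")
        unit = "%" if c.volume_unit == "percent" else "cm3"
        out.append(f"Dose [cGy]      Structure Volume [{unit}]")
        for d, v in zip(c.dose_gy, c.volume):
            out.append(f"{100.0 * d:14.4f}  {v:18.6f}")
        out.append("")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# pinnacle_like dialect (synthetic emulation)
# ---------------------------------------------------------------------------

def _parse_pinnacle_like(text: str) -> Plan:
    lines = text.splitlines()
    if not lines or lines[0].strip() != "#PinnDVH":
        raise DVHFormatError("pinnacle_like: missing '#PinnDVH' header")
    meta: dict[str, str] = {}
    i = 1
    while i < len(lines) and not lines[i].startswith("RegionOfInterest:"):
        ln = lines[i].strip()
        if ln and ":" in ln:
            key, _, val = ln.partition(":")
            meta[key.strip()] = val.strip()
        i += 1
    n_fx = int(meta.get("Fractions", "1"))
    dpf = float(meta.get("FractionDose_Gy", "2"))

    curves: dict[str, DVHCurve] = {}
    while i < len(lines):
        ln = lines[i].strip()
        if not ln:
            i += 1
            continue
        if not ln.startswith("RegionOfInterest:"):
            raise DVHFormatError(f"pinnacle_like line {i + 1}: expected RegionOfInterest")
        name = ln.partition(":")[2].strip()
        block: dict[str, str] = {}
        i += 1
        while i < len(lines) and ":" in lines[i] and not lines[i].startswith("RegionOfInterest:"):
            key, _, val = lines[i].strip().partition(":")
            block[key.strip()] = val.strip()
            i += 1
        if i >= len(lines) or not lines[i].strip().startswith("Dose_Gy"):
            raise DVHFormatError(f"pinnacle_like line {i + 1}: expected 'Dose_Gy ...' header")
        volume_unit = "percent" if lines[i].strip().endswith("Volume_pct") else "cc"
        i += 1
        dose: list[float] = []
        volume: list[float] = []
        while i < len(lines) and lines[i].strip() and not lines[i].startswith("RegionOfInterest:"):
            parts = lines[i].split()
            if len(parts) != 2:
                raise DVHFormatError(f"pinnacle_like line {i + 1}: expected two columns")
            dose.append(_parse_float(parts[0], f"line {i + 1}"))
            volume.append(_parse_float(parts[1], f"line {i + 1}"))
            i += 1
        kind = block.get("Mode", "Cumulative").strip().lower()
        tok = block.get("Volume_cc", "NA")
        total_cc = None if tok in ("", "NA") else _parse_float(tok, name)
        curves[name] = _finalize_curve(name, kind, dose, volume, "Gy", volume_unit, total_cc)

    return Plan(
        plan_label=meta.get("Trial", ""),
        patient_id=meta.get("PatientId", ""),
        schedule=Schedule.from_fractions(dpf, n_fx),
        curves=curves,
        source_dialect="pinnacle_like",
    )


def _write_pinnacle_like(plan: Plan) -> str:
    s = plan.schedule
    out = [
        "#PinnDVH",
        f"Trial: {plan.plan_label}",
        f"PatientId: {plan.patient_id}",
        f"Fractions: {s.n_fractions}",
        f"FractionDose_Gy: {_fmt(s.dose_per_fraction)}",
        "",
    ]
    for name, c in plan.curves.items():
        out.append(f"RegionOfInterest: {name}")
        vol = "NA" if c.total_volume_cc is None else _fmt(c.total_volume_cc)
        out.append(f"  Volume_cc: {vol}")
        out.append(f"  Mode: {c.kind.capitalize()}")
        out.append(f"  Points: {c.dose_gy.size}")
        unit = "Volume_pct" if c.volume_unit == "percent" else "Volume_cc"
        out.append(f"  Dose_Gy {unit}")
        for d, v in zip(c.dose_gy, c.volume):
            out.append(f"  {_fmt(d)} {_fmt(v)}")
        out.append("")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# brainscan_like dialect (synthetic emulation, comma-separated)
# ---------------------------------------------------------------------------

def _parse_brainscan_like(text: str) -> Plan:
    lines = text.splitlines()
    if not lines or lines[0].strip() != "BrainDVH Export":
        raise DVHFormatError("brainscan_like: missing 'BrainDVH Export' header")
    meta: dict[str, str] = {}
    i = 1
    while i < len(lines) and not lines[i].startswith("Structure,"):
        parts = lines[i].strip().split(",")
        if len(parts) >= 2:
            meta[parts[0]] = parts[1]
        i += 1
    n_fx = int(meta.get("Fractions", "1"))
    dpf = float(meta.get("FxDose_Gy", "2"))

    curves: dict[str, DVHCurve] = {}
    while i < len(lines):
        ln = lines[i].strip()
        if not ln:
            i += 1
            continue
        if not ln.startswith("Structure,"):
            raise DVHFormatError(f"brainscan_like line {i + 1}: expected 'Structure,...'")
        fields = ln.split(",")
        # Structure,<name>,Volume_ccm,<vol|NA>,Type,<CUMULATIVE|DIFFERENTIAL>,DoseUnit,<Gy|cGy>,VolUnit,<percent|cc>
        if len(fields) != 10:
            raise DVHFormatError(f"brainscan_like line {i + 1}: malformed structure line")
        name = fields[1]
        total_cc = None if fields[3] == "NA" else _parse_float(fields[3], name)
        kind = fields[5].lower()
        dose_unit = fields[7]
        volume_unit = fields[9]
        i += 1
        if i >= len(lines) or not lines[i].startswith("Dose,"):
            raise DVHFormatError(f"brainscan_like line {i + 1}: expected 'Dose,Volume' header")
        i += 1
        dose: list[float] = []
        volume: list[float] = []
        while i < len(lines) and lines[i].strip() and not lines[i].startswith("Structure,"):
            parts = lines[i].strip().split(",")
            if len(parts) != 2:
                raise DVHFormatError(f"brainscan_like line {i + 1}: expected two columns")
            dose.append(_parse_float(parts[0], f"line {i + 1}"))
            volume.append(_parse_float(parts[1], f"line {i + 1}"))
            i += 1
        curves[name] = _finalize_curve(name, kind, dose, volume, dose_unit, volume_unit, total_cc)

    return Plan(
        plan_label=meta.get("Plan", ""),
        patient_id=meta.get("Patient", ""),
        schedule=Schedule.from_fractions(dpf, n_fx),
        curves=curves,
        source_dialect="brainscan_like",
    )


def _write_brainscan_like(plan: Plan) -> str:
    s = plan.schedule
    out = [
        "BrainDVH Export",
        f"Patient,{plan.patient_id}",
        f"Plan,{plan.plan_label}",
        f"Fractions,{s.n_fractions}",
        f"FxDose_Gy,{_fmt(s.dose_per_fraction)}",
    ]
    for name, c in plan.curves.items():
        vol = "NA" if c.total_volume_cc is None else _fmt(c.total_volume_cc)
        out.append(
            f"Structure,{name},Volume_ccm,{vol},Type,{c.kind.upper()},"
            f"DoseUnit,Gy,VolUnit,{c.volume_unit}"
        )
        out.append("Dose,Volume")
        for d, v in zip(c.dose_gy, c.volume):
            out.append(f"{_fmt(d)},{_fmt(v)}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

register_dialect(
    "canonical",
    lambda head: head.splitlines()[0].strip() == CANONICAL_HEADER if head.strip() else False,
    _parse_canonical,
    _write_canonical,
)
register_dialect(
    "eclipse_like",
    lambda head: head.lstrip().startswith("Patient Name"),
    _parse_eclipse_like,
    _write_eclipse_like,
)
register_dialect(
    "pinnacle_like",
    lambda head: head.splitlines()[0].strip() == "#PinnDVH" if head.strip() else False,
    _parse_pinnacle_like,
    _write_pinnacle_like,
)
register_dialect(
    "brainscan_like",
    lambda head: head.splitlines()[0].strip() == "BrainDVH Export" if head.strip() else False,
    _parse_brainscan_like,
    _write_brainscan_like,
)
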