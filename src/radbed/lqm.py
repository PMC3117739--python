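"""Linear-quadratic (LQ) isoeffect mathematics.

The LQ model writes the log cell-surviving fraction after a total dose
``D`` delivered in fractions of size ``d`` as

    ln sf = -alpha * D * (1 + d / (alpha/beta)) = -alpha * BED

where ``BED = D * (1 + d/(alpha/beta))`` is the biologically effective
dose.  Two schedules with equal BED are isoeffective.  Given a target
BED and a fixed number of fractions ``n`` the isoeffective dose per
fraction is the positive root of the quadratic

    n * d * (1 + d / ab) = BED
    =>  d = (ab/2) * (-1 + sqrt(1 + 4*BED/(n*ab)))

This module houses that algebra plus the per-point conversion to the
normalised total dose at 2 Gy per fraction (NTD2, also called EQD2)

    NTD2 = D * (ab + d) / (ab + 2)

and the synthesis of simultaneous-integrated-boost (SIB) prescriptions:
the reference target fixes the fraction number and every other target is
re-solved to keep its own BED.

Repopulation / overall-treatment-time corrections are deliberately out
of scope: the formalism assumes complete inter-fraction repair and no
proliferation, which is adequate for late-responding tissues.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .errors import LQValidityWarning, ParameterError

__all__ = [
    "Schedule",
    "TumorLQParams",
    "TargetPrescription",
    "SIBPrescription",
    "log_surviving_fraction",
    "bed",
    "schedule_bed",
    "isobed_dose_per_fraction",
    "isobed_schedule",
    "ntd2_point",
    "sib_prescription",
]

#: Dose per fraction (Gy) above which LQ applicability is debated; a
#: warning (never an error) is emitted.
LQ_VALIDITY_WARN_GY = 18.0

_REL_TOL = 1e-9


def _check_finite(**values: float) -> None:
    for name, v in values.items():
        if not math.isfinite(v):
            raise ParameterError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class Schedule:
    """A fractionation regime: total dose, dose per fraction, fraction count.

    Invariant: ``total_dose == dose_per_fraction * n_fractions`` to a
    relative tolerance of 1e-9.
    """

    total_dose: float
    dose_per_fraction: float
    n_fractions: int

    def __post_init__(self) -> None:
        _check_finite(
            total_dose=self.total_dose, dose_per_fraction=self.dose_per_fraction
        )
        if self.total_dose < 0:
            raise ParameterError(f"total_dose must be >= 0, got {self.total_dose}")
        if self.dose_per_fraction <= 0:
            raise ParameterError(
                f"dose_per_fraction must be > 0, got {self.dose_per_fraction}"
            )
        n = self.n_fractions
        if not isinstance(n, int) or isinstance(n, bool) or n < 1:
            raise ParameterError(f"n_fractions must be a positive integer, got {n!r}")
        expected = self.dose_per_fraction * n
        if abs(self.total_dose - expected) > _REL_TOL * max(1.0, abs(expected)):
            raise ParameterError(
                f"inconsistent schedule: {self.total_dose} Gy != "
                f"{self.dose_per_fraction} Gy/fx x {n} fx = {expected} Gy"
            )
        if self.dose_per_fraction > LQ_VALIDITY_WARN_GY:
            warnings.warn(
                f"dose per fraction {self.dose_per_fraction:.4g} Gy exceeds "
                f"{LQ_VALIDITY_WARN_GY:.0f} Gy; LQ-model validity is debated "
                "in this range",
                LQValidityWarning,
                stacklevel=3,
            )

    @classmethod
    def from_fractions(cls, dose_per_fraction: float, n_fractions: int) -> "Schedule":
        """Build a schedule from dose per fraction and fraction count."""
        return cls(dose_per_fraction * n_fractions, dose_per_fraction, n_fractions)

    @classmethod
    def from_total(cls, total_dose: float, dose_per_fraction: float) -> "Schedule":
        """Build a schedule from total dose and dose per fraction.

        The fraction count must come out integral (to 1e-9 relative).
        """
        if dose_per_fraction <= 0:
            raise ParameterError("dose_per_fraction must be > 0")
        n = round(total_dose / dose_per_fraction)
        return cls(total_dose, dose_per_fraction, int(n))


@dataclass(frozen=True)
class TumorLQParams:
    """Tumor radiobiology bundle.

    ``alpha`` (1/Gy) and ``clonogen_number`` (the initial number of
    clonogenic cells, N*) are only needed for Poisson TCP; plain BED /
    isoeffect algebra needs ``alpha_beta`` alone.
    """

    alpha_beta: float
    alpha: float | None = None
    clonogen_number: float | None = None

    def __post_init__(self) -> None:
        if not (self.alpha_beta > 0 and math.isfinite(self.alpha_beta)):
            raise ParameterError(f"alpha_beta must be > 0, got {self.alpha_beta}")
        for name in ("alpha", "clonogen_number"):
            v = getattr(self, name)
            if v is not None and not (v > 0 and math.isfinite(v)):
                raise ParameterError(f"{name} must be > 0, got {v}")

    def require_tcp(self) -> None:
        if self.alpha is None or self.clonogen_number is None:
            raise ParameterError(
                "alpha and clonogen_number are required for TCP computation"
            )


@dataclass(frozen=True)
class TargetPrescription:
    """One target's prescription line: label, schedule and alpha/beta (Gy)."""

    label: str
    schedule: Schedule
    alpha_beta: float

    def __post_init__(self) -> None:
        if not (self.alpha_beta > 0 and math.isfinite(self.alpha_beta)):
            raise ParameterError(f"alpha_beta must be > 0, got {self.alpha_beta}")


@dataclass(frozen=True)
class SIBPrescription:
    """An ordered set of target prescriptions with one reference target.

    The reference target determines the fraction number for the whole
    simultaneous-integrated-boost treatment.  More than three targets is
    unusual in clinical use and draws a warning, not an error.
    """

    targets: tuple[TargetPrescription, ...]
    reference_index: int = 0

    def __post_init__(self) -> None:
        targets = tuple(self.targets)
        object.__setattr__(self, "targets", targets)
        if not targets:
            raise ParameterError("SIBPrescription needs at least one target")
        if not 0 <= self.reference_index < len(targets):
            raise ParameterError(
                f"reference_index {self.reference_index} out of range for "
                f"{len(targets)} targets"
            )
        if len(targets) > 3:
            warnings.warn(
                f"{len(targets)} targets given; SIB prescriptions normally "
                "carry at most 3",
                UserWarning,
                stacklevel=3,
            )

    @property
    def reference(self) -> TargetPrescription:
        return self.targets[self.reference_index]


def log_surviving_fraction(
    total_dose: float, dose_per_fraction: float, alpha: float, alpha_beta: float
) -> float:
    """ln sf = -alpha * D * (1 + d/(alpha/beta)); always <= 0."""
    if not (alpha > 0 and math.isfinite(alpha)):
        raise ParameterError(f"alpha must be > 0, got {alpha}")
    return -alpha * bed(total_dose, dose_per_fraction, alpha_beta)


def bed(total_dose: float, dose_per_fraction: float, alpha_beta: float) -> float:
    """Biologically effective dose D * (1 + d/(alpha/beta)), in Gy."""
    _check_finite(
        total_dose=total_dose,
        dose_per_fraction=dose_per_fraction,
        alpha_beta=alpha_beta,
    )
    if alpha_beta <= 0:
        raise ParameterError(f"alpha_beta must be > 0, got {alpha_beta}")
    if total_dose < 0:
        raise ParameterError(f"total_dose must be >= 0, got {total_dose}")
    if dose_per_fraction <= 0:
        raise ParameterError(f"dose_per_fraction must be > 0, got {dose_per_fraction}")
    return total_dose * (1.0 + dose_per_fraction / alpha_beta)


def schedule_bed(schedule: Schedule, alpha_beta: float) -> float:
    """BED of a :class:`Schedule` for a tissue with the given alpha/beta."""
    if schedule.total_dose == 0:
        return 0.0
    return bed(schedule.total_dose, schedule.dose_per_fraction, alpha_beta)


def isobed_dose_per_fraction(
    bed_target: float, n_fractions: int, alpha_beta: float
) -> float:
    """Dose per fraction giving ``bed_target`` in ``n_fractions`` fractions.

    Positive root of ``n*d*(1 + d/ab) = BED``:

        d = (ab/2) * (-1 + sqrt(1 + 4*BED/(n*ab)))

    The negative root is unphysical and never returned.  ``bed_target``
    of exactly 0 returns 0 (degenerate but correct).
    """
    _check_finite(bed_target=bed_target, alpha_beta=alpha_beta)
    if bed_target < 0:
        raise ParameterError(f"bed_target must be >= 0, got {bed_target}")
    if not isinstance(n_fractions, int) or isinstance(n_fractions, bool) or n_fractions < 1:
        raise ParameterError(f"n_fractions must be a positive integer, got {n_fractions!r}")
    if alpha_beta <= 0:
        raise ParameterError(f"alpha_beta must be > 0, got {alpha_beta}")
    if bed_target == 0:
        return 0.0
    d = 0.5 * alpha_beta * (
        -1.0 + math.sqrt(1.0 + 4.0 * bed_target / (n_fractions * alpha_beta))
    )
    if d > LQ_VALIDITY_WARN_GY:
        warnings.warn(
            f"isoeffective dose per fraction {d:.4g} Gy exceeds "
            f"{LQ_VALIDITY_WARN_GY:.0f} Gy; LQ-model validity is debated",
            LQValidityWarning,
            stacklevel=2,
        )
    return d


def isobed_schedule(bed_target: float, n_fractions: int, alpha_beta: float) -> Schedule:
    """Schedule delivering ``bed_target`` in ``n_fractions`` fractions."""
    d = isobed_dose_per_fraction(bed_target, n_fractions, alpha_beta)
    if d == 0.0:
        raise ParameterError("bed_target of 0 has no valid Schedule (d must be > 0)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", LQValidityWarning)  # already warned above
        return Schedule.from_fractions(d, n_fractions)


def ntd2_point(dose: float, dose_per_fraction: float, alpha_beta: float) -> float:
    """Normalised total dose at 2 Gy/fraction: NTD2 = D*(ab + d)/(ab + 2).

    The unique total dose delivered at 2 Gy per fraction with the same
    BED as ``(dose, dose_per_fraction)``.  ``dose_per_fraction`` may be
    0 only together with zero dose.
    """
    _check_finite(dose=dose, dose_per_fraction=dose_per_fraction, alpha_beta=alpha_beta)
    if alpha_beta <= 0:
        raise ParameterError(f"alpha_beta must be > 0, got {alpha_beta}")
    if dose < 0:
        raise ParameterError(f"dose must be >= 0, got {dose}")
    if dose_per_fraction < 0 or (dose_per_fraction == 0 and dose > 0):
        raise ParameterError(
            f"dose_per_fraction must be > 0 for nonzero dose, got {dose_per_fraction}"
        )
    return dose * (alpha_beta + dose_per_fraction) / (alpha_beta + 2.0)


def sib_prescription(
    prescription: SIBPrescription,
) -> list[tuple[str, Schedule]]:
    """Re-solve every non-reference target at the reference fraction count.

    Returns ``(label, Schedule)`` pairs in input order.  The reference
    target's schedule is passed through unchanged; every other target
    gets the isoeffective dose per fraction for its own alpha/beta at the
    reference ``n_fractions``, so each output schedule has exactly the
    BED of its input schedule.
    """
    ref = prescription.reference
    n_ref = ref.schedule.n_fractions
    out: list[tuple[str, Schedule]] = []
    for i, t in enumerate(prescription.targets):
        if i == prescription.reference_index:
            out.append((t.label, t.schedule))
            continue
        target_bed = schedule_bed(t.schedule, t.alpha_beta)
        out.append((t.label, isobed_schedule(target_bed, n_ref, t.alpha_beta)))
    return out
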