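"""DVH shape conversions, dose statistics and the NTD2-VH transform.

Grid conventions
----------------
A cumulative point ``(D, V)`` means "volume V receives at least dose D"
(left-closed).  A differential bin carries its volume at the midpoint of
the interval between consecutive cumulative grid points; any volume
still present at the last cumulative point becomes a terminal bin at the
maximum dose, so total volume is conserved exactly.

The NTD2 transform maps each bin dose ``D_i`` to the 2 Gy-per-fraction
isoeffective total dose using the bin's own dose per fraction
``d_i = D_i / n_fractions`` (the fraction number is a property of the
schedule, not of the bin); volumes are untouched.  The map
``D -> D*(ab + D/n)/(ab + 2)`` is strictly increasing for non-negative
dose, so curve shape invariants survive the transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DVHShapeWarning, ParameterError, RadbedError
from .io import DVHCurve, Plan, _fmt
from .lqm import ntd2_point

__all__ = [
    "DVHStats",
    "to_differential",
    "to_cumulative",
    "dvh_stats",
    "ntd2_transform",
    "compare_plans",
    "PlanComparison",
]

#: Bins with volume at or below this (in the curve's own volume unit)
#: are ignored when locating min/max/maximum-nonzero dose.
VOLUME_FLOOR = 1e-6

#: The comparison display of the original tool was limited to this many
#: plans; more are processed with a warning.
PLAN_DISPLAY_LIMIT = 5


@dataclass(frozen=True)
class DVHStats:
    """Per-structure dose summary (all doses in Gy)."""

    min_dose: float
    max_dose: float
    mean_dose: float
    median_dose: float
    modal_dose: float
    total_volume: float
    volume_unit: str

    def __post_init__(self) -> None:
        eps = 1e-9 * max(1.0, abs(self.max_dose))
        if not (
            self.min_dose <= self.median_dose + eps
            and self.median_dose <= self.max_dose + eps
            and self.min_dose <= self.modal_dose + eps
            and self.modal_dose <= self.max_dose + eps
            and self.min_dose <= self.mean_dose + eps
            and self.mean_dose <= self.max_dose + eps
        ):
            raise RadbedError("inconsistent DVH statistics (ordering violated)")


def _as_differential(curve: DVHCurve) -> DVHCurve:
    """Differential form without the already-differential warning."""
    if curve.kind == "differential":
        return curve
    return _convert_to_differential(curve)


def _convert_to_differential(curve: DVHCurve) -> DVHCurve:
    d, v = curve.dose_gy, curve.volume
    mids = 0.5 * (d[:-1] + d[1:])
    bins = v[:-1] - v[1:]
    bad = bins < -1e-9 * max(1.0, float(v[0]))
    if np.any(bad):
        raise RadbedError(
            f"{curve.structure_name}: cumulative volumes increase by more than "
            "tolerance; cannot differentiate"
        )
    bins = np.clip(bins, 0.0, None)
    residual = float(v[-1])
    if residual > 0.0:
        # volume still present at the last grid point: terminal bin at D_max
        mids = np.append(mids, d[-1])
        bins = np.append(bins, residual)
    if mids.size < 2:  # degenerate 2-point cumulative with zero tail
        mids = np.append(mids, d[-1])
        bins = np.append(bins, 0.0)
    return replace(curve, kind="differential", dose_gy=mids, volume=bins)


def to_differential(curve: DVHCurve) -> DVHCurve:
    """Cumulative -> differential; conserves total volume exactly.

    Bin ``i`` gets volume ``V(D_i) - V(D_i+1)`` (clamped at 0) at the
    interval midpoint.  Passing an already-differential curve returns a
    copy with a warning.
    """
    if curve.kind == "differential":
        warnings.warn(
            f"{curve.structure_name}: already differential", DVHShapeWarning, stacklevel=2
        )
        return curve.copy()
    return _convert_to_differential(curve)


def cumulative_at(curve: DVHCurve, dose_grid: np.ndarray) -> np.ndarray:
    """Cumulative volume >= each grid dose, from a differential curve."""
    diff = _as_differential(curve)
    d, v = diff.dose_gy, diff.volume
    # V(g) = sum of bin volumes with bin dose >= g; tiny slack for float grids
    tail = np.concatenate([np.cumsum(v[::-1])[::-1], [0.0]])
    idx = np.searchsorted(d, np.asarray(dose_grid, dtype=float) - 1e-12, side="left")
    return tail[idx]


def to_cumulative(curve: DVHCurve, dose_grid: Sequence[float] | None = None) -> DVHCurve:
    """Differential -> cumulative: ``V(D) = sum of bins with dose >= D``.

    By default the output grid is the differential bin-dose axis itself;
    an explicit ``dose_grid`` (e.g. the original cumulative grid)
    reconstructs the source curve exactly.  Passing an
    already-cumulative curve returns a copy with a warning.
    """
    if curve.kind == "cumulative":
        warnings.warn(
            f"{curve.structure_name}: already cumulative", DVHShapeWarning, stacklevel=2
        )
        return curve.copy()
    grid = np.asarray(dose_grid if dose_grid is not None else curve.dose_gy, dtype=float)
    vol = cumulative_at(curve, grid)
    return replace(curve, kind="cumulative", dose_gy=grid, volume=vol)


def dvh_stats(curve: DVHCurve) -> DVHStats:
    """Minimum, maximum, mean, median and modal dose of a DVH.

    Works on either curve kind (converted internally to differential).
    The mean is the volume-weighted bin mean; the median is the
    volume-weighted 50 % quantile with mass-midpoint interpolation (each
    bin's volume treated as centred on its bin dose); the modal dose is
    the bin with the largest volume, ties going to the lowest dose;
    min/max are the extreme bin doses carrying more than the volume
    floor (1e-6).
    """
    diff = _as_differential(curve)
    d, v = diff.dose_gy, diff.volume
    total = float(v.sum())
    nz = v > VOLUME_FLOOR
    if total <= 0 or not np.any(nz):
        raise RadbedError(f"{curve.structure_name}: all DVH volumes are zero")
    min_dose = float(d[nz][0])
    max_dose = float(d[nz][-1])
    mean_dose = float(np.dot(d, v) / total)
    modal_dose = float(d[int(np.argmax(v))])  # argmax -> first = lowest dose on ties
    # mass-midpoint cumulative fractions, ascending in dose
    c = (np.cumsum(v) - 0.5 * v) / total
    median_dose = float(np.interp(0.5, c, d))
    return DVHStats(
        min_dose=min_dose,
        max_dose=max_dose,
        mean_dose=mean_dose,
        median_dose=median_dose,
        modal_dose=modal_dose,
        total_volume=total if diff.volume_unit == "cc" else 100.0,
        volume_unit=diff.volume_unit,
    )


def ntd2_transform(curve: DVHCurve, n_fractions: int, alpha_beta: float) -> DVHCurve:
    """Map every dose ``D_i`` to NTD2 with ``d_i = D_i / n_fractions``.

    Volumes are unchanged; the dose map is strictly monotone so the
    output axis stays strictly increasing.  Works for both curve kinds.
    """
    if not isinstance(n_fractions, int) or isinstance(n_fractions, bool) or n_fractions < 1:
        raise ParameterError(f"n_fractions must be a positive integer, got {n_fractions!r}")
    if not alpha_beta > 0:
        raise ParameterError(f"alpha_beta must be > 0, got {alpha_beta}")
    d = curve.dose_gy
    new_d = d * (alpha_beta + d / n_fractions) / (alpha_beta + 2.0)
    return replace(curve, dose_gy=new_d, volume=curve.volume.copy())


@dataclass
class PlanComparison:
    """Aligned multi-plan comparison for one structure.

    ``table`` has the union dose grid in column ``dose_gy`` and one
    cumulative-volume column per plan label; ``stats`` maps plan label
    to :class:`DVHStats`.
    """

    structure: str
    table: pd.DataFrame
    stats: dict[str, DVHStats]

    def to_tsv(self) -> str:
        lines = ["\t".join(self.table.columns)]
        for row in self.table.itertuples(index=False):
            lines.append("\t".join(_fmt(x) for x in row))
        lines.append("")
        lines.append(
            "# stats\tplan\tmin_gy\tmax_gy\tmean_gy\tmedian_gy\tmodal_gy"
        )
        for label, s in self.stats.items():
            lines.append(
                "#\t" + "\t".join(
                    [label] + [_fmt(x) for x in (s.min_dose, s.max_dose, s.mean_dose, s.median_dose, s.modal_dose)]
                )
            )
        return "\n".join(lines) + "\n"


def compare_plans(plans: Sequence[Plan], structure: str) -> PlanComparison:
    """Align one structure's DVH across plans on a shared dose grid.

    Curves are interpolated linearly in cumulative form on the union of
    all dose grids (volume taken as 0 beyond each curve's last point).
    Plans lacking the structure are dropped with a warning; if none has
    it, that is an error.  More than five plans are processed, with a
    note that the comparison display was designed for at most five.
    """
    if not plans:
        raise RadbedError("no plans given")
    if len(plans) > PLAN_DISPLAY_LIMIT:
        warnings.warn(
            f"{len(plans)} plans given; the comparison display was designed "
            f"for at most {PLAN_DISPLAY_LIMIT}",
            DVHShapeWarning,
            stacklevel=2,
        )
    have: list[Plan] = []
    for p in plans:
        if structure in p.curves:
            have.append(p)
        else:
            warnings.warn(
                f"plan {p.plan_label!r} lacks structure {structure!r}; omitted",
                DVHShapeWarning,
                stacklevel=2,
            )
    if not have:
        raise RadbedError(f"structure {structure!r} absent from every plan")

    grids = [np.asarray(p.curves[structure].dose_gy, dtype=float) for p in have]
    union = np.unique(np.concatenate(grids))
    data: dict[str, np.ndarray] = {"dose_gy": union}
    stats: dict[str, DVHStats] = {}
    for p in have:
        curve = p.curves[structure]
        cum = curve if curve.kind == "cumulative" else to_cumulative(curve)
        col = np.interp(union, cum.dose_gy, cum.volume, left=cum.volume[0], right=0.0)
        label = p.plan_label or p.source_dialect
        data[label] = col
        stats[label] = dvh_stats(curve)
    return PlanComparison(structure=structure, table=pd.DataFrame(data), stats=stats)


def plot_dvh(curves, ax=None, **kwargs):  # pragma: no cover - thin optional helper
    """Plot one or more DVH curves (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if isinstance(curves, DVHCurve):
        curves = [curves]
    for c in curves:
        ax.plot(c.dose_gy, c.volume, label=c.structure_name, **kwargs)
    ax.set_xlabel("Dose [Gy]")
    ax.set_ylabel("Volume [%]" if curves and curves[0].volume_unit == "percent" else "Volume [cc]")
    ax.legend()
    return ax
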