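"""Poisson TCP, LKB NTCP with effective-volume DVH reduction, and P+.

Tumor control probability follows the Poisson model: if ``N*`` clonogens
each survive with probability ``sf``, control requires zero survivors,

    TCP = exp(-N* . sf),        ln sf = -alpha * D * (1 + d/ab).

For a heterogeneous dose distribution the clonogens are partitioned in
proportion to the DVH bin volumes (uniform clonogen density), giving
``TCP = exp(-N* . sum_i v_i sf_i)``; this collapses to the uniform-dose
formula when all bins share one dose.

Normal-tissue complication probability uses the Lyman-Kutcher-Burman
(LKB) probit model on the NTD2-corrected DVH.  The heterogeneous DVH is
first reduced with the effective-volume scheme,

    v_eff = sum_i v_i (NTD2_i / NTD2_max)^(1/n),

which converts the distribution into uniform irradiation of the organ
fraction ``v_eff`` at the maximum (NTD2) dose.  The tolerance dose
scales with the power law ``TD50(v) = TD50(1) * v^-n`` and

    NTCP = Phi( (NTD2_max - TD50(v_eff)) / (m * TD50(v_eff)) ).

``n`` is the volume-effect exponent (n -> 0 serial, n = 1 parallel;
n = 0 itself is rejected — use a small positive value such as 0.01),
``m`` the probit slope.

The therapeutic gain P+ combines tumor control with all complication
probabilities; the default is the product form
``P+ = TCP * prod_j (1 - NTCP_j)`` (probability of control with no
complication, assuming independence), with the difference form
``TCP - sum_j NTCP_j`` (clamped to [0, 1]) available for comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .analysis import VOLUME_FLOOR, _as_differential, dvh_stats, ntd2_transform
from .errors import ParameterError, RadbedError
from .io import DVHCurve, Plan, _fmt
from .lqm import TumorLQParams

__all__ = [
    "OARLKBParams",
    "DoseResponsePoint",
    "DoseResponseResult",
    "tcp_poisson",
    "effective_volume",
    "td50_at_veff",
    "ntcp_lkb",
    "ntcp_from_dvh",
    "therapeutic_gain",
    "dose_response_curves",
]


@dataclass(frozen=True)
class OARLKBParams:
    """LKB parameter bundle for one organ at risk.

    alpha_beta : Gy, fractionation sensitivity used for the NTD2 map.
    td50_whole : Gy, uniform whole-organ dose giving 50 % complications.
    slope_m    : dimensionless probit slope.
    volume_exponent : LKB volume-effect exponent n in (0, 1].
    """

    alpha_beta: float
    td50_whole: float
    slope_m: float
    volume_exponent: float

    def __post_init__(self) -> None:
        for name in ("alpha_beta", "td50_whole", "slope_m", "volume_exponent"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ParameterError(f"{name} must be > 0, got {v}")
        if self.volume_exponent > 1:
            raise ParameterError(
                f"volume_exponent must be in (0, 1], got {self.volume_exponent}"
            )


@dataclass(frozen=True)
class DoseResponsePoint:
    """One point of the dose-response scan."""

    prescribed_dose: float
    tcp: float
    ntcp_per_oar: dict[str, float]
    p_plus: float

    def __post_init__(self) -> None:
        probs = [self.tcp, self.p_plus, *self.ntcp_per_oar.values()]
        if any(not (-1e-12 <= p <= 1 + 1e-12) for p in probs):
            raise RadbedError("probability outside [0, 1]")


def _relative_volumes(curve: DVHCurve) -> np.ndarray:
    total = float(curve.volume.sum())
    if total <= 0:
        raise RadbedError(f"{curve.structure_name}: volumes are not normalizable")
    return curve.volume / total


def tcp_poisson(differential_ntd2_curve: DVHCurve, params: TumorLQParams) -> float:
    """Poisson TCP from a differential NTD2-converted DVH.

    ``TCP = exp(-N* sum_i v_i sf_i)`` with
    ``ln sf_i = -alpha * NTD2_i * (1 + 2/ab)`` (every NTD2 bin is, by
    construction, delivered at 2 Gy per fraction).
    """
    curve = differential_ntd2_curve
    if curve.kind != "differential":
        raise RadbedError("tcp_poisson needs a differential (NTD2) curve")
    params.require_tcp()
    v = _relative_volumes(curve)
    log_sf = -params.alpha * curve.dose_gy * (1.0 + 2.0 / params.alpha_beta)
    surviving = params.clonogen_number * float(np.dot(v, np.exp(log_sf)))
    return float(np.exp(-surviving))


def effective_volume(differential_ntd2_curve: DVHCurve, volume_exponent: float) -> float:
    """LKB effective volume of a differential NTD2 DVH, in (0, 1].

    ``v_eff = sum_i v_i (NTD2_i/NTD2_max)^(1/n)`` with ``NTD2_max`` the
    largest bin dose carrying volume above the floor.  A uniformly
    irradiated organ gives exactly 1.
    """
    if not volume_exponent > 0:
        raise ParameterError(
            f"volume_exponent must be > 0 (serial limit n->0: use a small "
            f"positive value), got {volume_exponent}"
        )
    curve = differential_ntd2_curve
    if curve.kind != "differential":
        raise RadbedError("effective_volume needs a differential (NTD2) curve")
    v = _relative_volumes(curve)
    d = curve.dose_gy
    nz = curve.volume > 0
    dmax = float(d[nz][-1])
    if dmax <= 0:
        return 1.0  # zero dose everywhere: uniform (null) irradiation
    ratio = np.clip(d / dmax, 0.0, 1.0)
    return float(np.dot(v, ratio ** (1.0 / volume_exponent)))


def td50_at_veff(td50_whole: float, veff: float, volume_exponent: float) -> float:
    """Power-law tolerance dose ``TD50(v) = TD50(1) * v^-n`` (Gy)."""
    if not veff > 0:
        raise ParameterError(f"veff must be in (0, 1], got {veff}")
    if veff > 1 + 1e-12:
        raise ParameterError(f"veff must be <= 1, got {veff}")
    if not td50_whole > 0:
        raise ParameterError(f"td50_whole must be > 0, got {td50_whole}")
    return td50_whole * veff ** (-volume_exponent)


def ntcp_lkb(ntd2_max: float, td50_veff: float, slope_m: float) -> float:
    """Probit NTCP: ``Phi((NTD2_max - TD50)/(m*TD50))``."""
    if not slope_m > 0:
        raise ParameterError(f"slope_m must be > 0, got {slope_m}")
    if not td50_veff > 0:
        raise ParameterError(f"td50_veff must be > 0, got {td50_veff}")
    if ntd2_max < 0:
        raise ParameterError(f"ntd2_max must be >= 0, got {ntd2_max}")
    s = (ntd2_max - td50_veff) / (slope_m * td50_veff)
    return float(ndtr(s))


def ntcp_from_dvh(curve: DVHCurve, n_fractions: int, params: OARLKBParams) -> float:
    """Full LKB chain from a raw DVH (either kind).

    differential form -> NTD2 transform -> effective volume ->
    TD50(v_eff) -> probit, identical to performing the steps by hand.
    """
    diff = _as_differential(curve)
    ntd2 = ntd2_transform(diff, n_fractions, params.alpha_beta)
    veff = effective_volume(ntd2, params.volume_exponent)
    td50 = td50_at_veff(params.td50_whole, veff, params.volume_exponent)
    nz = ntd2.volume > 0
    ntd2_max = float(ntd2.dose_gy[nz][-1])
    return ntcp_lkb(ntd2_max, td50, params.slope_m)


def therapeutic_gain(
    tcp: float, ntcps: Sequence[float], method: str = "product"
) -> float:
    """Therapeutic gain P+ from TCP and the per-OAR NTCPs.

    ``method='product'`` (default): ``TCP * prod(1 - NTCP_j)``.
    ``method='difference'``: ``TCP - sum(NTCP_j)``, clamped to [0, 1].
    """
    for p in (tcp, *ntcps):
        if not (0.0 <= p <= 1.0):
            raise ParameterError(f"probabilities must lie in [0, 1], got {p}")
    if method == "product":
        out = tcp
        for p in ntcps:
            out *= 1.0 - p
        return float(out)
    if method == "difference":
        return float(min(1.0, max(0.0, tcp - sum(ntcps))))
    raise ParameterError(f"unknown therapeutic-gain method {method!r}")


@dataclass
class DoseResponseResult:
    """TCP / NTCP / P+ versus prescription dose to the reference target."""

    reference_target: str
    points: list[DoseResponsePoint]
    gain_method: str = "product"

    @property
    def best(self) -> DoseResponsePoint:
        """The scan point maximising P+ (first on ties)."""
        return max(self.points, key=lambda p: (p.p_plus, -p.prescribed_dose))

    @property
    def optimal_dose(self) -> float:
        return self.best.prescribed_dose

    def to_frame(self) -> pd.DataFrame:
        oars = list(self.points[0].ntcp_per_oar)
        data = {
            "prescribed_dose_gy": [p.prescribed_dose for p in self.points],
            "tcp": [p.tcp for p in self.points],
        }
        for o in oars:
            data[f"ntcp_{o}"] = [p.ntcp_per_oar[o] for p in self.points]
        data["p_plus"] = [p.p_plus for p in self.points]
        return pd.DataFrame(data)

    def to_tsv(self) -> str:
        df = self.to_frame()
        lines = ["\t".join(df.columns)]
        for row in df.itertuples(index=False):
            lines.append("\t".join(_fmt(x) for x in row))
        return "\n".join(lines) + "\n"


def dose_response_curves(
    plan: Plan,
    reference_target: str,
    tumor_params: TumorLQParams,
    oar_params: Mapping[str, OARLKBParams],
    scale_grid: Sequence[float],
    gain_method: str = "product",
) -> DoseResponseResult:
    """Scan TCP / NTCP / P+ against the dose prescribed to the reference target.

    Each scale factor ``s > 0`` multiplies every structure's dose axis
    (the fraction number stays fixed, so dose per fraction scales with
    the prescription, as in SIB practice); NTD2 is recomputed and the
    models re-evaluated.  ``prescribed_dose`` is ``s`` times the plan
    schedule's total dose.
    """
    if reference_target not in plan.curves:
        raise RadbedError(f"reference target {reference_target!r} not in plan")
    scales = [float(s) for s in scale_grid]
    if not scales:
        raise RadbedError("scale_grid is empty")
    if any(s <= 0 for s in scales):
        raise ParameterError("scale factors must be > 0")
    oars = {
        name: p for name, p in oar_params.items()
        if name != reference_target and name in plan.curves
    }
    missing = set(oar_params) - set(oars) - {reference_target}
    if missing:
        warnings.warn(
            f"OAR parameters given for structures absent from the plan: "
            f"{sorted(missing)}",
            UserWarning,
            stacklevel=2,
        )
    n = plan.schedule.n_fractions
    ref_diff = _as_differential(plan.curves[reference_target])
    oar_diff = {name: _as_differential(plan.curves[name]) for name in oars}

    points: list[DoseResponsePoint] = []
    for s in scales:
        scaled_ref = replace(ref_diff, dose_gy=ref_diff.dose_gy * s)
        ntd2_ref = ntd2_transform(scaled_ref, n, tumor_params.alpha_beta)
        tcp = tcp_poisson(ntd2_ref, tumor_params)
        ntcps: dict[str, float] = {}
        for name, p in oars.items():
            scaled = replace(oar_diff[name], dose_gy=oar_diff[name].dose_gy * s)
            ntcps[name] = ntcp_from_dvh(scaled, n, p)
        p_plus = therapeutic_gain(tcp, list(ntcps.values()), method=gain_method)
        points.append(
            DoseResponsePoint(
                prescribed_dose=s * plan.schedule.total_dose,
                tcp=tcp,
                ntcp_per_oar=ntcps,
                p_plus=p_plus,
            )
        )
    return DoseResponseResult(
        reference_target=reference_target, points=points, gain_method=gain_method
    )
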