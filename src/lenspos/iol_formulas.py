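"""Intraocular-lens position and refraction predictors.

Two position predictors are implemented:

* the Olsen C constant, which places the IOL centre a fixed fraction of
  the preoperative lens thickness behind the preoperative anterior
  chamber depth: ``IOL_C = ACD_pre + C · LT_pre``.  The effective C of an
  operated eye is recovered postoperatively as
  ``C = (ACD_post + t/2 − ACD_pre) / LT_pre`` with ``t`` the IOL
  thickness;
* the SRK/T formula's optical anterior chamber depth, derived from axial
  length and mean keratometry through the published corneal-height
  construction, together with its thin-lens vergence refraction at the
  spectacle plane.

All SRK/T constants live in :data:`SRKT_CONSTANTS` so any published
erratum can be applied in one place.  Functions accept scalars or numpy
arrays and are pure: identical inputs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BiometryRangeError",
    "VergenceError",
    "IolImplant",
    "IolPositions",
    "SrktResult",
    "SRKT_CONSTANTS",
    "DEFAULT_VERTEX_MM",
    "effective_c_constant",
    "predict_iol_center",
    "iol_positions",
    "srkt_predicted_acd",
    "srkt_predicted_refraction",
    "srkt_power_for_refraction",
    "optimize_a_constant",
    "refractive_prediction_error",
    "spherical_equivalent",
]


class BiometryRangeError(ValueError):
    """Biometry out of supported range."""


class VergenceError(ValueError):
    """Non-physical vergence configuration."""


#: SRK/T constants from the published regression-derived theoretical
#: formula (1990), keratometric index 337.5 and aqueous/corneal indices
#: 1.336 / 1.333.
SRKT_CONSTANTS = {
    "keratometric_index_x1000": 337.5,
    "lcor_threshold_mm": 24.2,
    "lcor_poly": (-3.446, 1.715, -0.0237),
    "cw_poly": (-5.41, 0.58412, 0.098),
    "acd_const_slope": 0.62467,
    "acd_const_intercept": -68.747,
    "acd_offset": -3.336,
    "retinal_thickness_intercept": 0.65696,
    "retinal_thickness_slope": -0.02029,
    "n_aqueous": 1.336,
    "n_cornea_minus_1": 0.333,
}

#: Spectacle vertex distance assumed for refraction, mm.
DEFAULT_VERTEX_MM = 12.0

_AL_RANGE = (15.0, 40.0)
_K_RANGE = (30.0, 60.0)
_POWER_RANGE = (-10.0, 40.0)


@dataclass(frozen=True)
class IolImplant:
    """An implanted IOL: labelled power, central thickness and A constant."""

    power_d: float
    thickness_mm: float
    a_constant: float

    def __post_init__(self) -> None:
        if not self.thickness_mm > 0:
            raise ValueError("IOL thickness must be positive")


@dataclass(frozen=True)
class IolPositions:
    """Anterior / central / posterior IOL surface depths, mm from the cornea."""

    anterior_mm: float
    central_mm: float
    posterior_mm: float


@dataclass(frozen=True)
class SrktResult:
    """SRK/T outputs for one eye.

    ``predicted_acd_mm`` is the formula's optical anterior chamber depth —
    not an anatomic distance.  ``prediction_error_d`` is the measured
    postoperative spherical equivalent minus the predicted refraction.
    """

    predicted_acd_mm: float
    predicted_refraction_d: float
    prediction_error_d: float


def effective_c_constant(
    acd_pre: float, lt: float, anterior_iol: float, iol_thickness: float
) -> float:
    """Postoperatively observed C constant of one eye.

    ``(anterior_iol + iol_thickness/2 − acd_pre) / lt``: the fraction of
    the preoperative lens thickness at which the IOL centre settled.
    """
    acd_pre, lt, anterior_iol, iol_thickness = map(
        np.asarray, (acd_pre, lt, anterior_iol, iol_thickness)
    )
    if np.any(lt <= 0):
        raise ValueError("invalid lens thickness")
    out = (anterior_iol + iol_thickness / 2.0 - acd_pre) / lt
    return out.item() if out.ndim == 0 else out


def predict_iol_center(acd_pre: float, lt: float, c: float) -> float:
    """C-constant prediction of the central IOL position: ``acd_pre + c·lt``."""
    acd_pre, lt, c = map(np.asarray, (acd_pre, lt, c))
    if np.any(lt <= 0):
        raise ValueError("invalid lens thickness")
    out = acd_pre + c * lt
    return out.item() if out.ndim == 0 else out


def iol_positions(anterior_iol: float, iol_thickness: float) -> IolPositions:
    """Fill central and posterior IOL surface depths from the anterior one."""
    if not iol_thickness > 0:
        raise ValueError("IOL thickness must be positive")
    return IolPositions(
        anterior_mm=float(anterior_iol),
        central_mm=float(anterior_iol + iol_thickness / 2.0),
        posterior_mm=float(anterior_iol + iol_thickness),
    )


def _check_ranges(al, k, iol_power=None) -> None:
    if np.any((al <= _AL_RANGE[0]) | (al >= _AL_RANGE[1])) or np.any(
        (k <= _K_RANGE[0]) | (k >= _K_RANGE[1])
    ):
        raise BiometryRangeError("biometry out of supported range")
    if iol_power is not None and np.any(
        (iol_power <= _POWER_RANGE[0]) | (iol_power >= _POWER_RANGE[1])
    ):
        raise BiometryRangeError("biometry out of supported range: IOL power")


def srkt_predicted_acd(al, k, a_constant):
    """SRK/T predicted (optical) postoperative anterior chamber depth, mm.

    Chain: corneal radius ``r = 337.5/K``; corrected axial length
    ``LCOR = AL`` for AL ≤ 24.2 mm, else the published quadratic; computed
    corneal width ``Cw``; corneal height
    ``H = r − sqrt(r² − Cw²/4)`` (radicand clamped at zero, i.e. H capped
    at r for extreme corneal widths); A-constant translation
    ``ACDconst = 0.62467·A − 68.747``; finally
    ``ACD = H + ACDconst − 3.336``.
    """
    al = np.asarray(al, dtype=float)
    k = np.asarray(k, dtype=float)
    _check_ranges(al, k)
    c = SRKT_CONSTANTS
    r = c["keratometric_index_x1000"] / k
    p0, p1, p2 = c["lcor_poly"]
    lcor = np.where(al <= c["lcor_threshold_mm"], al, p0 + p1 * al + p2 * al**2)
    w0, w1, w2 = c["cw_poly"]
    cw = w0 + w1 * lcor + w2 * k
    radicand = np.clip(r**2 - cw**2 / 4.0, 0.0, None)
    h = r - np.sqrt(radicand)
    acd_const = c["acd_const_slope"] * np.asarray(a_constant, dtype=float) + c[
        "acd_const_intercept"
    ]
    out = h + acd_const + c["acd_offset"]
    return out.item() if out.ndim == 0 else out


def _optical_axial_length(al):
    c = SRKT_CONSTANTS
    return al + c["retinal_thickness_intercept"] + c["retinal_thickness_slope"] * al


def srkt_predicted_refraction(al, k, a_constant, iol_power, vertex=DEFAULT_VERTEX_MM):
    """SRK/T predicted spectacle-plane refraction for a given IOL power, D.

    Thin-lens vergence through cornea and IOL over the optical axial
    length ``AL + 0.65696 − 0.02029·AL`` (axial length plus retinal
    thickness), aqueous index 1.336 and corneal index 1.333, evaluated at
    spectacle vertex ``vertex`` mm.
    """
    al = np.asarray(al, dtype=float)
    k = np.asarray(k, dtype=float)
    iol_power = np.asarray(iol_power, dtype=float)
    _check_ranges(al, k, iol_power)
    c = SRKT_CONSTANTS
    na, ncm1 = c["n_aqueous"], c["n_cornea_minus_1"]
    acd = np.asarray(srkt_predicted_acd(al, k, a_constant))
    r = c["keratometric_index_x1000"] / k
    lopt = _optical_axial_length(al)
    num = 1000.0 * na * (na * r - ncm1 * lopt) - iol_power * (lopt - acd) * (
        na * r - ncm1 * acd
    )
    den = na * (vertex * (na * r - ncm1 * lopt) + lopt * r) - 0.001 * iol_power * (
        lopt - acd
    ) * (vertex * (na * r - ncm1 * acd) + acd * r)
    if np.any(np.abs(den) < 1e-9):
        raise VergenceError("non-physical vergence configuration")
    out = num / den
    return out.item() if out.ndim == 0 else out


def srkt_power_for_refraction(
    al, k, a_constant, target_refraction=0.0, vertex=DEFAULT_VERTEX_MM
):
    """IOL power achieving a target spectacle refraction (0 → emmetropia), D.

    Closed-form inversion of the vergence equation; the emmetropia power
    is the ``target_refraction = 0`` case.
    """
    al = np.asarray(al, dtype=float)
    k = np.asarray(k, dtype=float)
    _check_ranges(al, k)
    c = SRKT_CONSTANTS
    na, ncm1 = c["n_aqueous"], c["n_cornea_minus_1"]
    acd = np.asarray(srkt_predicted_acd(al, k, a_constant))
    r = c["keratometric_index_x1000"] / k
    lopt = _optical_axial_length(al)
    rx = np.asarray(target_refraction, dtype=float)
    num = 1000.0 * na * (
        na * r - ncm1 * lopt
    ) - rx * na * (vertex * (na * r - ncm1 * lopt) + lopt * r)
    den = (lopt - acd) * (
        na * r - ncm1 * acd - 0.001 * rx * (vertex * (na * r - ncm1 * acd) + acd * r)
    )
    if np.any(np.abs(den) < 1e-9):
        raise VergenceError("non-physical vergence configuration")
    out = num / den
    return out.item() if out.ndim == 0 else out


def optimize_a_constant(
    cohort,
    a_bracket=(110.0, 125.0),
    vertex=DEFAULT_VERTEX_MM,
    tol=1e-10,
):
    """A constant zeroing the cohort-mean refractive prediction error.

    ``cohort`` is a DataFrame with columns ``al_mm``, ``k_d``,
    ``iol_power_d`` and ``postop_se_d``.  The mean of
    ``postop_se − predicted refraction(A)`` is a smooth monotone function
    of A; its root is bracketed on ``a_bracket`` and solved by Brent's
    method, leaving ``|mean error| ≤ 1e-6`` D.

    Raises
    ------
    ValueError
        Fewer than two eyes, or no sign change over the bracket
        ("A constant not identifiable for cohort").
    """
    if len(cohort) < 2:
        raise ValueError("need at least two eyes to optimize the A constant")
    al = cohort["al_mm"].to_numpy()
    k = cohort["k_d"].to_numpy()
    power = cohort["iol_power_d"].to_numpy()
    se = cohort["postop_se_d"].to_numpy()

    def mean_error(a):
        return float(
            np.mean(se - srkt_predicted_refraction(al, k, a, power, vertex=vertex))
        )

    lo, hi = a_bracket
    if mean_error(lo) * mean_error(hi) > 0:
        raise ValueError("A constant not identifiable for cohort")
    return float(brentq(mean_error, lo, hi, xtol=tol))


def refractive_prediction_error(measured_se, predicted):
    """Measured postoperative spherical equivalent minus predicted refraction, D."""
    out = np.asarray(measured_se, dtype=float) - np.asarray(predicted, dtype=float)
    return out.item() if out.ndim == 0 else out


def spherical_equivalent(sphere, cylinder):
    """Spherical equivalent ``sphere + cylinder/2``, D."""
    out = np.asarray(sphere, dtype=float) + np.asarray(cylinder, dtype=float) / 2.0
    return out.item() if out.ndim == 0 else out
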