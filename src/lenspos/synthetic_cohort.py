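"""Synthetic pseudophakic cohort generator.

Generates per-eye biometry records with the joint structure of a cataract
cohort of older adults: age and lens thickness (LT) jointly normal and
positively correlated; the anterior surface depth (ASD) falling linearly
as the lens thickens while the posterior surface depth (PSD) is the exact
construction identity ``ASD + LT``; curvature radii (ACR, PCR) correlated
with LT; the equatorial surface depth (ESD) *computed* through the
circle-intersection geometry, never drawn; the anterior IOL surface
position a linear function of the three depths plus settling noise; and a
postoperative refraction built from the SRK/T prediction plus an error
correlated with how far the IOL settled from the formula's optical ACD.

Two quantities are calibrated indirectly:

* the ASD residual spread is set from the target ASD moments
  (mean 2.79 mm, sd 0.38 mm, corr with LT −0.65), which fixes the
  implied regression slope at −0.668 mm/mm;
* the IOL settling-noise sd is chosen on an internal pilot sample so the
  population R² of the position regression equals the target (0.71).

Age, LT and axial length are truncated to the cohort's observed ranges by
rejection; because naive truncation of a normal shrinks its moments, the
parent distributions are first moment-matched by a deterministic
quadrature solve so the *truncated* draws carry the target means, SDs and
correlation.

Reproducibility: one master seed; every sub-draw uses a child of its
`numpy` ``SeedSequence`` with a fixed spawn order, so identical params
give byte-identical cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from . import iol_formulas as iol
from . import lens_geometry as geom

__all__ = ["CohortParams", "default_params", "generate", "sample_surface_points"]


@dataclass(frozen=True)
class CohortParams:
    """Calibration of the synthetic cohort.

    Moments and correlations mirror the study cohort (n = 79); the K
    distribution is an explicit modelling assumption (mean 43.5 D,
    sd 1.5 D) since corneal power was not reported, and nothing
    downstream that is checked against the cohort depends on it.
    """

    n: int = 79
    seed: int = 42

    age_mean: float = 69.0
    age_sd: float = 11.0
    age_range: tuple = (26.0, 86.0)
    lt_mean: float = 4.48
    lt_sd: float = 0.37
    lt_range: tuple = (3.64, 5.40)
    r_age_lt: float = 0.53

    asd_mean: float = 2.79
    asd_sd: float = 0.38
    r_lt_asd: float = -0.65

    acr_mean: float = 10.21
    acr_sd: float = 1.32
    r_lt_acr: float = -0.60
    pcr_mean: float = 6.01
    pcr_sd: float = 0.53
    r_lt_pcr: float = -0.12

    al_mean: float = 24.60
    al_sd: float = 1.51
    al_range: tuple = (21.74, 28.47)
    k_mean: float = 43.5
    k_sd: float = 1.5

    # Anterior IOL surface position ~ depths: coefficients, intercept and
    # target population R² of the regression.
    iol_coef_asd: float = 0.25
    iol_coef_esd: float = 0.15
    iol_coef_psd: float = 0.44
    iol_intercept: float = -0.47
    iol_r2: float = 0.71

    # Refraction model: prediction-error sd and its correlation with the
    # (anterior IOL − SRK/T ACD) difference.
    error_sd: float = 0.45
    r_error_diff: float = 0.65

    iol_thickness_mm: float = 1.02
    a_constant: float = 118.4
    target_refraction_d: float = -1.5
    iol_power_step_d: float = 0.5

    aperture_mm: float = 4.0
    vertex_mm: float = 12.0


def default_params() -> CohortParams:
    """The study-cohort calibration."""
    return CohortParams()


# ---------------------------------------------------------------------------
# Truncated-normal moment matching
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _truncnorm_parent(mean: float, sd: float, lo: float, hi: float):
    """Parent (m, s) whose (lo, hi)-truncation has the given mean and sd."""

    def resid(p):
        m, s = p
        a, b = (lo - m) / s, (hi - m) / s
        mu, var = sps.truncnorm.stats(a, b, loc=m, scale=s, moments="mv")
        return [mu - mean, np.sqrt(var) - sd]

    sol = optimize.root(resid, x0=[mean, sd], method="hybr")
    if not sol.success:  # pragma: no cover - calibrations are feasible
        raise ValueError("infeasible calibration: univariate truncation")
    return float(sol.x[0]), float(sol.x[1])


def _rect_truncated_moments(m1, s1, m2, s2, rho, box1, box2, n_nodes=80):
    """Moments of a bivariate normal truncated to a rectangle (quadrature)."""
    x, wx = np.polynomial.legendre.leggauss(n_nodes)
    lo1, hi1 = box1
    lo2, hi2 = box2
    u = (hi1 - lo1) / 2 * x + (hi1 + lo1) / 2
    v = (hi2 - lo2) / 2 * x + (hi2 + lo2) / 2
    wu = (hi1 - lo1) / 2 * wx
    wv = (hi2 - lo2) / 2 * wx
    U, V = np.meshgrid(u, v, indexing="ij")
    W = np.outer(wu, wv)
    zu = (U - m1) / s1
    zv = (V - m2) / s2
    det = 1 - rho**2
    pdf = np.exp(-(zu**2 - 2 * rho * zu * zv + zv**2) / (2 * det)) / (
        2 * np.pi * s1 * s2 * np.sqrt(det)
    )
    mass = np.sum(W * pdf)
    e1 = np.sum(W * pdf * U) / mass
    e2 = np.sum(W * pdf * V) / mass
    v1 = np.sum(W * pdf * (U - e1) ** 2) / mass
    v2 = np.sum(W * pdf * (V - e2) ** 2) / mass
    cov = np.sum(W * pdf * (U - e1) * (V - e2)) / mass
    return e1, np.sqrt(v1), e2, np.sqrt(v2), cov / np.sqrt(v1 * v2)


@lru_cache(maxsize=32)
def _bivariate_parent(
    mean1, sd1, box1, mean2, sd2, box2, rho_target
):
    """Parent (m1, s1, m2, s2, rho) matching rectangle-truncated moments."""

    def resid(p):
        m1, s1, m2, s2, rho = p
        if s1 <= 0 or s2 <= 0 or not (-0.999 < rho < 0.999):
            return [1e3] * 5
        e1, t1, e2, t2, r = _rect_truncated_moments(m1, s1, m2, s2, rho, box1, box2)
        return [e1 - mean1, t1 - sd1, e2 - mean2, t2 - sd2, r - rho_target]

    sol = optimize.root(
        resid, x0=[mean1, sd1, mean2, sd2, rho_target], method="hybr"
    )
    if not sol.success:
        raise ValueError("infeasible calibration: bivariate truncation")
    return tuple(float(v) for v in sol.x)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _draw_lens_block(rng: np.random.Generator, params: CohortParams, n: int):
    """Draw n eyes' (age, LT, ASD, PSD, ACR, PCR, ESD), rejecting invalid ones.

    Returns a dict of arrays plus the number of draws rejected by the
    range truncation and by the circle-intersection geometry.
    """
    p = params
    m1, s1, m2, s2, rho = _bivariate_parent(
        p.age_mean, p.age_sd, p.age_range, p.lt_mean, p.lt_sd, p.lt_range, p.r_age_lt
    )
    cov = np.array(
        [[s1**2, rho * s1 * s2], [rho * s1 * s2, s2**2]]
    )
    # ASD | LT from target moments: slope = r · sd(ASD)/sd(LT).
    slope = p.r_lt_asd * p.asd_sd / p.lt_sd
    intercept = p.asd_mean - slope * p.lt_mean
    resid_sd = p.asd_sd * np.sqrt(1 - p.r_lt_asd**2)

    cols = {k: [] for k in ("age", "lt", "asd", "psd", "acr", "pcr", "esd")}
    got, rej_range, rej_geom = 0, 0, 0
    while got < n:
        m = max(2 * (n - got), 256)
        age_lt = rng.multivariate_normal([m1, m2], cov, size=m)
        age, lt = age_lt[:, 0], age_lt[:, 1]
        keep = (
            (age >= p.age_range[0])
            & (age <= p.age_range[1])
            & (lt >= p.lt_range[0])
            & (lt <= p.lt_range[1])
        )
        rej_range += int(m - keep.sum())
        age, lt = age[keep], lt[keep]
        k = len(lt)
        asd = intercept + slope * lt + rng.normal(0.0, resid_sd, k)
        psd = asd + lt
        zlt = (lt - p.lt_mean) / p.lt_sd
        acr = (
            p.acr_mean
            + p.r_lt_acr * p.acr_sd * zlt
            + rng.normal(0.0, p.acr_sd * np.sqrt(1 - p.r_lt_acr**2), k)
        )
        pcr = (
            p.pcr_mean
            + p.r_lt_pcr * p.pcr_sd * zlt
            + rng.normal(0.0, p.pcr_sd * np.sqrt(1 - p.r_lt_pcr**2), k)
        )
        esd, valid = geom.equatorial_depth_batch(asd + acr, acr, psd - pcr, pcr)
        valid &= (asd > 0) & (acr > 0) & (pcr > 0)
        rej_geom += int(k - valid.sum())
        for name, arr in zip(
            cols, (age, lt, asd, psd, acr, pcr, esd), strict=True
        ):
            cols[name].append(arr[valid])
        got += int(valid.sum())
    out = {k: np.concatenate(v)[:n] for k, v in cols.items()}
    return out, rej_range, rej_geom


def _iol_noise_sd(params: CohortParams, pilot_seed: np.random.SeedSequence) -> float:
    """Settling-noise sd giving the target position-regression R².

    Calibrated on an internal pilot sample of the lens geometry:
    ``sd_noise = sd(linear predictor) · sqrt((1 − R²)/R²)``.
    """
    p = params
    pilot, _, _ = _draw_lens_block(np.random.default_rng(pilot_seed), p, 20000)
    fit = (
        p.iol_coef_asd * pilot["asd"]
        + p.iol_coef_esd * pilot["esd"]
        + p.iol_coef_psd * pilot["psd"]
        + p.iol_intercept
    )
    return float(fit.std(ddof=1) * np.sqrt((1 - p.iol_r2) / p.iol_r2))


def generate(params: CohortParams | None = None) -> pd.DataFrame:
    """Generate a cohort table, one row per eye.

    Deterministic given ``params`` (including its seed).  Rejection counts
    of the range truncation and the geometric validity screen are stored
    in ``df.attrs["rejections"]``.

    Columns: ``eye_id, age_years, al_mm, k_d, acr_mm, pcr_mm, lt_mm,
    asd_mm, esd_mm, psd_mm, iol_power_d, iol_thickness_mm, a_constant,
    anterior_iol_mm, central_iol_mm, posterior_iol_mm, postop_se_d``.
    """
    p = params or default_params()
    if p.n < 1:
        raise ValueError("need at least one eye")
    ss = np.random.SeedSequence(p.seed)
    s_lens, s_pilot, s_optics, s_position, s_refraction = ss.spawn(5)

    lens, rej_range, rej_geom = _draw_lens_block(
        np.random.default_rng(s_lens), p, p.n
    )

    # Axial length (truncated, moment-matched) and keratometry.
    rng_o = np.random.default_rng(s_optics)
    m_al, s_al = _truncnorm_parent(p.al_mean, p.al_sd, *p.al_range)
    a, b = (p.al_range[0] - m_al) / s_al, (p.al_range[1] - m_al) / s_al
    al = sps.truncnorm.rvs(a, b, loc=m_al, scale=s_al, size=p.n, random_state=rng_o)
    k = rng_o.normal(p.k_mean, p.k_sd, p.n)

    # IOL power from SRK/T aiming at the target refraction, in clinical steps.
    power_exact = iol.srkt_power_for_refraction(
        al, k, p.a_constant, p.target_refraction_d, vertex=p.vertex_mm
    )
    power = np.round(np.asarray(power_exact) / p.iol_power_step_d) * p.iol_power_step_d
    predicted_refraction = iol.srkt_predicted_refraction(
        al, k, p.a_constant, power, vertex=p.vertex_mm
    )
    srkt_acd = iol.srkt_predicted_acd(al, k, p.a_constant)

    # Anterior IOL surface position: linear in the depths + settling noise.
    rng_p = np.random.default_rng(s_position)
    noise_sd = _iol_noise_sd(p, s_pilot)
    anterior_iol = (
        p.iol_coef_asd * lens["asd"]
        + p.iol_coef_esd * lens["esd"]
        + p.iol_coef_psd * lens["psd"]
        + p.iol_intercept
        + rng_p.normal(0.0, noise_sd, p.n)
    )

    # Prediction error correlated with the settling difference.
    rng_r = np.random.default_rng(s_refraction)
    diff = anterior_iol - srkt_acd
    z = (diff - diff.mean()) / diff.std(ddof=1) if p.n > 1 else np.zeros(p.n)
    error = p.error_sd * (
        p.r_error_diff * z
        + np.sqrt(1 - p.r_error_diff**2) * rng_r.standard_normal(p.n)
    )
    postop_se = np.asarray(predicted_refraction) + error

    df = pd.DataFrame(
        {
            "eye_id": [f"eye{i + 1:04d}" for i in range(p.n)],
            "age_years": lens["age"],
            "al_mm": al,
            "k_d": k,
            "acr_mm": lens["acr"],
            "pcr_mm": lens["pcr"],
            "lt_mm": lens["lt"],
            "asd_mm": lens["asd"],
            "esd_mm": lens["esd"],
            "psd_mm": lens["psd"],
            "iol_power_d": power,
            "iol_thickness_mm": np.full(p.n, p.iol_thickness_mm),
            "a_constant": np.full(p.n, p.a_constant),
            "anterior_iol_mm": anterior_iol,
            "central_iol_mm": anterior_iol + p.iol_thickness_mm / 2.0,
            "posterior_iol_mm": anterior_iol + p.iol_thickness_mm,
            "postop_se_d": postop_se,
        }
    )
    df.attrs["rejections"] = {"range": rej_range, "geometry": rej_geom}
    df.attrs["params"] = dataclasses.asdict(p)
    return df


def sample_surface_points(
    record,
    params: CohortParams | None = None,
    noise_sd: float = 0.0,
    n_points: int = 50,
    rng: np.random.Generator | None = None,
) -> tuple[geom.SurfaceSamples, geom.SurfaceSamples]:
    """Sample (depth, height) points on one eye's two lens surfaces.

    ``record`` is a cohort row (anything with ``acr_mm``, ``pcr_mm``,
    ``asd_mm``, ``psd_mm``).  Points are spread uniformly in height across
    the pupil aperture on the true circles, then Gaussian noise of sd
    ``noise_sd`` mm is added to the height coordinate, emulating
    segmentation jitter.  Feeding the result to
    :func:`lenspos.lens_geometry.fit_circle` recovers the generating
    radii exactly when ``noise_sd = 0``.
    """
    p = params or default_params()
    if p.aperture_mm <= 0:
        raise ValueError("invalid aperture")
    if p.aperture_mm > 10.0:
        raise ValueError("aperture exceeds the physical lens diameter")
    rng = rng or np.random.default_rng()
    acr, pcr = float(record["acr_mm"]), float(record["pcr_mm"])
    asd, psd = float(record["asd_mm"]), float(record["psd_mm"])
    half = min(p.aperture_mm / 2.0, 0.999 * min(acr, pcr))
    h = np.linspace(-half, half, n_points)
    samples = []
    for center, radius, sign in ((asd + acr, acr, -1.0), (psd - pcr, pcr, +1.0)):
        depth = center + sign * np.sqrt(radius**2 - h**2)
        height = h + rng.normal(0.0, noise_sd, n_points)
        # Noise can push a point marginally past the aperture edge; widen
        # the declared aperture accordingly rather than clipping data.
        aperture = max(p.aperture_mm, 2.0 * float(np.max(np.abs(height))))
        samples.append(
            geom.SurfaceSamples(
                points=np.column_stack([depth, height]), aperture_mm=aperture
            )
        )
    return samples[0], samples[1]
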