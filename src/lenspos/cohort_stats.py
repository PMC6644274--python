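"""Cohort-level statistics for the biometry analysis.

Summaries (mean ± SD and range), Pearson product-moment correlations with
per-family Bonferroni correction, first-order partial correlations with
age as the control variable, and ordinary least-squares multiple
regression with standardized coefficients.  Table builders reproduce the
report layout of the study design: a demographic/biometry summary, a
correlation table organised in four hypothesis families, the
inter-correlations of the three lens surface depths, and the multiple
regression of the anterior IOL surface position on ASD, ESD and PSD.

Correction convention: Bonferroni is applied within each analytic family
(the lens-thickness family of 9 tests, the C-constant-prediction and
IOL-position families of 3 each, and the prediction-error family of 4),
with corrected p-values capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "Summary",
    "CorrelationEntry",
    "RegressionFit",
    "DEFAULT_FAMILY_MAP",
    "summarize",
    "pearson",
    "bonferroni",
    "partial_corr",
    "multiple_regression",
    "standardized_coefficient",
    "difference_vs_srkt",
    "build_table1",
    "build_table2",
    "build_table3",
    "build_table4",
    "figure_data",
]

#: Bonferroni family sizes per analytic block of the correlation table.
DEFAULT_FAMILY_MAP = {"lt": 9, "c_prediction": 3, "iol_position": 3, "error": 4}


class Summary(NamedTuple):
    mean: float
    sd: float
    min: float
    max: float


@dataclass(frozen=True)
class CorrelationEntry:
    """One simple correlation: r, R² = r², raw and corrected p."""

    x_name: str
    y_name: str
    r: float
    r_squared: float
    p_raw: float
    p_bonferroni: float | None = None
    partial_r_given_age: float | None = None


@dataclass(frozen=True)
class RegressionFit:
    """An OLS fit: per-term raw and standardized coefficients plus R²."""

    response: str
    terms: list  # of (name, coefficient, standardized_coefficient)
    intercept: float
    r_squared_multiple: float


def summarize(values: Sequence[float]) -> Summary:
    """Mean, sample SD (n−1 denominator), min and max of a sequence."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("insufficient data: need at least 2 values")
    return Summary(
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        min=float(x.min()),
        max=float(x.max()),
    )


def pearson(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationEntry:
    """Pearson product-moment correlation with its two-sided p-value.

    p is the two-sided tail of ``t = r·sqrt((n−2)/(1−r²))`` on ``n − 2``
    degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("unaligned cohort")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate variable")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationEntry(
        x_name=x_name,
        y_name=y_name,
        r=r,
        r_squared=r * r,
        p_raw=float(res.pvalue),
    )


def bonferroni(
    entries: Sequence[CorrelationEntry], family_size: int
) -> list[CorrelationEntry]:
    """Attach ``min(1, m·p_raw)`` to every entry of one hypothesis family."""
    if family_size < 1:
        raise ValueError("family size must be >= 1")
    return [
        replace(e, p_bonferroni=min(1.0, family_size * e.p_raw)) for e in entries
    ]


def partial_corr(x, y, control) -> float:
    """First-order partial correlation of x and y given one control variable.

    ``r_xy·z = (r_xy − r_xz·r_yz) / sqrt((1 − r_xz²)(1 − r_yz²))``,
    equivalent to correlating the residuals of x and y each regressed on
    the control.
    """
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, control))
    if not (x.size == y.size == z.size):
        raise ValueError("unaligned cohort")
    if x.size < 4:
        raise ValueError("need at least 4 triples")
    r_xy = pearson(x, y).r
    r_xz = pearson(x, z).r
    r_yz = pearson(y, z).r
    if abs(r_xz) >= 1 - 1e-12 or abs(r_yz) >= 1 - 1e-12:
        raise ValueError("control collinear with variable")
    return float(
        (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    )


def standardized_coefficient(coefficient, sd_x, sd_y):
    """Standardized (beta) coefficient: ``coefficient · sd(x)/sd(y)``."""
    return coefficient * sd_x / sd_y


def multiple_regression(y, X: pd.DataFrame, response: str = "y") -> RegressionFit:
    """OLS regression of y on the columns of X with standardized coefficients.

    Standardized coefficients are the raw ones rescaled by
    ``sd(x_j)/sd(y)``; R² is the ordinary multiple coefficient of
    determination.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("insufficient data for regression")
    design = sm.add_constant(X.to_numpy(dtype=float))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear predictors")
    fit = sm.OLS(y, design).fit()
    sd_y = y.std(ddof=1)
    terms = [
        (
            name,
            float(fit.params[j + 1]),
            float(
                standardized_coefficient(
                    fit.params[j + 1], X.iloc[:, j].std(ddof=1), sd_y
                )
            ),
        )
        for j, name in enumerate(X.columns)
    ]
    return RegressionFit(
        response=response,
        terms=terms,
        intercept=float(fit.params[0]),
        r_squared_multiple=float(fit.rsquared),
    )


def difference_vs_srkt(df: pd.DataFrame) -> pd.DataFrame:
    """Per-eye depth minus SRK/T predicted ACD, for each axial landmark.

    Needs columns ``asd_mm``, ``esd_mm``, ``psd_mm``, ``anterior_iol_mm``
    and ``predicted_acd_srkt_mm``; returns one difference column per
    landmark, aligned to the input index.
    """
    required = [
        "asd_mm",
        "esd_mm",
        "psd_mm",
        "anterior_iol_mm",
        "predicted_acd_srkt_mm",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"unaligned cohort: missing column {missing[0]}")
    acd = df["predicted_acd_srkt_mm"]
    return pd.DataFrame(
        {
            "diff_anterior_iol_mm": df["anterior_iol_mm"] - acd,
            "diff_asd_mm": df["asd_mm"] - acd,
            "diff_esd_mm": df["esd_mm"] - acd,
            "diff_psd_mm": df["psd_mm"] - acd,
        },
        index=df.index,
    )


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

_TABLE1_ROWS = [
    ("Age (years)", "age_years"),
    ("IOL power (D)", "iol_power_d"),
    ("Axial length (mm)", "al_mm"),
    ("Predictive refraction by SRK/T (D)", "predicted_refraction_d"),
    ("Spherical equivalent of postoperative refraction (D)", "postop_se_d"),
    ("Prediction error (D)", "prediction_error_d"),
    ("Predicted postoperative ACD of SRK/T formula (mm)", "predicted_acd_srkt_mm"),
    ("C constant", "c_constant"),
    ("Predicted IOL position using C constant (mm)", "predicted_iol_c_mm"),
    ("Anterior curvature radius (mm)", "acr_mm"),
    ("Posterior curvature radius (mm)", "pcr_mm"),
    ("Lens thickness (mm)", "lt_mm"),
    ("Anterior surface depth (mm)", "asd_mm"),
    ("Equatorial surface depth (mm)", "esd_mm"),
    ("Posterior surface depth (mm)", "psd_mm"),
    ("Anterior IOL surface position (mm)", "anterior_iol_mm"),
    ("Central IOL thickness position (mm)", "central_iol_mm"),
    ("Posterior IOL surface position (mm)", "posterior_iol_mm"),
]


def build_table1(df: pd.DataFrame) -> pd.DataFrame:
    """Demographic / biometry summary: mean, SD and range per parameter."""
    rows = []
    for label, col in _TABLE1_ROWS:
        if col not in df.columns:
            continue
        s = summarize(df[col])
        rows.append(
            {
                "parameter": label,
                "mean": s.mean,
                "sd": s.sd,
                "min": s.min,
                "max": s.max,
            }
        )
    return pd.DataFrame(rows)


_LT_FAMILY = [
    ("Age", "age_years", False),
    ("Anterior curvature radius", "acr_mm", True),
    ("Posterior curvature radius", "pcr_mm", True),
    ("Anterior surface depth", "asd_mm", True),
    ("Equatorial surface depth", "esd_mm", True),
    ("Posterior surface depth", "psd_mm", True),
    ("Central IOL thickness position", "central_iol_mm", True),
    ("C constant", "c_constant", True),
    ("Predicted IOL position using C constant", "predicted_iol_c_mm", True),
]

_DEPTHS = [
    ("Anterior surface depth", "asd_mm"),
    ("Equatorial surface depth", "esd_mm"),
    ("Posterior surface depth", "psd_mm"),
]

_ERROR_FAMILY = [
    ("Difference: anterior IOL surface position", "diff_anterior_iol_mm"),
    ("Difference: anterior surface depth", "diff_asd_mm"),
    ("Difference: equatorial surface depth", "diff_esd_mm"),
    ("Difference: posterior surface depth", "diff_psd_mm"),
]


def build_table2(
    df: pd.DataFrame, family_map: dict | None = None
) -> pd.DataFrame:
    """Correlation table in four hypothesis families.

    Families: everything vs lens thickness (with age-controlled partial
    correlations), the three depths vs the C-constant prediction, the
    three depths vs the anterior IOL surface position, and the refractive
    prediction error vs each depth-minus-SRK/T-ACD difference.
    """
    fam = dict(DEFAULT_FAMILY_MAP)
    if family_map:
        fam.update(family_map)
    lt = df["lt_mm"]
    blocks: list[tuple[str, list[CorrelationEntry]]] = []

    entries = []
    for label, col, with_partial in _LT_FAMILY:
        e = pearson(lt, df[col], "lt_mm", col)
        if with_partial:
            e = replace(
                e, partial_r_given_age=partial_corr(lt, df[col], df["age_years"])
            )
        entries.append(e)
    blocks.append(("lt", bonferroni(entries, fam["lt"])))

    entries = [
        pearson(df["predicted_iol_c_mm"], df[col], "predicted_iol_c_mm", col)
        for _, col in _DEPTHS
    ]
    blocks.append(("c_prediction", bonferroni(entries, fam["c_prediction"])))

    entries = [
        pearson(df["anterior_iol_mm"], df[col], "anterior_iol_mm", col)
        for _, col in _DEPTHS
    ]
    blocks.append(("iol_position", bonferroni(entries, fam["iol_position"])))

    diffs = difference_vs_srkt(df)
    entries = [
        pearson(df["prediction_error_d"], diffs[col], "prediction_error_d", col)
        for _, col in _ERROR_FAMILY
    ]
    blocks.append(("error", bonferroni(entries, fam["error"])))

    labels = {
        "lt": dict((col, lab) for lab, col, _ in _LT_FAMILY),
        "c_prediction": dict((col, lab) for lab, col in _DEPTHS),
        "iol_position": dict((col, lab) for lab, col in _DEPTHS),
        "error": dict((col, lab) for lab, col in _ERROR_FAMILY),
    }
    rows = []
    for block, entries in blocks:
        for e in entries:
            rows.append(
                {
                    "family": block,
                    "variable": labels[block][e.y_name],
                    "r": e.r,
                    "r_squared": e.r_squared,
                    "partial_r_given_age": e.partial_r_given_age,
                    "p_raw": e.p_raw,
                    "p_bonferroni": e.p_bonferroni,
                }
            )
    return pd.DataFrame(rows)


def build_table3(df: pd.DataFrame) -> pd.DataFrame:
    """Pairwise correlations among ASD, ESD and PSD (symmetric, no diagonal)."""
    rows = []
    for i, (lab_i, col_i) in enumerate(_DEPTHS):
        for lab_j, col_j in _DEPTHS[i + 1 :]:
            e = pearson(df[col_i], df[col_j], col_i, col_j)
            rows.append(
                {"x": lab_i, "y": lab_j, "r": e.r, "p_raw": e.p_raw}
            )
    return pd.DataFrame(rows)


def build_table4(df: pd.DataFrame) -> pd.DataFrame:
    """Multiple regression of the anterior IOL surface position on the depths."""
    X = df[["asd_mm", "esd_mm", "psd_mm"]]
    fit = multiple_regression(df["anterior_iol_mm"], X, response="anterior_iol_mm")
    label = dict((col, lab) for lab, col in _DEPTHS)
    rows = [
        {
            "variable": label[name],
            "coefficient": coef,
            "standardized_coefficient": std,
            "simple_r": pearson(df[name], df["anterior_iol_mm"]).r,
        }
        for name, coef, std in fit.terms
    ]
    rows.append(
        {
            "variable": "Constant",
            "coefficient": fit.intercept,
            "standardized_coefficient": np.nan,
            "simple_r": np.nan,
        }
    )
    out = pd.DataFrame(rows)
    out.attrs["r_squared_multiple"] = fit.r_squared_multiple
    return out


_FIGURES = {
    "fig2": [("lt_mm", "acr_mm"), ("lt_mm", "pcr_mm")],
    "fig3": [("lt_mm", "asd_mm"), ("lt_mm", "esd_mm"), ("lt_mm", "psd_mm")],
    "fig4": [("lt_mm", "central_iol_mm"), ("lt_mm", "predicted_iol_c_mm")],
    "fig5": [
        ("asd_mm", "predicted_iol_c_mm"),
        ("esd_mm", "predicted_iol_c_mm"),
        ("psd_mm", "predicted_iol_c_mm"),
    ],
    "fig6": [
        ("asd_mm", "anterior_iol_mm"),
        ("esd_mm", "anterior_iol_mm"),
        ("psd_mm", "anterior_iol_mm"),
    ],
    "fig7": [("diff_anterior_iol_mm", "prediction_error_d")],
    "fig8": [
        ("diff_asd_mm", "prediction_error_d"),
        ("diff_esd_mm", "prediction_error_d"),
        ("diff_psd_mm", "prediction_error_d"),
    ],
}


def figure_data(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-figure scatter data with the fitted regression line.

    Returns a mapping figure name → long DataFrame with columns
    ``series, x, y, slope, intercept`` (the line constant within a
    series).  Figures cover the scatter panels of the analysis: lens
    thickness vs curvature radii, depths and IOL positions; the depths vs
    the two position predictions; and the prediction error vs each
    depth-minus-SRK/T difference.
    """
    diffs = difference_vs_srkt(df)
    new_cols = [c for c in diffs.columns if c not in df.columns]
    work = df.join(diffs[new_cols]) if new_cols else df
    out = {}
    for fig, pairs in _FIGURES.items():
        frames = []
        for xcol, ycol in pairs:
            lin = sps.linregress(work[xcol], work[ycol])
            frames.append(
                pd.DataFrame(
                    {
                        "series": f"{ycol}~{xcol}",
                        "x": work[xcol],
                        "y": work[ycol],
                        "slope": lin.slope,
                        "intercept": lin.intercept,
                    }
                )
            )
        out[fig] = pd.concat(frames, ignore_index=True)
    return out
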