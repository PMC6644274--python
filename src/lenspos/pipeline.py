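"""End-to-end orchestration: cohort in, report bundle out.

The analysis mirrors the study protocol: optimize the A constant on the
cohort so the mean refractive prediction error is zero, recompute the
SRK/T predictions and per-eye errors with the optimized A, derive the
C-constant quantities, then build the summary, correlation,
inter-correlation and regression tables plus the per-figure scatter data.
All computation happens in the domain modules; this layer only sequences
operations, applies presentation rounding and writes files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import cohort_stats as cs
from . import iol_formulas as iol

__all__ = [
    "RunConfig",
    "SchemaError",
    "REQUIRED_COLUMNS",
    "derive_analysis_columns",
    "analyze",
    "write_reports",
    "write_cohort",
]

#: Columns a cohort CSV must carry to be analyzable.
REQUIRED_COLUMNS = [
    "age_years",
    "al_mm",
    "k_d",
    "acr_mm",
    "pcr_mm",
    "lt_mm",
    "asd_mm",
    "esd_mm",
    "psd_mm",
    "iol_power_d",
    "iol_thickness_mm",
    "anterior_iol_mm",
    "postop_se_d",
]


class SchemaError(ValueError):
    """Cohort table does not match the expected column dictionary."""


@dataclass(frozen=True)
class RunConfig:
    """Presentation and testing configuration of an analysis run."""

    alpha: float = 0.05
    family_map: dict = field(default_factory=lambda: dict(cs.DEFAULT_FAMILY_MAP))
    vertex_mm: float = 12.0
    round_mm: int = 2
    round_d: int = 2
    round_p: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _validate_schema(df: pd.DataFrame) -> None:
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing column: {col}")


def derive_analysis_columns(
    df: pd.DataFrame, config: RunConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Add the derived per-eye quantities the report tables consume.

    Optimizes the A constant on the cohort, then adds: SRK/T predicted
    ACD and refraction, prediction error, central/posterior IOL surface
    positions, the per-eye effective C constant, the C-constant predicted
    position (using the cohort-mean C, as the position predictor would be
    applied prospectively) and the depth-minus-SRK/T differences.

    Returns the augmented copy and a metadata dict (optimized A, mean C).
    """
    config = config or RunConfig()
    _validate_schema(df)
    if len(df) < 4:
        raise ValueError("statistical precondition failed: need at least 4 eyes")
    out = df.copy()
    a_opt = iol.optimize_a_constant(out, vertex=config.vertex_mm)
    out["predicted_acd_srkt_mm"] = iol.srkt_predicted_acd(
        out["al_mm"].to_numpy(), out["k_d"].to_numpy(), a_opt
    )
    out["predicted_refraction_d"] = iol.srkt_predicted_refraction(
        out["al_mm"].to_numpy(),
        out["k_d"].to_numpy(),
        a_opt,
        out["iol_power_d"].to_numpy(),
        vertex=config.vertex_mm,
    )
    out["prediction_error_d"] = iol.refractive_prediction_error(
        out["postop_se_d"].to_numpy(), out["predicted_refraction_d"].to_numpy()
    )
    out["central_iol_mm"] = out["anterior_iol_mm"] + out["iol_thickness_mm"] / 2.0
    out["posterior_iol_mm"] = out["anterior_iol_mm"] + out["iol_thickness_mm"]
    out["c_constant"] = iol.effective_c_constant(
        out["asd_mm"].to_numpy(),
        out["lt_mm"].to_numpy(),
        out["anterior_iol_mm"].to_numpy(),
        out["iol_thickness_mm"].to_numpy(),
    )
    c_mean = float(out["c_constant"].mean())
    out["predicted_iol_c_mm"] = iol.predict_iol_center(
        out["asd_mm"].to_numpy(), out["lt_mm"].to_numpy(), c_mean
    )
    diffs = cs.difference_vs_srkt(out)
    out = out.join(diffs)
    meta = {"a_constant_optimized": a_opt, "c_constant_mean": c_mean}
    return out, meta


def analyze(df: pd.DataFrame, config: RunConfig | None = None):
    """Run the full statistical surface on a cohort table.

    Returns ``(tables, figures, meta)`` where ``tables`` maps
    ``table1_summary`` … ``table4_regression`` to DataFrames and
    ``figures`` maps figure names to scatter DataFrames.
    """
    config = config or RunConfig()
    work, meta = derive_analysis_columns(df, config)
    tables = {
        "table1_summary": cs.build_table1(work),
        "table2_correlations": cs.build_table2(work, config.family_map),
        "table3_intercorrelations": cs.build_table3(work),
        "table4_regression": cs.build_table4(work),
    }
    meta["r_squared_multiple"] = tables["table4_regression"].attrs[
        "r_squared_multiple"
    ]
    figures = cs.figure_data(work)
    return tables, figures, meta


def _round_table(table: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Presentation rounding: depths/coefficients 2 dp, p-values 3 dp."""
    out = table.copy()
    for col in out.columns:
        if out[col].dtype.kind != "f":
            continue
        digits = config.round_p if col.startswith("p_") else config.round_mm
        out[col] = out[col].round(digits)
    return out


def _to_markdown(table: pd.DataFrame) -> str:
    header = "| " + " | ".join(table.columns) + " |"
    sep = "| " + " | ".join("---" for _ in table.columns) + " |"
    rows = [
        "| " + " | ".join("" if pd.isna(v) else str(v) for v in rec) + " |"
        for rec in table.itertuples(index=False)
    ]
    return "\n".join([header, sep, *rows]) + "\n"


def write_reports(tables, figures, meta, outdir, config: RunConfig | None = None):
    """Write TSV + markdown tables, figure CSVs and a metadata sidecar."""
    config = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        rounded = _round_table(table, config)
        rounded.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        (outdir / f"{name}.md").write_text(_to_markdown(rounded))
    for name, fig in figures.items():
        fig.to_csv(outdir / f"{name}.csv", index=False)
    meta_out = dict(meta)
    meta_out["version"] = __version__
    meta_out["config"] = dataclasses.asdict(config)
    (outdir / "analysis_meta.json").write_text(
        json.dumps(meta_out, indent=2, sort_keys=True) + "\n"
    )


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort CSV plus a provenance sidecar (params, seed, version)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    sidecar = {
        "version": __version__,
        "params": df.attrs.get("params"),
        "rejections": df.attrs.get("rejections"),
        "sha256": digest,
    }
    path.with_suffix(".provenance.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )
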