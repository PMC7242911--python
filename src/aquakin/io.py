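"""Readers, writers and the pipeline runner.

All on-disk formats are plain text: CSV for traces and tables (units are
explicit in the column names, e.g. ``time_s``, ``concentration_um``,
``wet_g``) and JSON for configuration and AssayReports.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd

from aquakin.report import AssayReport, make_provenance

__all__ = ["read_trace", "write_trace", "read_titration", "run_pipeline",
           "PipelineError", "VALID_STAGES"]


class PipelineError(RuntimeError):
    pass


def read_trace(path: str | Path, time_col: str = "time_s") -> pd.DataFrame:
    """Read and validate a two-or-more-column trace CSV.

    The time column must exist, be numeric and strictly increasing; every
    other column must be numeric. Errors name the offending column and row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if time_col not in df.columns:
        raise ValueError(f"{path.name}: missing time column {time_col!r} "
                         f"(found {list(df.columns)})")
    if df.shape[1] < 2:
        raise ValueError(f"{path.name}: need at least one signal column")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path.name}: non-numeric value in column {col!r}, row {row}"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna())[0])
            raise ValueError(f"{path.name}: missing value in column {col!r}, "
                             f"row {row}")
        df[col] = coerced
    t = df[time_col].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path.name}: column {time_col!r} must be strictly "
                         "increasing")
    return df


def write_trace(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_titration(path: str | Path):
    """Read a titration CSV (concentration_um, signal[, replicate])."""
    from aquakin.binding import TitrationSeries

    df = pd.read_csv(path)
    for col in ("concentration_um", "signal"):
        if col not in df.columns:
            raise ValueError(f"{Path(path).name}: missing column {col!r}")
    rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
    return df, rep


# ---------------------------------------------------------------------------
# pipeline


def _stage_simulate_mst(cfg: dict, ctx: dict) -> AssayReport:
    from aquakin.simulate import MstDesign, gen_mst_titration

    design = MstDesign(**cfg.get("design", {}))
    series = gen_mst_titration(
        s1=cfg.get("s1", 1.0), s2=cfg.get("s2", 0.9),
        kd=cfg.get("kd", 29.0), design=design,
        seed=ctx["seed"], no_binding=cfg.get("no_binding", False),
    )
    ctx["titration"] = series
    rep = AssayReport("mst_binding", provenance=ctx["provenance"])
    rep.add_parameter("n_points", len(series.l_tot), units="count")
    rep.flags.append("stage:simulate_mst")
    return rep


def _stage_fit_binding(cfg: dict, ctx: dict) -> AssayReport:
    from aquakin.binding import fit_binding

    series = ctx.get("titration")
    if series is None:
        raise PipelineError("fit_binding requires a prior simulate_mst stage "
                            "or an input titration")
    fit = fit_binding(series)
    ctx["binding_fit"] = fit
    rep = AssayReport("mst_binding", provenance=ctx["provenance"])
    rep.add_parameter("s1", fit.s1, fit.se_s1)
    rep.add_parameter("s2", fit.s2, fit.se_s2)
    rep.add_parameter("kd", fit.kd, fit.se_kd, units="uM")
    if not fit.binding_detected:
        rep.flags.append("no_binding_detected")
    if not fit.converged:
        rep.flags.append("not_converged")
    return rep


def _stage_ztest(cfg: dict, ctx: dict) -> AssayReport:
    from aquakin.stats import EstimateWithError, z_test_estimates

    a = EstimateWithError(*cfg["a"])
    b = EstimateWithError(*cfg["b"])
    res = z_test_estimates(a, b, tail=cfg.get("tail", "one"))
    rep = AssayReport("stats", provenance=ctx["provenance"])
    rep.add_parameter("z", res.z)
    rep.add_parameter("p", res.p)
    rep.flags.extend(res.flags)
    return rep


def _stage_simulate_stopflow(cfg: dict, ctx: dict) -> AssayReport:
    from aquakin.simulate import StopFlowDesign, gen_stopflow_trace

    design = StopFlowDesign(**cfg.get("design", {}))
    ctx["stopflow_trace"] = gen_stopflow_trace(design, seed=ctx["seed"])
    rep = AssayReport("stopflow", provenance=ctx["provenance"])
    rep.add_parameter("n_samples", len(ctx["stopflow_trace"].time), units="count")
    rep.flags.append("stage:simulate_stopflow")
    return rep


def _stage_fit_stopflow(cfg: dict, ctx: dict) -> AssayReport:
    from aquakin.permeability import (
        LiposomeGeometry, fit_double_exponential, osmotic_permeability,
    )

    trace = ctx.get("stopflow_trace")
    if trace is None:
        raise PipelineError("fit_stopflow requires a prior simulate_stopflow "
                            "stage or an input trace")
    fit = fit_double_exponential(trace)
    geom = LiposomeGeometry(**cfg.get("geometry", {}))
    pf = osmotic_permeability(fit.k_selected, geom)
    rep = AssayReport("stopflow", provenance=ctx["provenance"])
    rep.add_parameter("k_fast", fit.k_fast, units="1/s")
    rep.add_parameter("k_slow", fit.k_slow, units="1/s")
    rep.add_parameter("pf", pf, units="cm/s")
    if fit.single_exponential:
        rep.flags.append("single_exponential_fallback")
    return rep


STAGES: dict[str, Callable[[dict, dict], AssayReport]] = {
    "simulate_mst": _stage_simulate_mst,
    "fit_binding": _stage_fit_binding,
    "ztest": _stage_ztest,
    "simulate_stopflow": _stage_simulate_stopflow,
    "fit_stopflow": _stage_fit_stopflow,
}

VALID_STAGES = tuple(STAGES)


def run_pipeline(config: dict[str, Any],
                 out_dir: str | Path | None = None) -> list[AssayReport]:
    """Execute the configured stages in order, sharing one provenance block.

    ``config`` holds ``seed`` and a ``stages`` list of
    ``{"name": ..., **stage-options}`` dicts. Reports are written to
    ``out_dir`` (when given) as each stage completes, so reports from
    stages preceding a failure survive on disk. Unknown stage names raise
    a PipelineError listing the valid stages.
    """
    seed = int(config.get("seed", 0))
    stages = config.get("stages", [])
    provenance = make_provenance(config=config, seed=seed)
    ctx: dict[str, Any] = {"seed": seed, "provenance": provenance}
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    reports: list[AssayReport] = []
    for i, stage_cfg in enumerate(stages):
        name = stage_cfg.get("name")
        if name not in STAGES:
            raise PipelineError(
                f"unknown stage {name!r}; valid stages: {sorted(STAGES)}"
            )
        rep = STAGES[name](stage_cfg, ctx)
        reports.append(rep)
        if out_dir is not None:
            rep.save(out_dir / f"{i:02d}_{name}.json")
    return reports


def load_config(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
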