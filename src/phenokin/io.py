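"""Table readers/writers and the end-to-end analysis pipeline.

The on-disk interchange format is a UTF-8 comma-separated table with a
header row ``reactor,time_h,analyte,conc_mg_L``; one row per measurement.
The pipeline reads such a table (or generates a synthetic assay), fits
every (reactor, analyte) series, summarises removals, compares the fitted
first-order constants pairwise, and writes delimited reports whose column
order mirrors the campaign summary tables (p, h, q, S0-q, K0, K1, K2, R).
Rounding is applied only when formatting; stored values keep full
precision.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import DEFAULT_R_THRESHOLD, FitError, FitResult, ReactorSeries, fit_series
from .stats import pairwise_comparisons, removal_percent

__all__ = [
    "REQUIRED_COLUMNS",
    "SeriesTableError",
    "RunConfig",
    "ReportBundle",
    "read_series_table",
    "write_series_table",
    "run_pipeline",
]

logger = logging.getLogger("phenokin")

REQUIRED_COLUMNS = ("reactor", "time_h", "analyte", "conc_mg_L")

FIT_COLUMNS = ["reactor", "analyte", "p", "h", "q", "s0_minus_q",
               "k0", "k1", "k2", "r", "se_k1", "n_obs", "good_fit"]


class SeriesTableError(ValueError):
    """Malformed series table; the message names the offending lines."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run; JSON round-trippable."""

    input_path: Optional[str] = None
    analyte: str = "phenol"
    fix_s0: bool = True
    alpha: float = 0.05
    bonferroni: bool = False
    r_threshold: float = DEFAULT_R_THRESHOLD
    restart_seed: int = 20221031
    output_dir: Optional[str] = None
    percent_decimals: int = 1
    rate_decimals: int = 3

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class ReportBundle:
    """Pipeline output: fit, removal and comparison tables plus failures."""

    fits: pd.DataFrame
    removals: pd.DataFrame
    comparisons: pd.DataFrame
    fit_results: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.fits.to_csv(outdir / "fits.csv", index=False)
        self.removals.to_csv(outdir / "removals.csv", index=False)
        self.comparisons.to_csv(outdir / "comparisons.csv", index=False)
        sidecar = {
            "failures": {k: str(v) for k, v in self.failures.items()},
            "n_fits": int(len(self.fits)),
        }
        (outdir / "report.json").write_text(json.dumps(sidecar, indent=2))


def read_series_table(path) -> list[ReactorSeries]:
    """Read a measurement table into one series per (reactor, analyte).

    Validates the header, numeric fields and uniqueness of
    (reactor, analyte, time) triples; errors name the offending file lines
    (1-based, header = line 1).  Rows with a missing concentration are
    dropped with a logged warning.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"reactor": str, "analyte": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SeriesTableError(f"{path}: missing required columns {missing}")

    lines = df.index + 2  # header occupies line 1
    for col in ("time_h", "conc_mg_L"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            raise SeriesTableError(
                f"{path}: non-numeric {col} on line(s) {list(lines[bad])}"
            )
        df[col] = coerced

    absent = df["conc_mg_L"].isna() | df["time_h"].isna()
    if absent.any():
        logger.warning("%s: dropping %d row(s) with missing values (lines %s)",
                       path, int(absent.sum()), list(lines[absent]))
        df = df[~absent]

    dup = df.duplicated(subset=["reactor", "analyte", "time_h"], keep=False)
    if dup.any():
        raise SeriesTableError(
            f"{path}: duplicate (reactor, analyte, time) rows on line(s) "
            f"{list(df.index[dup] + 2)}"
        )

    out = []
    for (reactor, analyte), grp in df.groupby(["reactor", "analyte"], sort=True):
        grp = grp.sort_values("time_h")
        out.append(ReactorSeries(
            reactor_id=str(reactor), analyte=str(analyte),
            times=grp["time_h"].to_numpy(float),
            concentrations=grp["conc_mg_L"].to_numpy(float),
        ))
    return out


def write_series_table(series: Sequence[ReactorSeries], path) -> None:
    """Write series to the interchange CSV (full-precision decimals)."""
    rows = [
        {"reactor": s.reactor_id, "time_h": t, "analyte": s.analyte, "conc_mg_L": c}
        for s in series
        for t, c in zip(s.times, s.concentrations)
    ]
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(
        path, index=False, float_format="%.10g"
    )


def _fit_row(series: ReactorSeries, fr: FitResult) -> dict:
    d, c = fr.derived, fr.coeffs
    return {
        "reactor": series.reactor_id,
        "analyte": series.analyte,
        "p": d.p, "h": d.h, "q": d.q, "s0_minus_q": d.s0 - d.q,
        "k0": c.k0, "k1": c.k1, "k2": c.k2, "r": fr.r,
        "se_k1": fr.standard_errors.get("k1", float("nan")),
        "n_obs": fr.n_obs, "good_fit": fr.good_fit,
    }


def run_pipeline(config: RunConfig, series: Optional[Sequence[ReactorSeries]] = None) -> ReportBundle:
    """Fit, summarise and compare every series of the selected analyte.

    ``series`` may be passed directly (e.g. from the generator); otherwise
    ``config.input_path`` is read.  A fit failure on one reactor is logged
    and recorded in ``failures`` while the remaining reactors proceed.
    Deterministic given the config seeds.
    """
    if series is None:
        if config.input_path is None:
            raise ValueError("config.input_path is unset and no series were passed")
        series = read_series_table(config.input_path)
    selected = [s for s in series if s.analyte == config.analyte]

    fit_rows, removal_rows = [], []
    fit_results, failures = {}, {}
    for s in selected:
        removal_rows.append({
            "reactor": s.reactor_id, "analyte": s.analyte,
            "initial": float(s.concentrations[0]),
            "final": float(s.concentrations[-1]),
            "percent_removal": removal_percent(
                float(s.concentrations[0]), float(s.concentrations[-1])
            ),
        })
        try:
            fr = fit_series(s, fix_s0=config.fix_s0,
                            r_threshold=config.r_threshold,
                            restart_seed=config.restart_seed)
        except (FitError, ValueError) as exc:
            logger.error("fit failed for reactor %s (%s): %s",
                         s.reactor_id, s.analyte, exc)
            failures[s.reactor_id] = exc
            continue
        fit_results[s.reactor_id] = fr
        fit_rows.append(_fit_row(s, fr))

    fits = pd.DataFrame(fit_rows, columns=FIT_COLUMNS)
    removals = pd.DataFrame(
        removal_rows,
        columns=["reactor", "analyte", "initial", "final", "percent_removal"],
    )

    comp_input = [
        (label, fr.coeffs.k1, fr.standard_errors.get("k1", float("nan")), fr.n_obs)
        for label, fr in sorted(fit_results.items())
        if np.isfinite(fr.standard_errors.get("k1", float("nan")))
        and fr.standard_errors.get("k1", 0.0) > 0
    ]
    comparisons = pd.DataFrame(
        columns=["treatment_a", "treatment_b", "statistic", "dof",
                 "p_value", "significant"]
    )
    if len(comp_input) >= 2:
        comps = pairwise_comparisons(comp_input, alpha=config.alpha,
                                     bonferroni=config.bonferroni)
        comparisons = pd.DataFrame([
            {"treatment_a": c.treatment_a, "treatment_b": c.treatment_b,
             "statistic": c.statistic, "dof": c.dof,
             "p_value": c.p_value, "significant": c.significant}
            for c in comps
        ])

    bundle = ReportBundle(fits=fits, removals=removals, comparisons=comparisons,
                          fit_results=fit_results, failures=failures)
    if config.output_dir:
        bundle.write(config.output_dir)
    return bundle
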