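"""End-to-end run orchestration: cohorts -> life tables -> bootstrap -> comparison,
and bioassay tables -> LT50 / LC50 reports.

Every output CSV starts with a comment line embedding a hash of the run
configuration, so a result file can always be traced to the exact settings
that produced it; re-running with an identical configuration and seed
reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bioassay as ba
from .bootstrap import bootstrap_parameters, compare_many
from .cohort import DEFAULT_STAGE_ORDER, read_bioassay, read_cohort
from .lifetable import (
    build_age_stage_counts,
    fecundity_schedule,
    intrinsic_rate,
    life_expectancy,
    net_reproductive_rate,
    reproductive_value,
    survival_matrix,
    transition_model,
)

log = logging.getLogger("agestage")

__all__ = ["RunConfig", "PipelineError", "run_lifetable_pipeline", "run_bioassay_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run."""

    cohorts: dict[str, str] = field(default_factory=dict)  # label -> CSV path
    bioassay: str | None = None
    stage_order: tuple[str, ...] = DEFAULT_STAGE_ORDER
    bootstrap_B: int = 100_000
    seed: int = 42
    alpha: float = 0.05
    out_dir: str = "results"
    plots: bool = False
    lc50_day: int = 14
    allow_stage_skip: bool = False

    def __post_init__(self):
        if self.bootstrap_B < 1:
            raise ValueError("bootstrap_B must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def hash(self) -> str:
        """Hash of the analysis-defining settings (the output location excluded)."""
        payload = json.dumps(
            {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()
                if k != "out_dir"
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# config={config_hash}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def _tidy_matrix(mat, states, value_name="value") -> pd.DataFrame:
    arr = np.ma.filled(np.ma.asarray(mat, dtype=float), np.nan)
    rows = []
    for x in range(arr.shape[0]):
        for j, st in enumerate(states):
            v = arr[x, j]
            if not np.isnan(v):
                rows.append({"age": x, "stage": st, value_name: v})
    return pd.DataFrame(rows)


def run_lifetable_pipeline(config: RunConfig) -> dict:
    """Full demographic analysis of one or more cohorts.

    Writes, per cohort, the tidy age-stage survival (``sxj.csv``), the
    l_x/f_x/m_x schedule (``schedule.csv``), life expectancy (``exj.csv``),
    reproductive value (``vxj.csv``) and the bootstrap parameter summary
    (``params.csv``); with more than one cohort a Holm-lettered comparison
    table (``comparison.csv``).  Returns the in-memory bundle.
    """
    if not config.cohorts:
        raise PipelineError("lifetable pipeline: no cohort inputs configured")
    missing = [p for p in config.cohorts.values() if not Path(p).exists()]
    if missing:
        raise PipelineError(f"lifetable pipeline: missing input files {missing}")

    h = config.hash()
    out = Path(config.out_dir)
    bundle: dict = {"config_hash": h, "cohorts": {}}
    boots = {}
    for label, path in config.cohorts.items():
        log.info("lifetable: cohort %s from %s (seed=%d)", label, path, config.seed)
        try:
            cohort = read_cohort(
                path, config.stage_order, config.allow_stage_skip, label=label
            )
        except Exception as exc:
            raise PipelineError(f"lifetable pipeline: reading {path}: {exc}") from exc
        counts = build_age_stage_counts(cohort)
        s = survival_matrix(counts)
        fs = fecundity_schedule(cohort, s)
        tm = transition_model(cohort)
        R0 = net_reproductive_rate(fs)
        r = intrinsic_rate(fs) if R0 > 0 else None
        exj = life_expectancy(tm)
        vxj = reproductive_value(tm, fs, r) if r is not None else None

        log.info("lifetable: bootstrap %s B=%d", label, config.bootstrap_B)
        boot = bootstrap_parameters(cohort, B=config.bootstrap_B, seed=config.seed)
        boots[label] = boot

        d = out / label
        _write_csv(_tidy_matrix(s.s, s.states), d / "sxj.csv", h)
        _write_csv(
            pd.DataFrame(
                {"age": np.arange(fs.l.size), "lx": fs.l, "mx": fs.m,
                 "fx": fs.f.sum(axis=1)}
            ),
            d / "schedule.csv",
            h,
        )
        _write_csv(_tidy_matrix(exj, s.states), d / "exj.csv", h)
        if vxj is not None:
            _write_csv(_tidy_matrix(vxj, s.states), d / "vxj.csv", h)
        est = boot.estimates
        _write_csv(
            pd.DataFrame(
                {
                    "parameter": list(est),
                    "estimate": [est[p] for p in est],
                    "se": [boot.se[p] for p in est],
                    "ci_low": [boot.percentiles[p][0] for p in est],
                    "ci_high": [boot.percentiles[p][1] for p in est],
                }
            ),
            d / "params.csv",
            h,
        )
        if config.plots:
            _save_plots(d, s, fs, exj, vxj)
        bundle["cohorts"][label] = {
            "survival": s, "schedule": fs, "transitions": tm,
            "exj": exj, "vxj": vxj, "bootstrap": boot,
        }

    if len(boots) > 1:
        comparison = compare_many(boots, alpha=config.alpha)
        _write_csv(comparison, out / "comparison.csv", h)
        bundle["comparison"] = comparison
    return bundle


def _save_plots(outdir: Path, s, fs, exj, vxj) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    panels = [("sxj", s.s, "age-stage survival rate s_xj")]
    if exj is not None:
        panels.append(("exj", np.ma.filled(exj, np.nan), "life expectancy e_xj"))
    if vxj is not None:
        panels.append(("vxj", np.ma.filled(vxj, np.nan), "reproductive value v_xj"))
    ages = np.arange(s.s.shape[0])
    for name, mat, title in panels:
        fig, ax = plt.subplots(figsize=(6, 4))
        for j, st in enumerate(s.states):
            col = np.asarray(mat)[:, j]
            if np.nansum(np.abs(col)) > 0:
                ax.plot(ages, col, label=st)
        ax.set_xlabel("age (days)")
        ax.set_title(title)
        ax.legend(fontsize=7)
        fig.savefig(outdir / f"{name}.png", dpi=120)
        plt.close(fig)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ages, fs.l, label="l_x")
    ax2 = ax.twinx()
    ax2.plot(ages, fs.m, color="C1", label="m_x")
    ax.set_xlabel("age (days)")
    ax.set_ylabel("l_x")
    ax2.set_ylabel("m_x (eggs/day)")
    fig.savefig(outdir / "schedule.png", dpi=120)
    plt.close(fig)


def run_bioassay_pipeline(config: RunConfig) -> dict:
    """Time-mortality and dose-response analysis of a bioassay table.

    For each (strain, concentration) series the replicate-mean cumulative
    mortality is Abbott-corrected against concentration-0 rows when present,
    the logistic time-mortality curve is fitted, and LT50 (or the reason it is
    undefined) reported; per strain a probit LC50 at ``config.lc50_day`` is
    estimated whenever at least three positive concentrations are available.
    """
    if not config.bioassay:
        raise PipelineError("bioassay pipeline: no input configured")
    if not Path(config.bioassay).exists():
        raise PipelineError(f"bioassay pipeline: missing input {config.bioassay}")
    h = config.hash()
    out = Path(config.out_dir)
    table = read_bioassay(config.bioassay)
    df = table.data

    def mean_mortality(sub: pd.DataFrame) -> pd.Series:
        pct = 100.0 * sub["n_dead_cum"] / sub["n_total"]
        return pct.groupby(sub["day"]).mean()

    controls = df[df["concentration"] == 0]
    control_by_day = mean_mortality(controls) / 100.0 if len(controls) else None

    tm_rows = []
    fits: dict = {}
    for (strain, conc), sub in df[df["concentration"] > 0].groupby(
        ["strain", "concentration"]
    ):
        series = mean_mortality(sub)
        if control_by_day is not None:
            ctrl = control_by_day.reindex(series.index).fillna(0.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # sub-control days clip to 0 below
                corrected = [
                    ba.abbott_correction(p / 100.0, c) for p, c in zip(series, ctrl)
                ]
            # day-wise correction can wobble; restore cumulativity
            series = pd.Series(corrected, index=series.index).clip(lower=0.0).cummax()
        row = {"strain": strain, "concentration": conc}
        try:
            fit = ba.fit_time_mortality(series.index.to_numpy(), series.to_numpy())
            res = ba.lt50(fit)
            row.update(
                K=fit.K, a=fit.a, b=fit.b, r2=fit.r2,
                lt50=res.value if res.defined else None,
                lt50_note="" if res.defined else f"— ({res.reason})",
            )
            fits[(strain, conc)] = fit
        except (ba.FitFailureError, ValueError) as exc:
            row.update(K=None, a=None, b=None, r2=None, lt50=None,
                       lt50_note=f"— ({exc})")
        tm_rows.append(row)
    tm_table = pd.DataFrame(tm_rows)
    _write_csv(tm_table, out / "time_mortality.csv", h)

    lc_rows = []
    day = config.lc50_day
    for strain, sub in df[(df["concentration"] > 0) & (df["day"] == day)].groupby(
        "strain"
    ):
        agg = sub.groupby("concentration")[["n_total", "n_dead_cum"]].sum()
        if len(agg) < 3:
            continue
        try:
            drf = ba.fit_dose_response(
                agg.index.to_numpy(), agg["n_total"].to_numpy(), agg["n_dead_cum"].to_numpy()
            )
            ci = drf.lc50_ci or (None, None)
            lc_rows.append(
                {"strain": strain, "day": day, "lc50": drf.lc50,
                 "ci_low": ci[0], "ci_high": ci[1], "slope": drf.slope,
                 "chi2_gof": drf.chi2_gof, "valid": drf.valid}
            )
        except ba.SeparationError as exc:
            lc_rows.append({"strain": strain, "day": day, "lc50": None,
                            "ci_low": None, "ci_high": None, "slope": None,
                            "chi2_gof": None, "valid": False, "note": str(exc)})
    if lc_rows:
        _write_csv(pd.DataFrame(lc_rows), out / "lc50.csv", h)
    return {"config_hash": h, "time_mortality": tm_table,
            "lc50": pd.DataFrame(lc_rows), "fits": fits}
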