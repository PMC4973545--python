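"""End-to-end orchestration: files in, report tables and model files out.

``run_calibration`` reproduces the whole workflow for one constituent:
average replicate scans, split calibration/validation, search the
pre-treatment grid, validate the winner, and write a leaderboard TSV, a
validation TSV, a serialized model and a run log.  ``run_report`` renders
summary tables (per-set composition/energy summaries, calibration and
validation statistics) in the layout conventional for NIRS calibration
reports.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import model_selection as ms
from .mpls import MPLSModel
from .pretreatment import (
    PretreatmentSpec,
    ScatterReference,
    build_grid,
    parse_treatment_code,
    reduced_grid,
)
from .spectra_io import (
    COMPOSITION_COLUMNS,
    ENERGY_COLUMNS,
    ReferenceTable,
    SpectraSet,
    average_duplicates,
    read_spectra,
    split_cal_val,
)
from .stats import EvalStats, summary_stats

__all__ = ["RunConfig", "run_calibration", "run_report", "save_model", "load_model"]


@dataclasses.dataclass
class RunConfig:
    """Configuration of one calibration run (defaults are the standard protocol)."""

    spectra_path: str
    reference_path: str
    constituent: str = "de_d"
    outdir: str = "nirscal_out"
    n_val: int = 29
    cv_groups: int = 6
    gh_threshold: float = ms.DEFAULT_GH_THRESHOLD
    t_threshold: float = ms.DEFAULT_T_THRESHOLD
    max_passes: int = 2
    max_factors: int | None = None
    grid: str = "full"  # "full" (77 cells) or "reduced" (20 cells)
    seed: int = 0

    def grid_specs(self) -> list[PretreatmentSpec]:
        if self.grid == "full":
            return build_grid()
        if self.grid == "reduced":
            return reduced_grid()
        # otherwise a comma-of-semicolons spec list: "2,4,4,1+SNVD;0,0,1,1+None"
        specs = []
        for item in self.grid.split(";"):
            code, _, method = item.strip().partition("+")
            specs.append(parse_treatment_code(code, scatter_method=method or "None"))
        return specs


def _spec_to_dict(spec: PretreatmentSpec) -> dict:
    d = {
        "derivative_order": spec.derivative_order,
        "gap": spec.gap,
        "segment1": spec.segment1,
        "segment2": spec.segment2,
        "scatter_method": spec.scatter_method,
    }
    if spec.reference is not None:
        d["reference"] = {
            "mean_spectrum": spec.reference.mean_spectrum.tolist(),
            "weights": None
            if spec.reference.weights is None
            else spec.reference.weights.tolist(),
        }
    return d


def _spec_from_dict(d: dict) -> PretreatmentSpec:
    ref = None
    if d.get("reference") is not None:
        ref = ScatterReference(
            np.asarray(d["reference"]["mean_spectrum"], dtype=float),
            None
            if d["reference"]["weights"] is None
            else np.asarray(d["reference"]["weights"], dtype=float),
        )
    return PretreatmentSpec(
        d["derivative_order"], d["gap"], d["segment1"], d["segment2"],
        scatter_method=d["scatter_method"], reference=ref,
    )


def save_model(result: ms.CalibrationResult, path: str | Path) -> None:
    """Serialize a calibration (model + pre-treatment + audit trail) to JSON."""
    payload = {
        "format": "nirscal-calibration/1",
        "pretreatment": _spec_to_dict(result.pretreatment),
        "model": result.model.to_dict(),
        "n_used": result.n_used,
        "kept_ids": result.kept_ids,
        "removed": result.removed,
        "passes": result.passes,
        "secv_curve": result.secv_curve.tolist(),
        "opt_factors": result.opt_factors,
        "stats": dataclasses.asdict(result.stats),
        "seed": result.seed,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> ms.CalibrationResult:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "nirscal-calibration/1":
        raise ValueError(f"unknown calibration format {payload.get('format')!r}")
    return ms.CalibrationResult(
        pretreatment=_spec_from_dict(payload["pretreatment"]),
        model=MPLSModel.from_dict(payload["model"]),
        n_used=payload["n_used"],
        kept_ids=payload["kept_ids"],
        removed=payload["removed"],
        passes=payload["passes"],
        secv_curve=np.asarray(payload["secv_curve"], dtype=float),
        opt_factors=payload["opt_factors"],
        stats=EvalStats(**payload["stats"]),
        seed=payload["seed"],
    )


_LEADERBOARD_FORMATS = {
    "mean": "{:.2f}", "sd": "{:.3f}", "sec": "{:.3f}", "rsq_cal": "{:.2f}",
    "secv": "{:.3f}", "r2_cv": "{:.2f}", "rpd_cv": "{:.2f}",
    "sep": "{:.3f}", "rsq_v": "{:.2f}", "rpd_v": "{:.2f}", "bias": "{:.3f}",
}


def _format_table(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    for col, fmt in _LEADERBOARD_FORMATS.items():
        if col in out.columns:
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else fmt.format(v)  # noqa: B023
            )
    return out


def run_calibration(cfg: RunConfig) -> dict:
    """Execute the full pipeline for one constituent; returns artifacts.

    Output files in ``cfg.outdir``: ``leaderboard_<constituent>.tsv`` (one
    row per grid cell, ranked), ``model_<constituent>.json`` (winner),
    ``validation_<constituent>.tsv`` and ``run_<constituent>.log``.
    """
    spectra = read_spectra(cfg.spectra_path)
    reference = ReferenceTable.from_csv(cfg.reference_path)
    if cfg.constituent not in reference.data.columns:
        raise KeyError(f"constituent {cfg.constituent!r} not in the reference table")

    averaged = average_duplicates(spectra)
    cal_ids, val_ids = split_cal_val(averaged.sample_ids, cfg.n_val, cfg.seed)
    s_cal = averaged.select_samples(cal_ids)
    s_val = averaged.select_samples(val_ids)
    y_cal = reference.values(cfg.constituent, cal_ids)
    y_val = reference.values(cfg.constituent, val_ids)

    search = ms.grid_search(
        s_cal,
        y_cal,
        grid=cfg.grid_specs(),
        seed=cfg.seed,
        max_factors=cfg.max_factors,
        n_groups=cfg.cv_groups,
        gh_threshold=cfg.gh_threshold,
        t_threshold=cfg.t_threshold,
        max_passes=cfg.max_passes,
    )
    val_stats = ms.validate(search.best, s_val, y_val)

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = cfg.constituent
    _format_table(search.leaderboard).to_csv(
        outdir / f"leaderboard_{tag}.tsv", sep="\t", index=False
    )
    save_model(search.best, outdir / f"model_{tag}.json")
    val_row = pd.DataFrame([{"constituent": tag.upper(), **dataclasses.asdict(val_stats)}])
    _format_table(val_row).to_csv(outdir / f"validation_{tag}.tsv", sep="\t", index=False)

    best = search.best
    log_lines = [
        f"constituent: {tag}",
        f"seed: {cfg.seed}",
        f"grid: {cfg.grid} ({len(search.results)} cells)",
        f"winner: {best.pretreatment.label}, {best.opt_factors} factors, "
        f"n={best.n_used}, passes={best.passes}",
        "secv_curve: " + " ".join(f"{v:.4f}" for v in best.secv_curve),
        f"removed: {json.dumps(best.removed)}",
    ]
    (outdir / f"run_{tag}.log").write_text("\n".join(log_lines) + "\n")

    return {
        "search": search,
        "validation": val_stats,
        "cal_ids": cal_ids,
        "val_ids": val_ids,
        "outdir": outdir,
    }


def summary_table(
    reference: ReferenceTable, sets: dict[str, Sequence[str]] | None = None
) -> pd.DataFrame:
    """Per-set min/max/mean/SD/CV% of every composition and energy column."""
    if sets is None:
        sets = {"entire": reference.sample_ids}
    rows = []
    for set_name, ids in sets.items():
        for col in (*COMPOSITION_COLUMNS, *ENERGY_COLUMNS):
            if col not in reference.data.columns:
                continue
            st = summary_stats(reference.values(col, ids))
            rows.append(
                {
                    "set": set_name, "item": col, "n": st.n,
                    "min": st.min, "max": st.max, "mean": st.mean,
                    "sd": st.sd, "cv": st.cv,
                }
            )
    return pd.DataFrame(rows)


def run_report(
    reference: ReferenceTable,
    calibrations: dict[str, ms.CalibrationResult] | None = None,
    validations: dict[str, EvalStats] | None = None,
    sets: dict[str, Sequence[str]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Assemble the three standard report tables from serialized results.

    Returns dataframes keyed ``summary`` (per-set distribution of every
    constituent), ``calibration`` (winner rows: derivative, scatter,
    factors, n, mean, SD, SEC, RSQ_cal, SECV, R²cv, RPD_cv) and
    ``validation`` (n, mean, SD, SEP, RSQ_v, RPD_v).
    """
    tables: dict[str, pd.DataFrame] = {"summary": summary_table(reference, sets)}
    if calibrations:
        rows = []
        for name, res in calibrations.items():
            st = res.stats
            rows.append(
                {
                    "constituent": name.upper(),
                    "derivative": res.pretreatment.code,
                    "scatter": res.pretreatment.scatter_method,
                    "factors": res.opt_factors,
                    "n": res.n_used,
                    "mean": st.mean, "sd": st.sd, "sec": st.sec,
                    "rsq_cal": st.rsq_cal, "secv": st.secv,
                    "r2_cv": st.r2_cv, "rpd_cv": st.rpd_cv,
                }
            )
        tables["calibration"] = pd.DataFrame(rows)
    if validations:
        rows = [
            {"constituent": name.upper(), "n": st.n, "mean": st.mean, "sd": st.sd,
             "sep": st.sep, "rsq_v": st.rsq_v, "rpd_v": st.rpd_v}
            for name, st in validations.items()
        ]
        tables["validation"] = pd.DataFrame(rows)
    return tables
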