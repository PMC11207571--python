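"""End-to-end composition: wells -> efflux -> K_p,uu models -> reports."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from . import __version__
from .classify import classify_compound, summarize_performance
from .compare import dynamic_range_iqr, pairwise_correlation
from .errors import InsufficientDataError, InvalidInputError
from .ic50 import correct_ic50, fit_ic50
from .io import PipelineConfig
from .kpuu import (
    KpuuObservation,
    evaluate_prediction,
    fit_scaling_factors,
    predict_kpuu_mdr1_ref,
    predict_kpuu_ref,
    predict_kpuu_scaled,
    predict_kpuu_total,
)
from .simulate import MDR1_LINES, GeneratorConfig, SimulatedStudy, simulate_study
from .transport import QCSettings, build_efflux_table, build_total_efflux_table, compute_ref

__all__ = ["run_pipeline", "run_simulated_pipeline", "report_to_json"]


def _jsonable(obj):
    if isinstance(obj, dict):
        # private keys hold in-memory tables, not report content
        return {str(k): _jsonable(v) for k, v in obj.items() if not str(k).startswith("_")}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def report_to_json(report: dict) -> str:
    """Deterministic serialization (sorted keys, no timestamps)."""
    return json.dumps(_jsonable(report), sort_keys=True, indent=2)


def _classification_block(er: pd.Series, kpuu: pd.Series, er_cutoff: float, kpuu_cutoff: float):
    quadrants = [
        classify_compound(e, k, er_cutoff=er_cutoff, kpuu_cutoff=kpuu_cutoff)
        for e, k in zip(er, kpuu)
    ]
    metrics = summarize_performance(quadrants)
    return metrics, quadrants


def run_pipeline(
    wells: pd.DataFrame,
    ly: pd.DataFrame | None,
    abundance: pd.DataFrame,
    kpuu_obs: pd.DataFrame,
    dose_response=None,
    config: PipelineConfig | None = None,
) -> dict:
    """Execute transport -> K_p,uu fit/predict -> classify -> compare.

    Returns a JSON-serializable report with all metrics, the fitted scaling
    factors, QC exclusion log and configuration provenance.  Deterministic
    for a given config seed.
    """
    config = config or PipelineConfig()
    qc = QCSettings(
        ly_papp_limit=config.ly_papp_limit, recovery_limit_pct=config.recovery_limit_pct
    )
    efflux, qc_log = build_efflux_table(wells, ly, qc)
    if not len(efflux):
        raise InsufficientDataError("no efflux records survive QC")

    ab = abundance.set_index("transporter")
    try:
        ref_mdr1 = compute_ref(
            ab.loc["hMDR1", "brain_abundance"], ab.loc["hMDR1", "cell_abundance"]
        )
        ref_bcrp = compute_ref(
            ab.loc["BCRP", "brain_abundance"], ab.loc["BCRP", "cell_abundance"]
        )
    except KeyError as exc:
        raise InvalidInputError(f"abundance table missing transporter: {exc}") from exc

    total = build_total_efflux_table(efflux, ref_mdr1, ref_bcrp)

    # join measured efflux with in vivo observations
    obs = kpuu_obs.merge(
        total[["compound_id", "net_er_mdr1", "net_er_bcrp", "total_er", "total_er_ref"]],
        on="compound_id",
        how="inner",
        suffixes=("_truth", ""),
    )
    if "low_permeability_flag" not in obs.columns:
        obs["low_permeability_flag"] = False

    observations = [
        KpuuObservation(
            compound_id=r.compound_id,
            net_er_mdr1=r.net_er_mdr1,
            net_er_bcrp=r.net_er_bcrp,
            kpuu_invivo=r.kpuu_invivo,
            low_permeability_flag=bool(r.low_permeability_flag),
        )
        for r in obs.itertuples()
    ]
    fit = fit_scaling_factors(
        observations,
        n_starts=config.n_starts,
        start_range=config.start_range,
        log_scale=config.fit_log_scale,
        resid_z_threshold=config.resid_z_threshold,
        kpuu_cap=config.kpuu_cap,
        random_state=config.seed,
    )

    # per-compound predictions under the four models
    obs["kpuu_pred_mdr1_ref"] = predict_kpuu_mdr1_ref(obs["net_er_mdr1"], ref_mdr1)
    obs["kpuu_pred_total"] = predict_kpuu_total(obs["total_er"])
    obs["kpuu_pred_ref"] = predict_kpuu_ref(
        obs["net_er_mdr1"], obs["net_er_bcrp"], ref_mdr1, ref_bcrp
    )
    obs["kpuu_pred_scaled"] = predict_kpuu_scaled(
        obs["net_er_mdr1"], obs["net_er_bcrp"], fit.alpha, fit.beta
    )

    # regression summaries on the compounds the fit retained
    excluded_ids = {e["compound_id"] for e in fit.excluded_ids}
    used = obs[~obs["compound_id"].isin(excluded_ids)]
    regressions = {}
    for model in ("mdr1_ref", "total", "ref", "scaled"):
        summ = evaluate_prediction(
            used[f"kpuu_pred_{model}"], used["kpuu_invivo"], log_scale=True
        )
        regressions[model] = {
            "r_squared": summ.r_squared,
            "slope": summ.slope,
            "intercept": summ.intercept,
            "p_value": summ.p_value,
            "n": summ.n,
        }

    # classification blocks (single lines at cutoff 2; totals at cutoff 3)
    er_wide = efflux.pivot_table(
        index="compound_id", columns="cell_line", values="er_vehicle"
    )
    cls_input = obs.set_index("compound_id")
    classification = {}
    for line in MDR1_LINES:
        if line not in er_wide.columns:
            continue
        joined = cls_input.join(er_wide[line].rename("er"), how="inner").dropna(
            subset=["er"]
        )
        metrics, _ = _classification_block(
            joined["er"], joined["kpuu_invivo"], config.er_cutoff_single, config.kpuu_cutoff
        )
        classification[line] = {"raw": metrics, "rounded": metrics.rounded()}
    for name, col in (("total_er", "total_er"), ("total_er_ref", "total_er_ref")):
        metrics, _ = _classification_block(
            cls_input[col], cls_input["kpuu_invivo"], config.er_cutoff_total, config.kpuu_cutoff
        )
        classification[name] = {"raw": metrics, "rounded": metrics.rounded()}

    # cross-ortholog comparison on the full surviving ER panel
    comparisons = {}
    iqr = {}
    for line in MDR1_LINES:
        if line in er_wide.columns and er_wide[line].dropna().size >= 4:
            iqr[line] = dynamic_range_iqr(er_wide[line].dropna())
    for i, a in enumerate(MDR1_LINES):
        for b in MDR1_LINES[i + 1 :]:
            if a not in er_wide.columns or b not in er_wide.columns:
                continue
            pair = er_wide[[a, b]].dropna()
            if len(pair) >= 3:
                rep = pairwise_correlation(
                    pair[a], pair[b], labels=pair.index, scale=config.comparison_scale
                )
                comparisons[f"{a}_vs_{b}"] = rep.to_dict()

    report = {
        "software": {"name": "bbbflux", "version": __version__},
        "config": config.to_dict(),
        "qc": {"n_exclusions": len(qc_log), "log": qc_log},
        "refs": {"mdr1": ref_mdr1, "bcrp": ref_bcrp},
        "n_efflux_records": int(len(efflux)),
        "scaling_fit": fit.to_dict(),
        "regressions": regressions,
        "classification": {
            k: {"counts_and_metrics": v["rounded"]} for k, v in classification.items()
        },
        "comparisons": comparisons,
        "iqr": iqr,
    }

    if dose_response:
        ic50_rows = []
        for series in dose_response:
            res = fit_ic50(series)
            cell_ab = None
            line_key = series.cell_line if series.cell_line in ab.index else None
            if line_key is not None:
                cell_ab = float(ab.loc[line_key, "cell_abundance"])
                res = correct_ic50(res, cell_ab)
            ic50_rows.append(
                {
                    "inhibitor_id": res.inhibitor_id,
                    "substrate": res.substrate,
                    "cell_line": res.cell_line,
                    "ic50_uM": res.ic50,
                    "censored": res.censored,
                    "hill_slope": res.hill_slope,
                    "corrected_ic50": res.corrected_ic50,
                }
            )
        report["ic50"] = ic50_rows

    report["_tables"] = {
        "efflux": efflux,
        "total_efflux": total,
        "observations": obs,
    }
    return report


def run_simulated_pipeline(
    gen_config: GeneratorConfig,
    pipe_config: PipelineConfig | None = None,
    with_ic50: bool = False,
) -> tuple[dict, SimulatedStudy]:
    """Simulate a study and push it through the full pipeline."""
    study = simulate_study(gen_config)
    pipe_config = pipe_config or PipelineConfig(seed=gen_config.seed)
    report = run_pipeline(
        study.wells,
        study.ly,
        study.abundance,
        study.kpuu_obs[["compound_id", "kpuu_invivo", "low_permeability_flag"]],
        dose_response=study.dose_response if with_ic50 else None,
        config=pipe_config,
    )
    return report, study
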