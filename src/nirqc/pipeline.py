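"""End-to-end model search, external validation, and system comparison.

The workflow mirrors routine multivariate-calibration practice for this
formulation: for each indicator (ANTI-NO, epigoitrin, geniposide, baicalin)
and each acquisition system (traditional tube vs through-vial),

1. hold out ~10% of samples at random as an external validation set;
2. divide the remaining samples 3:1 into calibration/prediction by SPXY
   using that indicator's reference values;
3. scan the five pretreatments (raw, normalization, SNV, SG, MSC), fitting a
   global PLSR with leave-one-out RMSECV-selected LVs on the calibration
   set, and keep the pretreatment with the lowest RMSECV (tie: fewer LVs);
4. run the three variable selectors on the pretreated calibration block and
   keep the selector whose subset gives the lowest leave-one-out RMSECV
   (tie: fewer LVs, then fewer variables);
5. refit the final model on the selected subset and report calibration and
   prediction metrics (Rc/RMSEC/RSEC, Rp/RMSEP/RSEP, RPD, LVs).

Model choice consults calibration-side criteria only; validation samples
never touch pretreatment fitting, SPXY, selection, or LV choice.
All randomness flows from one top-level seed through a spawned
``numpy.random.SeedSequence`` per (indicator, system, stage), so one seed
reproduces the whole report byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluation import MetricsReport, regression_metrics, rpd, wilcoxon_rank_sum
from .io_core import INDICATORS, ReferenceTable, SpectraSet, Split
from .partitioning import random_holdout, spxy_split
from .pls import PLSModel, cv_rmsecv_curve, fit_pls, predict, select_lvs_loocv
from .preprocessing import PRETREATMENTS, PretreatmentSpec, fit_apply_pretreatment
from .selection import VariableSubset, cars_select, random_frog_select, sipls_select

__all__ = [
    "SearchGrid",
    "CandidateResult",
    "IndicatorModel",
    "SearchReport",
    "run_model_search",
    "external_validate",
    "compare_systems",
    "TABLE5_COLUMNS",
]

#: header roles of the optimal-model comparison table
TABLE5_COLUMNS = ("indicator", "system", "P.M.", "V.S.M.", "V.N.", "LVs",
                  "Rc", "RMSEC", "RSEC", "Rp", "RMSEP", "RSEP", "RPD")


@dataclass(frozen=True)
class SearchGrid:
    """Hyperparameter grid for the orchestrated search.

    The selector settings here are the orchestration defaults, sized so a
    full four-indicator search stays interactive; the standalone selector
    functions keep their own (heavier) defaults.
    """

    pretreatments: tuple[str, ...] = PRETREATMENTS
    selectors: tuple[str, ...] = ("sipls", "cars", "random_frog")
    max_lvs: int = 15
    selection_cv: int = 5
    selection_max_lvs: int = 10
    sipls_k: tuple[int, ...] = (18,)
    sipls_m: tuple[int, ...] = (2, 3)
    cars_runs: int = 50
    cars_mc_ratio: float = 0.8
    frog_iter: int = 300
    frog_theta: float = 0.3
    frog_omega: float = 3.0
    frog_eta: float = 0.1
    cal_fraction: float = 0.75
    holdout_fraction: float = 0.10
    sg_window: int = 11
    sg_polyorder: int = 2


@dataclass(frozen=True)
class CandidateResult:
    """One cell of the search grid (a pretreatment or selector candidate)."""

    stage: str  # "pretreatment" | "selector"
    name: str
    rmsecv: float
    n_lvs: int
    n_vars: int
    error: str | None = None


@dataclass(frozen=True)
class IndicatorModel:
    """The chosen model for one indicator under one acquisition system."""

    indicator: str
    system: str
    split: Split
    pretreatment: PretreatmentSpec
    subset: VariableSubset
    model: PLSModel
    rmsecv: float
    calibration: MetricsReport
    prediction: MetricsReport
    candidates: tuple[CandidateResult, ...]


@dataclass(frozen=True)
class SearchReport:
    """Search outcome over all indicators for one acquisition system."""

    system: str
    seed: int
    models: Mapping[str, IndicatorModel]
    failures: Mapping[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Optimal-model table, one row per indicator (Table-5 shape)."""
        rows = []
        for name, m in self.models.items():
            rows.append({
                "indicator": name,
                "system": self.system,
                "P.M.": m.pretreatment.method,
                "V.S.M.": m.subset.method,
                "V.N.": m.subset.n_selected,
                "LVs": m.model.n_lvs,
                "Rc": m.calibration.R,
                "RMSEC": m.calibration.RMSE,
                "RSEC": m.calibration.RSE,
                "Rp": m.prediction.R,
                "RMSEP": m.prediction.RMSE,
                "RSEP": m.prediction.RSE,
                "RPD": m.prediction.RPD,
            })
        return pd.DataFrame(rows, columns=list(TABLE5_COLUMNS))


def _loocv_on_subset(Xc: np.ndarray, y: np.ndarray, indices: Sequence[int],
                     max_lvs: int) -> tuple[float, int]:
    idx = np.asarray(indices, dtype=int)
    curve = cv_rmsecv_curve(Xc[:, idx], y, max_lvs=min(max_lvs, idx.size), cv=Xc.shape[0])
    h = int(np.argmin(curve)) + 1
    return float(curve[h - 1]), h


def _search_one(
    spectra: SpectraSet,
    refs: ReferenceTable,
    indicator: str,
    grid: SearchGrid,
    validation_ids: Sequence[str],
    seed: int,
) -> IndicatorModel:
    model_ids = [s for s in spectra.sample_ids if s not in set(validation_ids)]
    work = spectra.subset_samples(model_ids)
    y_all = refs.subset_samples(model_ids).indicator(indicator)

    # SPXY split on raw spectra (pretreatment is chosen later, on calibration only)
    split = spxy_split(work.absorbance, y_all, model_ids,
                       cal_fraction=grid.cal_fraction, validation_ids=tuple(validation_ids))
    cal = work.subset_samples(split.calibration_ids)
    pred = work.subset_samples(split.prediction_ids)
    y = {sid: v for sid, v in zip(model_ids, y_all)}
    y_cal = np.array([y[s] for s in split.calibration_ids])
    y_pred = np.array([y[s] for s in split.prediction_ids])

    candidates: list[CandidateResult] = []

    # --- stage 1: pretreatment scan (global model, LOO RMSECV) ---------------
    best_pre: tuple[float, int, str, PretreatmentSpec, SpectraSet] | None = None
    for method in grid.pretreatments:
        spec = PretreatmentSpec(method=method, window=grid.sg_window, polyorder=grid.sg_polyorder)
        try:
            cal_t, fitted = fit_apply_pretreatment(cal, spec, fit=True)
            h, curve = select_lvs_loocv(cal_t.absorbance, y_cal, max_lvs=grid.max_lvs)
            rmsecv = float(curve[h - 1])
        except Exception as exc:  # a failing cell must not kill the grid
            candidates.append(CandidateResult("pretreatment", method, math.inf, 0, cal.n_vars, str(exc)))
            continue
        candidates.append(CandidateResult("pretreatment", method, rmsecv, h, cal.n_vars))
        key = (rmsecv, h)
        if best_pre is None or key < (best_pre[0], best_pre[1]):
            best_pre = (rmsecv, h, method, fitted, cal_t)
    if best_pre is None:
        raise RuntimeError(f"all pretreatments failed for {indicator}")
    _, _, pre_method, pre_spec, cal_t = best_pre
    Xc = cal_t.absorbance

    # --- stage 2: selector scan on the chosen pretreatment -------------------
    ss = np.random.SeedSequence([seed, 1])
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    selector_results: list[tuple[float, int, int, VariableSubset]] = []
    for selector in grid.selectors:
        try:
            if selector == "sipls":
                best_sub = None
                for k in grid.sipls_k:
                    for m in grid.sipls_m:
                        sub = sipls_select(Xc, y_cal, k, m, max_lvs=grid.selection_max_lvs,
                                           cv=grid.selection_cv)
                        if best_sub is None or sub.rmsecv < best_sub.rmsecv:
                            best_sub = sub
                sub = best_sub
            elif selector == "cars":
                sub = cars_select(Xc, y_cal, n_runs=grid.cars_runs, mc_ratio=grid.cars_mc_ratio,
                                  cv=grid.selection_cv, max_lvs=grid.selection_max_lvs,
                                  seed=child_seeds[0])
            elif selector == "random_frog":
                sub = random_frog_select(Xc, y_cal, n_iter=grid.frog_iter, theta=grid.frog_theta,
                                         omega=grid.frog_omega, eta=grid.frog_eta,
                                         cv=grid.selection_cv, max_lvs=grid.selection_max_lvs,
                                         seed=child_seeds[1])
            else:
                raise ValueError(f"unknown selector {selector!r}")
            # rank selectors on a common footing: LOO RMSECV of the subset
            loo_rmsecv, h = _loocv_on_subset(Xc, y_cal, sub.indices, grid.max_lvs)
        except Exception as exc:
            candidates.append(CandidateResult("selector", selector, math.inf, 0, 0, str(exc)))
            continue
        candidates.append(CandidateResult("selector", selector, loo_rmsecv, h, sub.n_selected))
        selector_results.append((loo_rmsecv, h, sub.n_selected, sub))
    if not selector_results:
        raise RuntimeError(f"all selectors failed for {indicator}")
    loo_rmsecv, h, _, subset = min(selector_results, key=lambda t: (t[0], t[1], t[2]))

    # --- final refit and metrics ---------------------------------------------
    idx = np.asarray(subset.indices, dtype=int)
    model = fit_pls(Xc[:, idx], y_cal, n_lvs=h, indicator=indicator,
                    variable_indices=subset.indices, pretreatment=pre_method)
    pred_t, _ = fit_apply_pretreatment(pred, pre_spec, fit=False)
    yhat_cal = predict(model, Xc[:, idx])
    yhat_pred = predict(model, pred_t.absorbance[:, idx])

    mc = regression_metrics(y_cal, yhat_cal)
    mp = regression_metrics(y_pred, yhat_pred)
    rp = rpd(y_pred, mp["RMSE"])
    calibration = MetricsReport("calibration", y_cal.size, mc["R"], mc["RMSE"], mc["RSE"],
                                RMSECV=loo_rmsecv, LVs=h)
    prediction = MetricsReport("prediction", y_pred.size, mp["R"], mp["RMSE"], mp["RSE"],
                               RPD=rp["RPD"], LVs=h)
    return IndicatorModel(
        indicator=indicator, system=spectra.mode.value, split=split,
        pretreatment=pre_spec, subset=subset, model=model, rmsecv=loo_rmsecv,
        calibration=calibration, prediction=prediction, candidates=tuple(candidates),
    )


def run_model_search(
    spectra: SpectraSet,
    refs: ReferenceTable,
    grid: SearchGrid | None = None,
    seed: int = 0,
    indicators: Sequence[str] = INDICATORS,
    validation_ids: Sequence[str] | None = None,
) -> SearchReport:
    """Pretreatment x selector search per indicator for one acquisition system.

    ``validation_ids`` may be supplied (e.g. shared across systems); when
    None, a fresh 10% random holdout is drawn from ``seed``.  Failures are
    isolated per indicator and recorded in ``report.failures``.
    """
    grid = grid or SearchGrid()
    if spectra.sample_ids != refs.sample_ids:
        raise ValueError("spectra and references must be joined (same id order) before searching")
    if validation_ids is None:
        validation_ids = random_holdout(spectra.sample_ids, grid.holdout_fraction, seed)
    models: dict[str, IndicatorModel] = {}
    failures: dict[str, str] = {}
    for indicator in indicators:
        try:
            models[indicator] = _search_one(spectra, refs, indicator, grid, validation_ids, seed)
        except Exception as exc:
            failures[indicator] = str(exc)
    return SearchReport(system=spectra.mode.value, seed=seed, models=models, failures=failures)


def external_validate(
    chosen: IndicatorModel,
    spectra: SpectraSet,
    refs: ReferenceTable,
) -> dict[str, object]:
    """Score the chosen model on its external-validation samples.

    Returns the per-sample reference/predicted table plus Rv, RMSEV, RSEV
    and the Wilcoxon rank-sum p comparing the two columns.  A validation
    range outside the calibration range is reported via ``range_warning``
    (predictions are still emitted — extrapolation is the realistic case).
    """
    val_ids = chosen.split.validation_ids
    if not val_ids:
        raise ValueError("chosen model has no external-validation samples")
    overlap = set(val_ids) & set(chosen.split.calibration_ids + chosen.split.prediction_ids)
    if overlap:
        raise ValueError(f"validation ids overlap training ids: {sorted(overlap)}")
    val = spectra.subset_samples(val_ids)
    y_val = refs.subset_samples(val_ids).indicator(chosen.indicator)
    val_t, _ = fit_apply_pretreatment(val, chosen.pretreatment, fit=False)
    idx = np.asarray(chosen.subset.indices, dtype=int)
    y_hat = predict(chosen.model, val_t.absorbance[:, idx])

    m = regression_metrics(y_val, y_hat)
    _, p = wilcoxon_rank_sum(y_val, y_hat)
    y_cal = refs.subset_samples(chosen.split.calibration_ids).indicator(chosen.indicator)
    out_of_range = bool(y_val.min() < y_cal.min() or y_val.max() > y_cal.max())
    table = pd.DataFrame({
        "sample_id": list(val_ids),
        "reference": y_val,
        "predicted": y_hat,
    })
    return {
        "indicator": chosen.indicator,
        "system": chosen.system,
        "table": table,
        "Rv": m["R"],
        "RMSEV": m["RMSE"],
        "RSEV": m["RSE"],
        "wilcoxon_p": p,
        "n": len(val_ids),
        "range_warning": out_of_range,
    }


def compare_systems(report_a: SearchReport, report_b: SearchReport) -> pd.DataFrame:
    """Side-by-side optimal-model rows for two systems plus per-indicator deltas.

    Deltas are b minus a for R-type columns and RPD, and are antisymmetric
    under argument swap.
    """
    if set(report_a.models) != set(report_b.models):
        raise ValueError("reports cover different indicator sets")
    fa = report_a.to_frame().set_index("indicator")
    fb = report_b.to_frame().set_index("indicator")
    rows = []
    for ind in fa.index:
        a, b = fa.loc[ind], fb.loc[ind]
        row = {"indicator": ind}
        for col in TABLE5_COLUMNS[1:]:
            row[f"{col} ({report_a.system})"] = a[col]
            row[f"{col} ({report_b.system})"] = b[col]
        row["dRc"] = b["Rc"] - a["Rc"]
        row["dRp"] = b["Rp"] - a["Rp"]
        row["dRMSEC"] = b["RMSEC"] - a["RMSEC"]
        row["dRMSEP"] = b["RMSEP"] - a["RMSEP"]
        row["dRPD"] = b["RPD"] - a["RPD"]
        rows.append(row)
    return pd.DataFrame(rows)
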