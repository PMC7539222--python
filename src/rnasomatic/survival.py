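"""Outcome analysis: subgroup construction, Kaplan-Meier/log-rank,
uni-/multivariable Cox with proportional-hazards checking, and the
mutation-or-low-expression genotype.

All gene/pathway/TMB stratifications route through the same km_logrank and
cox_fit contracts.  Cox uses Efron tie handling; "lower quartile" uses the
linear-interpolation (type-7) quantile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, proportional_hazard_test

from .io_core import ClinicalRecord

__all__ = [
    "SurvivalResult",
    "define_subgroups",
    "km_logrank",
    "cox_fit",
    "pten_mutexp",
]

TREATMENT_GROUPS = ("none", "endo_only", "endo_chemo_any", "her2_any")
BIOMARKER_GROUPS = ("hor_pos_her2_neg", "hor_pos_her2_pos", "hor_neg_her2_pos", "tnbc")


@dataclass
class SurvivalResult:
    groups: dict  # label -> n
    logrank_p: Optional[float]
    hr: float
    ci95: tuple
    cox_p: float
    mv_hr: Optional[float] = None
    mv_ci: Optional[tuple] = None
    mv_p: Optional[float] = None
    ph_ok: Optional[bool] = None


def define_subgroups(records: Sequence[ClinicalRecord]) -> dict:
    """Treatment and biomarker subgroups as name -> set of sample ids.

    Treatment: none (no rx flags), endo_only, endo_chemo_any (endocrine and
    chemo, any HER2), her2_any (HER2 treatment with anything else or nothing).
    Biomarker: hormone-receptor positive means ER+ and PgR+; TNBC means
    ER-, PgR-, HER2-.  Samples with missing determinants are excluded from
    the affected biomarker groups.
    """
    groups = {name: set() for name in (*TREATMENT_GROUPS, *BIOMARKER_GROUPS)}
    for r in records:
        if r.rx_her2:
            groups["her2_any"].add(r.sample_id)
        elif r.rx_endocrine and r.rx_chemo:
            groups["endo_chemo_any"].add(r.sample_id)
        elif r.rx_endocrine and not r.rx_chemo:
            groups["endo_only"].add(r.sample_id)
        elif not (r.rx_endocrine or r.rx_chemo or r.rx_her2):
            groups["none"].add(r.sample_id)
        statuses = (r.er_status, r.pgr_status, r.her2_status)
        if "missing" in statuses:
            continue
        hor_pos = r.er_status == "pos" and r.pgr_status == "pos"
        her2_pos = r.her2_status == "pos"
        if hor_pos and not her2_pos:
            groups["hor_pos_her2_neg"].add(r.sample_id)
        elif hor_pos and her2_pos:
            groups["hor_pos_her2_pos"].add(r.sample_id)
        elif not hor_pos and her2_pos:
            groups["hor_neg_her2_pos"].add(r.sample_id)
        if r.er_status == "neg" and r.pgr_status == "neg" and not her2_pos:
            groups["tnbc"].add(r.sample_id)
    return groups


def km_logrank(
    times: Sequence[float],
    events: Sequence[bool],
    labels: Sequence,
):
    """Product-limit curves per group plus the two-sided log-rank p.

    Returns (curves, p) where curves maps label -> KaplanMeierFitter.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    labels = np.asarray(labels)
    uniques = pd.unique(labels)
    if len(uniques) < 2:
        raise ValueError("km_logrank needs >= 2 groups")
    curves = {}
    for g in uniques:
        mask = labels == g
        if mask.sum() == 0:
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=str(g))
        curves[g] = kmf
    if events.sum() == 0:
        raise ValueError("log-rank undefined with zero events")
    res = multivariate_logrank_test(times, labels, events)
    return curves, float(res.p_value)


def _rank_check(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(mat)), mat])) < X.shape[1] + 1:
        raise ValueError(
            f"design matrix is rank deficient (collinear columns among {list(X.columns)})"
        )


def cox_fit(
    times: Sequence[float],
    events: Sequence[bool],
    exposure: Sequence,
    covariables: Optional[pd.DataFrame] = None,
    alpha_ph: float = 0.05,
) -> SurvivalResult:
    """Cox proportional-hazards fit of a binary exposure, optionally adjusted.

    Reports the univariable HR/CI/Wald p for exposure, the multivariable
    equivalents when covariables are supplied, and a proportional-hazards
    flag from the score test on scaled Schoenfeld residuals.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    exposure = np.asarray(exposure, dtype=float)
    if np.all(exposure == exposure[0]):
        raise ValueError("exposure is constant; hazard ratio undefined")

    def _fit(df: pd.DataFrame) -> CoxPHFitter:
        _rank_check(df.drop(columns=["time", "event"]))
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        return cph

    uni_df = pd.DataFrame({"time": times, "event": events, "exposure": exposure})
    uni = _fit(uni_df)
    hr = float(np.exp(uni.params_["exposure"]))
    ci = uni.confidence_intervals_.loc["exposure"]
    ci95 = (float(np.exp(ci.iloc[0])), float(np.exp(ci.iloc[1])))
    cox_p = float(uni.summary.loc["exposure", "p"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ph = proportional_hazard_test(uni, uni_df, time_transform="rank")
    ph_ok = bool(ph.summary["p"].min() > alpha_ph)

    n_exposed = int((exposure != 0).sum())
    result = SurvivalResult(
        groups={"reference": len(exposure) - n_exposed, "exposed": n_exposed},
        logrank_p=None,
        hr=hr,
        ci95=ci95,
        cox_p=cox_p,
        ph_ok=ph_ok,
    )
    if len(np.unique(exposure)) == 2:
        _, result.logrank_p = km_logrank(times, events, exposure)

    if covariables is not None and len(covariables.columns) > 0:
        mv_df = pd.DataFrame({"time": times, "event": events, "exposure": exposure})
        for col in covariables.columns:
            mv_df[col] = np.asarray(covariables[col], dtype=float)
        mv = _fit(mv_df)
        result.mv_hr = float(np.exp(mv.params_["exposure"]))
        mci = mv.confidence_intervals_.loc["exposure"]
        result.mv_ci = (float(np.exp(mci.iloc[0])), float(np.exp(mci.iloc[1])))
        result.mv_p = float(mv.summary.loc["exposure", "p"])
    return result


def covariable_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    """Standard adjustment set: age, node status, tumor size, plus ER/PgR/HER2
    binaries and NHG dummies with G1 reference.  Rows with missing core
    covariables are dropped (index = sample ids)."""
    rows = {}
    for r in records:
        if r.tumor_size_mm is None or r.n_positive_nodes is None:
            continue
        if "missing" in (r.er_status, r.pgr_status, r.her2_status) or r.nhg == "missing":
            continue
        rows[r.sample_id] = {
            "age": r.age_years,
            "nodes_positive": 1.0 if r.n_positive_nodes > 0 else 0.0,
            "size_mm": r.tumor_size_mm,
            "er": 1.0 if r.er_status == "pos" else 0.0,
            "pgr": 1.0 if r.pgr_status == "pos" else 0.0,
            "her2": 1.0 if r.her2_status == "pos" else 0.0,
            "nhg_G2": 1.0 if r.nhg == "G2" else 0.0,
            "nhg_G3": 1.0 if r.nhg == "G3" else 0.0,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def pten_mutexp(
    mut_status: Mapping[str, bool],
    expression: Mapping[str, float],
    quantile: float = 0.25,
) -> dict:
    """Mutation-or-low-expression genotype: "low" iff mutated or expression at
    or below the cohort lower-quartile (type-7 quantile), else "normal".

    Samples with neither a mutation call nor an expression value are excluded
    with a warning.
    """
    values = np.asarray([expression[s] for s in sorted(expression)], dtype=float)
    if values.size == 0:
        raise ValueError("no expression values supplied")
    cutoff = float(np.quantile(values, quantile))  # numpy default = type 7
    out = {}
    for sample in sorted(set(mut_status) | set(expression)):
        mutated = mut_status.get(sample)
        expr = expression.get(sample)
        if expr is None and mutated is None:
            warnings.warn(f"sample {sample}: no mutation call and no expression; excluded")
            continue
        if mutated or (expr is not None and expr <= cutoff):
            out[sample] = "low"
        else:
            out[sample] = "normal"
    return out
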