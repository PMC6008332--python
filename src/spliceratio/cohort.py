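"""Cohort-level association of splicing events.

Given a tumor cohort with per-sample ASE occurrence (0/1), a binary group
label (e.g. copy-number loss of a tumor suppressor), survival time and
censoring flag, this stage

* keeps ASEs occurring in more than ``min_frequency`` of samples
  ("cancer-related" at the default 5%),
* tests occurrence-group association with a two-sided Fisher's exact test,
* tests occurrence-survival association with the log-rank test and a
  hazard ratio from a single-binary-covariate Cox model (Newton iteration
  on the Breslow partial likelihood),
* intersects the resulting sets Venn-style.

Group labels are generic binary covariates; raw p-values are reported
alongside a Benjamini-Hochberg column, with selection defaulting to raw
p < 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "SurvivalResult",
    "ase_frequency_filter",
    "fisher_association",
    "cox_hr_binary",
    "survival_association",
    "intersect_sets",
    "cohort_association_table",
]

_META_COLS = ("sample_id", "group", "time", "event")


def _ase_columns(cohort: pd.DataFrame) -> list[str]:
    return [c for c in cohort.columns if c not in _META_COLS]


def ase_frequency_filter(cohort: pd.DataFrame, min_frequency: float = 0.05) -> list[str]:
    """ASE ids whose occurrence frequency strictly exceeds ``min_frequency``."""
    if cohort.empty:
        raise ValueError("empty cohort")
    n = len(cohort)
    return [c for c in _ase_columns(cohort) if cohort[c].sum() / n > min_frequency]


@dataclass(frozen=True, slots=True)
class AssociationResult:
    """Fisher's exact association of one ASE with the binary group."""

    ase_id: str
    table: tuple[tuple[int, int], tuple[int, int]]  # rows: group 1/0; cols: occ 1/0
    fisher_p: float
    frequency: float
    frequency_group1: float
    frequency_group0: float


def fisher_association(
    occurrence: Sequence[int], group: Sequence[int], ase_id: str = ""
) -> AssociationResult:
    """Two-sided Fisher's exact test of an occurrence column against a
    binary group (probabilities of all fixed-margin tables at most as
    likely as the observed one are summed).  A zero margin yields p = 1
    with a warning."""
    occ = np.asarray(occurrence, dtype=int)
    grp = np.asarray(group, dtype=int)
    a = int(np.sum((grp == 1) & (occ == 1)))
    b = int(np.sum((grp == 1) & (occ == 0)))
    c = int(np.sum((grp == 0) & (occ == 1)))
    d = int(np.sum((grp == 0) & (occ == 0)))
    table = ((a, b), (c, d))
    if min(a + b, c + d, a + c, b + d) == 0:
        warnings.warn(f"zero margin for {ase_id or 'ASE'}; Fisher p = 1", stacklevel=2)
        p = 1.0
    else:
        p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    n = occ.size
    n1 = a + b
    n0 = c + d
    return AssociationResult(
        ase_id=ase_id,
        table=table,
        fisher_p=p,
        frequency=occ.sum() / n,
        frequency_group1=a / n1 if n1 else math.nan,
        frequency_group0=c / n0 if n0 else math.nan,
    )


def cox_hr_binary(
    time: Sequence[float],
    event_flag: Sequence[int],
    covariate: Sequence[int],
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[float, float, float]:
    """Hazard ratio of a single binary covariate by Newton iteration on the
    Cox partial likelihood with Breslow tie handling.

    Returns ``(hr, ci_low, ci_high)`` with a Wald 95% interval.  When the
    likelihood is monotone (e.g. one group has no events) the estimate is
    unbounded and ``inf``/0 is returned with infinite interval.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event_flag, dtype=int)
    x = np.asarray(covariate, dtype=float)
    if not set(np.unique(x)) <= {0.0, 1.0}:
        raise ValueError("covariate must be binary 0/1")
    order = np.argsort(t, kind="mergesort")
    t, e, x = t[order], e[order], x[order]
    event_times = np.unique(t[e == 1])
    # Breslow: per distinct event time, deaths d_k, death covariate sum s_k,
    # and risk set (all with t_i >= t_k)
    d_k = np.array([np.sum((t == tk) & (e == 1)) for tk in event_times], dtype=float)
    s_k = np.array(
        [np.sum(x[(t == tk) & (e == 1)]) for tk in event_times], dtype=float
    )
    n1_k = np.array([np.sum(x[t >= tk]) for tk in event_times], dtype=float)
    n_k = np.array([np.sum(t >= tk) for tk in event_times], dtype=float)
    n0_k = n_k - n1_k

    beta = 0.0
    for _ in range(max_iter):
        w1 = n1_k * math.exp(beta)
        denom = w1 + n0_k
        mu = w1 / denom  # E[x | risk set] under current beta
        grad = float(np.sum(s_k - d_k * mu))
        hess = float(-np.sum(d_k * mu * (1.0 - mu)))
        if hess > -1e-300:
            break
        step = -grad / hess
        beta += step
        if abs(beta) > 15:  # monotone likelihood: estimate unbounded
            hr = math.inf if beta > 0 else 0.0
            return hr, 0.0, math.inf
        if abs(step) < tol:
            break
    w1 = n1_k * math.exp(beta)
    denom = w1 + n0_k
    mu = w1 / denom
    info = float(np.sum(d_k * mu * (1.0 - mu)))
    if info <= 0:
        return math.exp(beta), 0.0, math.inf
    se = 1.0 / math.sqrt(info)
    return math.exp(beta), math.exp(beta - 1.96 * se), math.exp(beta + 1.96 * se)


@dataclass(frozen=True, slots=True)
class SurvivalResult:
    """Survival association of one ASE: log-rank test and Cox hazard ratio."""

    ase_id: str
    logrank_p: float
    logrank_statistic: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    direction: str  # unfavorable iff HR > 1 for occurrence = 1


def survival_association(
    occurrence: Sequence[int],
    time: Sequence[float],
    event_flag: Sequence[int],
    ase_id: str = "",
) -> SurvivalResult:
    """Log-rank test and hazard ratio of ASE occurrence on overall survival."""
    occ = np.asarray(occurrence, dtype=int)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event_flag, dtype=int)
    if min(np.sum(occ == 1), np.sum(occ == 0)) < 2:
        raise ValueError(f"{ase_id or 'ASE'}: need >= 2 samples per group")
    lr = logrank_test(t[occ == 1], t[occ == 0], e[occ == 1], e[occ == 0])
    if min(np.sum(e[occ == 1]), np.sum(e[occ == 0])) == 0:
        hr, lo, hi = (math.inf if np.sum(e[occ == 1]) else 0.0), 0.0, math.inf
    else:
        hr, lo, hi = cox_hr_binary(t, e, occ)
    return SurvivalResult(
        ase_id=ase_id,
        logrank_p=float(lr.p_value),
        logrank_statistic=float(lr.test_statistic),
        hazard_ratio=hr,
        ci_low=lo,
        ci_high=hi,
        direction="unfavorable" if hr > 1 else "favorable",
    )


def intersect_sets(sets: Mapping[str, set]) -> dict[str, dict]:
    """All Venn regions of 2 or 3 labelled sets.

    Returns a mapping from region label (e.g. ``"A&B"``, exclusive region)
    to ``{"members": sorted ids, "count": n}``, plus the all-sets ``"core"``
    (the inclusive intersection of every set, the headline region).
    """
    labels = list(sets)
    if not 2 <= len(labels) <= 3:
        raise ValueError("intersect_sets takes 2 or 3 labelled sets")
    regions: dict[str, dict] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(sets[l] for l in combo))
            outside = set.union(
                *(sets[l] for l in labels if l not in combo), set()
            ) if len(combo) < len(labels) else set()
            members = sorted(inside - outside)
            regions["&".join(combo)] = {"members": members, "count": len(members)}
    core = sorted(set.intersection(*(sets[l] for l in labels)))
    regions["core"] = {"members": core, "count": len(core)}
    return regions


def cohort_association_table(
    cohort: pd.DataFrame,
    min_frequency: float = 0.05,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One row per ASE: frequency filter, Fisher association, survival
    association, BH-adjusted p's and the three selection flags.

    ASEs failing the frequency filter or with a degenerate occurrence split
    carry NaN test results and False flags.
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    ase_ids = _ase_columns(cohort)
    frequent = set(ase_frequency_filter(cohort, min_frequency))
    rows = []
    for ase in ase_ids:
        occ = cohort[ase].to_numpy()
        row: dict = {
            "ase_id": ase,
            "frequency": float(occ.mean()),
            "cancer_related": ase in frequent,
            "fisher_p": math.nan,
            "hazard_ratio": math.nan,
            "hr_ci_low": math.nan,
            "hr_ci_high": math.nan,
            "logrank_p": math.nan,
        }
        if ase in frequent and 0 < occ.sum() < len(occ):
            assoc = fisher_association(occ, cohort["group"].to_numpy(), ase)
            row["fisher_p"] = assoc.fisher_p
            if min(occ.sum(), len(occ) - occ.sum()) >= 2:
                surv = survival_association(
                    occ, cohort["time"].to_numpy(), cohort["event"].to_numpy(), ase
                )
                row.update(
                    hazard_ratio=surv.hazard_ratio,
                    hr_ci_low=surv.ci_low,
                    hr_ci_high=surv.ci_high,
                    logrank_p=surv.logrank_p,
                )
        rows.append(row)
    out = pd.DataFrame(rows)
    for col, adj in (("fisher_p", "fisher_p_bh"), ("logrank_p", "logrank_p_bh")):
        adjusted = np.full(len(out), math.nan)
        mask = out[col].notna().to_numpy()
        if mask.any():
            adjusted[mask] = multipletests(out[col][mask], method="fdr_bh")[1]
        out[adj] = adjusted
    out["group_associated"] = out["cancer_related"] & (out["fisher_p"] < alpha)
    out["survival_associated"] = out["cancer_related"] & (out["logrank_p"] < alpha)
    return out.sort_values("ase_id", kind="mergesort").reset_index(drop=True)
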