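"""Dose-response and group-comparison statistics for treatment cohorts.

The hematologic endpoint is the *relative platelet nadir*: the lowest
platelet count in the window after a treatment fraction divided by the
pretreatment baseline.  Dose-response is assessed by Spearman rank
correlation of absorbed dose (fraction-1 dose after the first fraction,
cumulative dose after the second) against that ratio, so a toxic dose
effect appears as a negative r_s.  Group contrasts (doses with vs. without
skeletal metastases; male vs. female lumbar concentrations) use the
Wilcoxon rank-sum test.

Small samples get exact permutation p values (full enumeration); larger
samples use the standard t- or normal approximations with mid-rank tie
handling.  No multiple-testing adjustment is applied; each test is reported
with its raw p value and a fixed 0.05 significance threshold.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dosimetry import DoseResult

__all__ = [
    "ALPHA",
    "CohortRecord",
    "DoseResponseResult",
    "relative_platelet_nadir",
    "spearman_correlation",
    "wilcoxon_rank_sum",
    "dose_response_analysis",
    "dose_response_grid",
    "group_comparisons",
]

#: Significance threshold for all reported tests.
ALPHA = 0.05

#: Largest n for which the Spearman p value is an exact permutation p.
SPEARMAN_EXACT_MAX_N = 9

#: Largest pooled sample for which the rank-sum p is an exact enumeration p.
RANKSUM_EXACT_MAX_N = 12

GROUPS = ("all", "with_mets", "without_mets")

_EPS = 1e-12


@dataclass
class CohortRecord:
    """Per-patient clinical data joined with per-fraction dose results."""

    patient_id: str
    sex: str  # "female" | "male"
    skeletal_metastases: bool
    baseline_platelets: float  # 1e9/L
    nadir_platelets: dict[int, float]  # fraction -> 1e9/L
    doses: dict[tuple[str, int], DoseResult]  # (method, fraction) -> result
    l1_l4_mean_concentration: float | None = None  # kBq/mL

    def __post_init__(self) -> None:
        if self.baseline_platelets <= 0:
            raise ValueError("baseline platelets must be > 0")
        if any(v <= 0 for v in self.nadir_platelets.values()):
            raise ValueError("nadir platelets must be > 0")


@dataclass
class DoseResponseResult:
    """Spearman dose-response summary for one method/fraction/group cell."""

    method: str
    fraction: int
    group: str
    n: int
    r_s: float
    p_value: float
    significant: bool

    def __post_init__(self) -> None:
        if not math.isnan(self.r_s) and abs(self.r_s) > 1 + 1e-12:
            raise ValueError("|r_s| must be <= 1")


def relative_platelet_nadir(baseline: float, nadir: float) -> float:
    """Nadir-to-baseline platelet ratio (1.0 means no response)."""
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    if nadir < 0:
        raise ValueError("nadir must be >= 0")
    return nadir / baseline


def _ranks(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p value.

    r_s is the Pearson correlation of mid-ranks.  For n <= 9 the p value is
    exact: every permutation of the y-ranks is enumerated and the fraction
    with |r| >= |r_observed| reported.  For larger n the usual
    t-approximation ``t = r sqrt((n-2)/(1-r^2))`` is used.
    """
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if x_arr.shape != y_arr.shape or x_arr.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    n = x_arr.size
    if n < 3:
        raise ValueError("need n >= 3")
    rx = _ranks(x_arr)
    ry = _ranks(y_arr)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    sx = np.sqrt(np.sum(rx_c**2))
    sy = np.sqrt(np.sum(ry_c**2))
    if sx == 0 or sy == 0:
        raise ValueError("zero rank variance")
    r = float(np.dot(rx_c, ry_c) / (sx * sy))

    if n <= SPEARMAN_EXACT_MAX_N:
        perms = np.array(list(itertools.permutations(ry_c)))
        r_all = perms @ rx_c / (sx * sy)
        p = float(np.mean(np.abs(r_all) >= abs(r) - _EPS))
    else:
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, p


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Wilcoxon rank-sum test; statistic is the rank sum of group ``a``.

    For pooled samples of at most 12 the two-sided p value is exact,
    counting group assignments whose rank sum deviates from its expectation
    at least as much as the observed one.  Larger samples use the normal
    approximation with mid-rank tie correction.
    """
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    if a_arr.size == 0 or b_arr.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a_arr.size, b_arr.size
    n = n_a + n_b
    pooled = np.concatenate([a_arr, b_arr])
    ranks = _ranks(pooled)
    w = float(ranks[:n_a].sum())
    mean_w = n_a * ranks.mean()

    if n <= RANKSUM_EXACT_MAX_N:
        dev = abs(w - mean_w)
        count = 0
        total = 0
        for idx in itertools.combinations(range(n), n_a):
            total += 1
            if abs(ranks[list(idx)].sum() - mean_w) >= dev - _EPS:
                count += 1
        p = count / total
    else:
        # normal approximation with tie correction
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
        var_w = n_a * n_b / 12.0 * (n + 1 - tie_term)
        if var_w <= 0:
            p = 1.0
        else:
            z = (w - mean_w) / math.sqrt(var_w)
            p = float(2.0 * stats.norm.sf(abs(z)))
    return w, min(p, 1.0)


def _group_filter(cohort: list[CohortRecord], group: str) -> list[CohortRecord]:
    if group == "all":
        return list(cohort)
    if group == "with_mets":
        return [r for r in cohort if r.skeletal_metastases]
    if group == "without_mets":
        return [r for r in cohort if not r.skeletal_metastases]
    raise ValueError(f"unknown group {group!r}")


def _dose_for_correlation(record: CohortRecord, method: str, fraction: int) -> float | None:
    """Fraction-1 dose, or the cumulative dose for later fractions."""
    result = record.doses.get((method, fraction))
    if result is None:
        return None
    if fraction == 1:
        return result.dose_gy
    return result.cumulative_gy


def dose_response_analysis(
    cohort: list[CohortRecord],
    method: str,
    fraction: int,
    group: str = "all",
) -> DoseResponseResult:
    """Spearman correlation of absorbed dose vs. relative platelet nadir.

    Pairs each patient's dose (fraction-1 dose, or cumulative dose for
    fraction 2 and beyond) with the relative platelet nadir of that
    fraction's window.  Groups with fewer than 3 complete pairs return a
    flagged result with ``r_s = nan`` that never counts as significant.
    """
    records = _group_filter(cohort, group)
    doses: list[float] = []
    responses: list[float] = []
    for rec in records:
        d = _dose_for_correlation(rec, method, fraction)
        nadir = rec.nadir_platelets.get(fraction)
        if d is None or nadir is None:
            continue
        doses.append(d)
        responses.append(relative_platelet_nadir(rec.baseline_platelets, nadir))
    n = len(doses)
    if n < 3:
        return DoseResponseResult(
            method=method,
            fraction=fraction,
            group=group,
            n=n,
            r_s=float("nan"),
            p_value=float("nan"),
            significant=False,
        )
    r, p = spearman_correlation(doses, responses)
    return DoseResponseResult(
        method=method,
        fraction=fraction,
        group=group,
        n=n,
        r_s=r,
        p_value=p,
        significant=bool(p < ALPHA),
    )


def dose_response_grid(
    cohort: list[CohortRecord],
    methods: tuple[str, ...] = ("planar", "L4_SPECT", "V_SPECT", "L_SPECT", "T_SPECT"),
    fractions: tuple[int, ...] = (1, 2),
    groups: tuple[str, ...] = GROUPS,
) -> pd.DataFrame:
    """Full method x fraction x group grid of dose-response results."""
    rows = []
    for method in methods:
        for fraction in fractions:
            for group in groups:
                res = dose_response_analysis(cohort, method, fraction, group)
                rows.append(
                    {
                        "method": res.method,
                        "fraction": res.fraction,
                        "group": res.group,
                        "n": res.n,
                        "r_s": res.r_s,
                        "p_value": res.p_value,
                        "significant": res.significant,
                    }
                )
    return pd.DataFrame(rows)


def group_comparisons(
    cohort: list[CohortRecord],
    methods: tuple[str, ...] = ("planar", "L4_SPECT", "V_SPECT", "L_SPECT", "T_SPECT"),
    fraction: int = 1,
) -> pd.DataFrame:
    """Wilcoxon rank-sum contrasts reported alongside the correlations.

    Per method: absorbed dose in patients with vs. without skeletal
    metastases.  Additionally: mean L1-L4 vertebral concentration in men
    vs. women (where recorded).
    """
    rows = []
    for method in methods:
        with_m = [
            r.doses[(method, fraction)].dose_gy
            for r in cohort
            if r.skeletal_metastases and (method, fraction) in r.doses
        ]
        without_m = [
            r.doses[(method, fraction)].dose_gy
            for r in cohort
            if not r.skeletal_metastases and (method, fraction) in r.doses
        ]
        if with_m and without_m:
            w, p = wilcoxon_rank_sum(with_m, without_m)
            rows.append(
                {
                    "comparison": f"dose_{method}_mets_vs_no_mets",
                    "n_a": len(with_m),
                    "n_b": len(without_m),
                    "mean_a": float(np.mean(with_m)),
                    "mean_b": float(np.mean(without_m)),
                    "statistic": w,
                    "p_value": p,
                    "significant": p < ALPHA,
                }
            )
    male = [
        r.l1_l4_mean_concentration
        for r in cohort
        if r.sex == "male" and r.l1_l4_mean_concentration is not None
    ]
    female = [
        r.l1_l4_mean_concentration
        for r in cohort
        if r.sex == "female" and r.l1_l4_mean_concentration is not None
    ]
    if male and female:
        w, p = wilcoxon_rank_sum(male, female)
        rows.append(
            {
                "comparison": "l1_l4_concentration_male_vs_female",
                "n_a": len(male),
                "n_b": len(female),
                "mean_a": float(np.mean(male)),
                "mean_b": float(np.mean(female)),
                "statistic": w,
                "p_value": p,
                "significant": p < ALPHA,
            }
        )
    return pd.DataFrame(rows)
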