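"""Descriptive tables, rank-sum comparisons, and small-count suppression.

The two-group comparison is the two-sample Wilcoxon rank-sum (Mann-Whitney)
test: an exact conditional enumeration for small samples, a normal
approximation with tie and continuity corrections otherwise. Displayed counts
below five are replaced by ``"<5"`` (a governance rule protecting anonymity);
percentages are computed before suppression.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

#: largest pooled sample for which the exact conditional null is enumerated
EXACT_MAX_POOLED = 14

SUPPRESSION_THRESHOLD = 5
SUPPRESSION_TOKEN = "<5"


def percentage(numerator: int, denominator: int) -> int:
    """Integer percent, rounded half-up (the convention of printed tables).

    Exact integer arithmetic, so 82.5 rounds to 83 and floating-point noise
    cannot push a .5 boundary the wrong way.
    """
    if denominator == 0:
        raise ValueError("percentage: denominator must be positive")
    numerator, denominator = int(numerator), int(denominator)
    return (200 * numerator + denominator) // (2 * denominator)


def describe(values: Iterable[float]) -> dict:
    """n, mean, sample SD (n-1 denominator; 0 when n=1), median, min, max."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("describe: empty sample")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return {
        "n": int(arr.size),
        "mean": float(arr.mean()),
        "sd": sd,
        "median": float(np.median(arr)),
        "min": float(arr.min()),
        "max": float(arr.max()),
    }


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of sample a over b (ties count one half)."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def _exact_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by enumerating all C(n, n_a) group assignments of the
    pooled values (conditions on the observed values, so ties are handled).

    Two-sided convention: twice the smaller tail, capped at 1.
    """
    pooled = np.concatenate([a, b])
    n, n_a = pooled.size, a.size
    total = comb(n, n_a)
    le = ge = 0
    idx = np.arange(n)
    for picks in combinations(idx, n_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(picks)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        if u <= u_obs:
            le += 1
        if u >= u_obs:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def rank_sum_test(values_a: Sequence[float], values_b: Sequence[float]
                  ) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum; returns (U of sample A, p value).

    Pooled size <= 14: exact enumeration of the conditional permutation null.
    Larger: normal approximation with continuity and tie corrections.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank_sum_test: both samples must be non-empty")
    u_obs = _u_statistic(a, b)
    if a.size + b.size <= EXACT_MAX_POOLED:
        return u_obs, _exact_p(a, b, u_obs)
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return u_obs, float(res.pvalue)


def format_p(p: float | None) -> str:
    """Printed p value, floored at <0.0001."""
    if p is None or (isinstance(p, float) and np.isnan(p)):
        return "NA"
    if p < 1e-4:
        return "<0.0001"
    return f"{p:.4g}"


def suppress_count(n: int, threshold: int = SUPPRESSION_THRESHOLD) -> str:
    """Counts 1..threshold-1 are masked; 0 and >= threshold print as-is."""
    n = int(n)
    if 0 < n < threshold:
        return SUPPRESSION_TOKEN
    return str(n)


def _fmt_count_pct(n: int, denominator: int | None = None) -> str:
    """``"123 (45%)"`` with suppression; a suppressed count hides its percent
    too (otherwise the percent would reveal the masked number)."""
    shown = suppress_count(n)
    if shown == SUPPRESSION_TOKEN or denominator in (None, 0):
        return shown
    return f"{shown} ({percentage(n, denominator)}%)"


def render_table_one(cohort: pd.DataFrame, observations: pd.DataFrame,
                     episodes: pd.DataFrame) -> pd.DataFrame:
    """Characteristics-of-patients table: one column per diagnosis group,
    suppression applied to every displayed count."""
    baseline = observations[observations["period_index"] == 1][
        ["patient_id", "status"]
    ].rename(columns={"status": "baseline_status"})
    coh = cohort.merge(baseline, on="patient_id", how="left")
    coh = coh.merge(
        episodes[["patient_id", "timing"]], on="patient_id", how="left"
    )
    obs = observations.merge(
        cohort[["patient_id", "diagnosis_group"]], on="patient_id"
    )

    groups = [g for g in ("UC", "CD", "IBD_undefined")
              if g in set(coh["diagnosis_group"])]
    table: dict[str, dict[str, str]] = {}
    for g in groups:
        sub = coh[coh["diagnosis_group"] == g]
        n = len(sub)
        col: dict[str, str] = {"Patients (n)": suppress_count(n)}
        for sex, label in (("M", "Sex: male"), ("F", "Sex: female")):
            col[label] = _fmt_count_pct(int((sub["sex"] == sex).sum()), n)
        for band in ("18-59", "60+"):
            col[f"Age {band} years"] = _fmt_count_pct(
                int((sub["age_band"] == band).sum()), n
            )
        for status in ("active", "remission"):
            in_status = sub[sub["baseline_status"] == status]
            col[f"Baseline {status}"] = _fmt_count_pct(len(in_status), n)
            for band in ("18-59", "60+"):
                col[f"Baseline {status}, {band} years"] = _fmt_count_pct(
                    int((in_status["age_band"] == band).sum()),
                    len(in_status) or None,
                )
        treated = sub[sub["timing"].notna()]
        col["Biologic treatment: yes"] = _fmt_count_pct(len(treated), n)
        for timing in ("early", "late"):
            col[f"Biologic treatment: {timing}"] = suppress_count(
                int((treated["timing"] == timing).sum())
            )
        col["Biologic treatment: no"] = _fmt_count_pct(n - len(treated), n)

        gobs = obs[obs["diagnosis_group"] == g]
        col["Total observations"] = suppress_count(len(gobs))
        col["Observations classified as remission"] = _fmt_count_pct(
            int((gobs["status"] == "remission").sum()), len(gobs) or None
        )
        table[g] = col

    out = pd.DataFrame(table)
    out.index.name = "characteristic"
    return out


def compare_groups(values_a: Sequence[float], values_b: Sequence[float],
                   labels: Tuple[str, str] = ("active", "remission"),
                   alpha: float = 0.05) -> dict:
    """One comparison row: descriptives per group, U, p, significance flag.

    Either group smaller than two → p is None and ``insufficient`` is set.
    """
    a = list(values_a)
    b = list(values_b)
    row: dict = {"group_a": labels[0], "group_b": labels[1]}
    for suffix, vals in (("a", a), ("b", b)):
        if vals:
            d = describe(vals)
            row.update({f"{k}_{suffix}": v for k, v in d.items()})
        else:
            row.update({f"{k}_{suffix}": np.nan
                        for k in ("n", "mean", "sd", "median", "min", "max")})
            row[f"n_{suffix}"] = 0
    if len(a) < 2 or len(b) < 2:
        row.update({"u_statistic": np.nan, "p_value": None,
                    "significant": False, "insufficient": True})
        return row
    u, p = rank_sum_test(a, b)
    row.update({"u_statistic": u, "p_value": p,
                "significant": bool(p < alpha), "insufficient": False})
    return row


def compare_by_status(per_patient: pd.DataFrame, measure: str,
                      by: Sequence[str] = ("diagnosis_group", "care_type"),
                      alpha: float = 0.05) -> pd.DataFrame:
    """Active-vs-remission comparisons of a per-patient measure within each
    cell of ``by`` (any subset of diagnosis_group / care_type / age_band).

    ``per_patient`` is long format: one row per patient × status (× by-cell)
    holding per-patient totals for ``measure``. No multiplicity correction is
    applied; raw p values are reported with a 0.05 significance flag.
    """
    by = [c for c in by if c in per_patient.columns]
    rows: List[dict] = []
    grouped = per_patient.groupby(by, sort=True) if by else [((), per_patient)]
    for keys, cell in grouped:
        if not isinstance(keys, tuple):
            keys = (keys,)
        a = cell.loc[cell["status"] == "active", measure]
        b = cell.loc[cell["status"] == "remission", measure]
        row = {"measure": measure, **dict(zip(by, keys))}
        row.update(compare_groups(a, b, alpha=alpha))
        row["p_display"] = format_p(row["p_value"])
        rows.append(row)
    return pd.DataFrame(rows)
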