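"""Independent brute-force oracles used only by the test suite.

These deliberately take a different computational route from the package:
the rank-sum oracle enumerates group-label assignments and derives U from
rank sums, and the event oracle re-scans the full prescription history for
every row instead of carrying state.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import rankdata


def brute_force_rank_sum(a, b):
    """Exact two-sided rank-sum p by enumerating every assignment of the
    pooled values into groups of sizes (n_a, n_b); U from the rank-sum
    formula with midranks."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = np.array(a + b)
    n, n_a = len(pooled), len(a)

    def u_of(indices):
        ranks = rankdata(pooled)
        r_a = sum(ranks[i] for i in indices)
        return r_a - n_a * (n_a + 1) / 2

    u_obs = u_of(range(n_a))
    le = ge = 0
    for picks in combinations(range(n), n_a):
        u = u_of(picks)
        if u <= u_obs:
            le += 1
        if u >= u_obs:
            ge += 1
    total = comb(n, n_a)
    return u_obs, min(1.0, 2.0 * min(le, ge) / total)


def oracle_events(rows, new_course_gap_days=90, ongoing_window_days=60):
    """Naive per-row rule evaluation over the whole history.

    ``rows`` are dicts with date (Timestamp), drug_name, molecule,
    drug_class, dose_value, is_biologic, sorted by (date, drug_name).
    Returns [(date, drug_name, event_type), ...].
    """
    seen = set()
    rs = []
    for r in rows:
        key = (r["date"], r["drug_name"])
        if key in seen:
            continue
        seen.add(key)
        rs.append(r)

    out = []
    for i, r in enumerate(rs):
        hist = rs[:i]
        same_mol = [h for h in hist if h["molecule"] == r["molecule"]]
        prev = same_mol[-1] if same_mol else None
        initiating = (prev is None
                      or (r["date"] - prev["date"]).days >= new_course_gap_days)
        bio_hist = [h for h in hist if h["is_biologic"]]

        event = None
        if r["is_biologic"]:
            if not bio_hist:
                event = "new_biologic"
            elif bio_hist[-1]["molecule"] != r["molecule"]:
                event = "biologic_change"
            elif initiating:
                event = "new_biologic"
            elif r["dose_value"] > prev["dose_value"]:
                event = "dose_escalation"
        else:
            if initiating:
                other_ongoing = any(
                    h["drug_class"] != r["drug_class"]
                    and (r["date"] - h["date"]).days <= ongoing_window_days
                    for h in hist
                )
                event = "class_addition" if other_ongoing else "new_non_biologic"
            elif r["dose_value"] > prev["dose_value"]:
                event = "dose_escalation"

        if event is not None:
            out.append((r["date"], r["drug_name"], event))
    return out
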