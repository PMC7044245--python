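"""Nonparametric group comparisons for outcome tables.

Each outcome is tested with the Kruskal-Wallis rank sum test (tie-corrected
H, chi-square p with k-1 df) for a main effect of lung condition across all
rows and for a main effect of ventilation modality separately within each
condition, at the 0.05 level.  Significant modality effects are followed by
Dunn's post hoc pairwise z comparisons with tie-corrected variance, adjusted
by the Benjamini-Hochberg step-up procedure within each outcome's family of
pairwise comparisons.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _stars(p: float) -> str:
    for level, mark in STAR_LEVELS:
        if p < level:
            return mark
    return ""


def _group_arrays(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    keep = np.isfinite(values)
    values, groups = values[keep], groups[keep]
    labels = pd.unique(groups)
    arrays = [values[groups == g] for g in labels]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(a) == 0 for a in arrays):
        raise ValueError("empty group")
    return labels, arrays


def kruskal_wallis(values, groups):
    """Kruskal-Wallis H and p-value for ``values`` split by ``groups``.

    Rank-based with tie correction; p from the chi-square approximation with
    k-1 degrees of freedom.  Returns (H, p); H = 0 and p = 1 when every
    observation is identical.
    """
    _, arrays = _group_arrays(values, groups)
    if sum(len(a) for a in arrays) < 2:
        raise ValueError("need at least 2 observations")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def dunn_posthoc_bh(values, groups) -> pd.DataFrame:
    """Dunn's pairwise post hoc z tests with tie correction and BH adjustment.

    For groups i, j the statistic is
    ``z = (Rbar_i - Rbar_j) / sqrt(S (1/n_i + 1/n_j))`` with
    ``S = N(N+1)/12 - sum(t^3 - t) / (12 (N-1))`` over tied groups; two-sided
    normal p-values are adjusted across the outcome's set of pairwise
    comparisons by Benjamini-Hochberg.
    """
    labels, arrays = _group_arrays(values, groups)
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for lbl, arr in zip(labels, arrays):
        mean_ranks[lbl] = ranks[start : start + len(arr)].mean()
        start += len(arr)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    s2 = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        s2 -= tie_term / (12.0 * (n_total - 1))
    rows = []
    for (la, aa), (lb, ab) in combinations(zip(labels, arrays), 2):
        se = np.sqrt(s2 * (1.0 / len(aa) + 1.0 / len(ab)))
        z = (mean_ranks[la] - mean_ranks[lb]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": la, "group_b": lb, "z": z, "p_raw": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    return out


def build_outcome_report(
    table: pd.DataFrame,
    outcomes: list[str] | None = None,
    alpha: float = 0.05,
):
    """Significance grid over an outcome table.

    ``table`` is long-format with columns ``subject``, ``condition``
    (baseline/injured), ``modality`` (CMV/HFOV/MFOV) and one column per
    outcome.  For each outcome, tests the condition main effect across all
    rows, and the modality effect separately within each condition; emits a
    grid with p-values and star levels, plus Dunn/BH pairwise tables for
    significant modality effects.

    Returns ``(report, posthoc)`` where ``report`` is a DataFrame indexed by
    outcome and ``posthoc`` maps ``(outcome, condition)`` to a Dunn table.
    """
    required = {"subject", "condition", "modality"}
    if not required <= set(table.columns):
        raise ValueError(f"table must contain columns {sorted(required)}")
    if outcomes is None:
        outcomes = [c for c in table.columns if c not in required]
    conditions = list(pd.unique(table["condition"]))
    rows = []
    posthoc: dict[tuple[str, str], pd.DataFrame] = {}
    for outcome in outcomes:
        vals = table[outcome].to_numpy(dtype=float)
        n_missing = int(np.sum(~np.isfinite(vals)))
        row = {"outcome": outcome, "n_missing": n_missing}
        _, p_cond = kruskal_wallis(vals, table["condition"].to_numpy())
        row["condition_p"] = p_cond
        row["condition_effect"] = _stars(p_cond)
        for cond in conditions:
            sel = table["condition"] == cond
            _, p_mod = kruskal_wallis(
                vals[sel.to_numpy()], table.loc[sel, "modality"].to_numpy()
            )
            row[f"modality_{cond}_p"] = p_mod
            row[f"modality_{cond}_effect"] = _stars(p_mod)
            if p_mod < alpha:
                posthoc[(outcome, cond)] = dunn_posthoc_bh(
                    vals[sel.to_numpy()], table.loc[sel, "modality"].to_numpy()
                )
        rows.append(row)
    report = pd.DataFrame(rows).set_index("outcome")
    return report, posthoc
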