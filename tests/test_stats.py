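"""Nonparametric group comparisons: Kruskal-Wallis, Dunn, BH."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ventstrain.stats import build_outcome_report, dunn_posthoc_bh, kruskal_wallis


def brute_force_kw(groups_of_values):
    """Independent oracle: H from first principles with tie correction."""
    pooled = np.concatenate(groups_of_values)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    # average ranks for ties
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j - 1) + 1
        i = j
    n = len(pooled)
    h = 0.0
    start = 0
    for g in groups_of_values:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    h /= correction
    p = sps.chi2.sf(h, len(groups_of_values) - 1)
    return h, p


def bh_adjust(p_raw):
    """Hand implementation of the Benjamini-Hochberg step-up rule."""
    p = np.asarray(p_raw, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj


def permutation_kw_null(values, groups, n_perm=100_000, seed=0):
    """Vectorized permutation distribution of tie-corrected H."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ranks = sps.rankdata(values)
    n = len(values)
    _, counts = np.unique(values, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    labels, inv = np.unique(groups, return_inverse=True)
    sizes = np.bincount(inv)
    rng = np.random.default_rng(seed)

    def h_of(rank_rows):  # rank_rows: (B, n)
        h = np.zeros(rank_rows.shape[0])
        start = 0
        for s in sizes:
            h += rank_rows[:, start : start + s].sum(axis=1) ** 2 / s
            start += s
        return (12.0 / (n * (n + 1)) * h - 3 * (n + 1)) / correction

    h_obs = h_of(np.concatenate([ranks[inv == k] for k in range(len(labels))])[None])[0]
    perms = np.array([rng.permutation(ranks) for _ in range(n_perm)])
    h_null = h_of(perms)
    p_perm = (1 + np.sum(h_null >= h_obs - 1e-12)) / (n_perm + 1)
    return h_obs, p_perm


class TestKruskalWallis:
    def test_identical_constant_groups_have_zero_h(self):
        h, p = kruskal_wallis([3.0] * 6, ["a"] * 2 + ["b"] * 2 + ["c"] * 2)
        assert h == 0.0 and p == 1.0

    def test_matches_brute_force_oracle(self):
        groups = [np.array([1.0, 2, 3]), np.array([4.0, 5, 6]), np.array([7.0, 8, 9])]
        h_ref, p_ref = brute_force_kw(groups)
        values = np.concatenate(groups)
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        h, p = kruskal_wallis(values, labels)
        assert h == pytest.approx(h_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_tied_data_matches_oracle(self):
        rng = np.random.default_rng(4)
        values = rng.integers(0, 5, size=24).astype(float)
        labels = np.repeat(["a", "b", "c"], 8)
        arrays = [values[labels == g] for g in ("a", "b", "c")]
        h_ref, p_ref = brute_force_kw(arrays)
        h, p = kruskal_wallis(values, labels)
        assert h == pytest.approx(h_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_small_sample_p_consistent_with_permutation_null(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=15)
        values[10:] += 1.0
        labels = np.repeat(["a", "b", "c"], 5)
        _, p_chi2 = kruskal_wallis(values, labels)
        _, p_perm = permutation_kw_null(values, labels, n_perm=100_000, seed=1)
        # chi-square approximation vs exact permutation: close at this n
        assert p_chi2 == pytest.approx(p_perm, abs=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0, 2.0], ["a", "a"])


class TestDunn:
    def test_identical_groups_adjusted_p_near_one(self):
        rng = np.random.default_rng(0)
        pooled = rng.normal(size=16)
        # two copies of the same sample: mean ranks coincide exactly
        mirrored = np.concatenate([pooled[:8], pooled[:8]])
        out = dunn_posthoc_bh(mirrored, ["a"] * 8 + ["b"] * 8)
        assert out["p_adj"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_single_shifted_group_flagged_only_in_its_comparisons(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        c = rng.normal(loc=6.0, size=10)
        values = np.concatenate([a, b, c])
        labels = np.repeat(["a", "b", "c"], 10)
        out = dunn_posthoc_bh(values, labels).set_index(["group_a", "group_b"])
        assert out.loc[("a", "c"), "p_adj"] < 0.05
        assert out.loc[("b", "c"), "p_adj"] < 0.05
        assert out.loc[("a", "b"), "p_adj"] >= 0.05

    def test_bh_adjustment_matches_hand_rule(self):
        # the step-up rule on {0.01, 0.02, 0.04} gives {0.03, 0.03, 0.04}
        assert np.allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])
        rng = np.random.default_rng(2)
        values = rng.normal(size=30)
        values[20:] += 1.5
        labels = np.repeat(["a", "b", "c"], 10)
        out = dunn_posthoc_bh(values, labels)
        assert np.allclose(out["p_adj"], bh_adjust(out["p_raw"]), atol=1e-12)

    def test_adjusted_p_monotone_and_bounded(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=24)
        labels = np.repeat(["a", "b", "c", "d"], 6)
        out = dunn_posthoc_bh(values, labels).sort_values("p_raw")
        assert out["p_adj"].is_monotonic_increasing
        assert (out["p_adj"] <= 1.0).all()

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(0.1, 2.0, size=18)
        labels = np.repeat(["a", "b", "c"], 6)
        out1 = dunn_posthoc_bh(values, labels)
        out2 = dunn_posthoc_bh(np.log(values), labels)
        assert np.allclose(out1["z"], out2["z"])
        h1, _ = kruskal_wallis(values, labels)
        h2, _ = kruskal_wallis(np.exp(values), labels)
        assert h1 == pytest.approx(h2)


class TestOutcomeReport:
    @staticmethod
    def _cohort(effect=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for subject in range(10):
            for condition in ("baseline", "injured"):
                for k, modality in enumerate(("CMV", "HFOV", "MFOV")):
                    rows.append(
                        {
                            "subject": subject,
                            "condition": condition,
                            "modality": modality,
                            "delta_eps_mean": rng.normal(0.2, 0.01)
                            - effect * 0.05 * k,
                        }
                    )
        return pd.DataFrame(rows)

    def test_strong_modality_effect_flagged_in_both_conditions(self):
        report, posthoc = build_outcome_report(self._cohort(effect=1.0))
        row = report.loc["delta_eps_mean"]
        assert row["modality_baseline_effect"] != ""
        assert row["modality_injured_effect"] != ""
        assert ("delta_eps_mean", "baseline") in posthoc

    def test_identical_outcome_flags_nothing(self):
        table = self._cohort(effect=0.0)
        table["delta_eps_mean"] = 1.0
        report, posthoc = build_outcome_report(table)
        row = report.loc["delta_eps_mean"]
        assert row["condition_effect"] == ""
        assert row["modality_baseline_effect"] == ""
        assert not posthoc

    def test_missing_cells_reported_not_fatal(self):
        table = self._cohort(effect=1.0)
        table.loc[3, "delta_eps_mean"] = np.nan
        report, _ = build_outcome_report(table)
        assert report.loc["delta_eps_mean", "n_missing"] == 1

    def test_requires_design_columns(self):
        with pytest.raises(ValueError):
            build_outcome_report(pd.DataFrame({"x": [1.0, 2.0]}))
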