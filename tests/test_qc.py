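"""Quantile normalization, probe collapse, and the outlier/duplicate screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dnmeta import (
    DataError,
    SimulationConfig,
    UsageError,
    assess_dataset,
    collapse_probes,
    concordance_scores,
    detect_doppelgangers,
    dixon_q,
    generate_multiset,
    ka_distances,
    quantile_normalize,
    rosner_esd,
)
from conftest import make_matrix


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        col = np.array([1.0, 5.0, 3.0, 2.0])
        m = pd.DataFrame({"a": col, "b": col})
        out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out, m)

    def test_single_column_unchanged(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize(m), m)

    def test_matches_sort_average_reassign_oracle(self, rng):
        m = make_matrix(rng, 50, 4)
        out = quantile_normalize(m)
        # oracle: sort each column, average across columns, hand values
        # back by rank (tie-free input)
        ref = np.sort(m.to_numpy(), axis=0).mean(axis=1)
        for col in m.columns:
            order = np.argsort(m[col].to_numpy())
            expected = np.empty(50)
            expected[order] = ref
            np.testing.assert_allclose(out[col].to_numpy(), expected, atol=1e-12)

    def test_idempotent(self, rng):
        m = make_matrix(rng, 40, 5)
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-10)

    def test_column_exchangeable(self, rng):
        m = make_matrix(rng, 30, 4)
        out = quantile_normalize(m)
        shuffled = m[["s2", "s0", "s3", "s1"]]
        out_shuffled = quantile_normalize(shuffled)
        np.testing.assert_allclose(
            out[["s2", "s0", "s3", "s1"]].to_numpy(),
            out_shuffled.to_numpy(), atol=1e-12,
        )

    def test_ties_get_mean_of_target_quantiles(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 9.0]})
        out = quantile_normalize(m)
        ref = np.sort(m.to_numpy(), axis=0).mean(axis=1)  # [1.5, 2.5, 7]
        assert out["a"].iloc[0] == out["a"].iloc[1] == pytest.approx(2.0)
        assert out["a"].iloc[2] == pytest.approx(ref[2])

    def test_nan_rejected(self):
        m = pd.DataFrame({"a": [1.0, np.nan]})
        with pytest.raises(DataError):
            quantile_normalize(m)


class TestCollapseProbes:
    def test_mean_of_probes_for_same_gene(self):
        m = pd.DataFrame({"s1": [2.0, 4.0]}, index=["p1", "p2"])
        pm = pd.Series({"p1": "GENEA", "p2": "GENEA"})
        out = collapse_probes(m, pm)
        assert out.loc["GENEA", "s1"] == pytest.approx(3.0)

    def test_multimapping_probe_dropped(self):
        m = pd.DataFrame({"s1": [2.0, 5.0]}, index=["p1", "p2"])
        # p1 maps to two symbols (duplicated probe-map entries)
        pm = pd.Series(["GENEA", "GENEB", "GENEC"], index=["p1", "p1", "p2"])
        out = collapse_probes(m, pm)
        assert list(out.index) == ["GENEC"]

    def test_one_probe_per_gene_is_identity_with_renames(self, rng):
        m = make_matrix(rng, 10, 3)
        pm = pd.Series({f"g{i}": f"GENE{i}" for i in range(10)})
        out = collapse_probes(m, pm)
        assert sorted(out.index) == sorted(pm.values)
        np.testing.assert_allclose(
            out.loc[[f"GENE{i}" for i in range(10)]].to_numpy(), m.to_numpy()
        )

    def test_all_dropped_is_error(self):
        m = pd.DataFrame({"s1": [1.0]}, index=["p1"])
        with pytest.raises(DataError):
            collapse_probes(m, pd.Series({"px": "GENEA"}))


class TestDoppelgangers:
    def test_exact_duplicate_detected_at_one(self, rng):
        m = make_matrix(rng, 100, 3)
        m["s3"] = m["s0"]
        pairs, _ = detect_doppelgangers(m, 0.99)
        assert ("s0", "s3", pytest.approx(1.0)) in [
            (a, b, r) for a, b, r in pairs
        ]

    def test_independent_columns_give_no_pairs(self, rng):
        m = make_matrix(rng, 2000, 6)
        pairs, _ = detect_doppelgangers(m, 0.99)
        assert pairs == []

    def test_planted_duplicate_found_in_bundle(self, default_bundle):
        datasets, truth = default_bundle
        found = set()
        for d in datasets:
            pairs, _ = detect_doppelgangers(d.expr, 0.99)
            found |= {frozenset((a, b)) for a, b, _ in pairs}
        assert {frozenset(p) for p in truth.duplicate_pairs} <= found

    def test_zero_variance_sample_excluded_with_warning(self, rng):
        m = make_matrix(rng, 50, 3)
        m["s2"] = 1.0
        pairs, warns = detect_doppelgangers(m, 0.99)
        assert any("s2" in w for w in warns)


class TestConcordance:
    def test_identical_arrays_score_one(self):
        col = np.arange(20, dtype=float)
        m = pd.DataFrame({f"s{i}": col for i in range(4)})
        scores = concordance_scores(m)
        np.testing.assert_allclose(scores, 1.0)

    def test_shuffled_array_has_minimal_score(self, rng):
        base = rng.normal(8, 1.5, 500)
        m = pd.DataFrame(
            {f"s{i}": base + rng.normal(0, 0.3, 500) for i in range(9)}
        )
        m["s0"] = rng.permutation(m["s0"].to_numpy())
        scores = concordance_scores(m)
        assert scores.idxmin() == "s0"
        assert scores["s0"] < scores.drop("s0").min() - 0.3

    def test_matches_rank_correlation_oracle(self, rng):
        m = make_matrix(rng, 20, 5)
        scores = concordance_scores(m)
        ranks = m.rank(axis=0)
        for col in m.columns:
            med = ranks.drop(columns=col).median(axis=1)
            rho = stats.spearmanr(m[col], med).statistic
            assert scores[col] == pytest.approx(rho, abs=1e-12)


class TestKa:
    def test_identical_arrays_zero_no_flags(self):
        col = np.arange(30, dtype=float)
        m = pd.DataFrame({f"s{i}": col for i in range(4)})
        ka, flags = ka_distances(m)
        np.testing.assert_allclose(ka, 0.0)
        assert flags == set()

    def test_shifted_array_flagged(self, rng):
        m = make_matrix(rng, 500, 9)
        m["s0"] = m["s0"] + 3.0
        ka, flags = ka_distances(m)
        assert "s0" in flags
        assert ka["s0"] > 0.5

    def test_matches_ecdf_max_gap_oracle(self, rng):
        m = make_matrix(rng, 30, 4)
        ka, _ = ka_distances(m)
        for j, col in enumerate(m.columns):
            own = np.sort(m[col].to_numpy())
            rest = np.sort(m.drop(columns=col).to_numpy().ravel())
            grid = np.concatenate([own, rest])
            e1 = np.searchsorted(own, grid, side="right") / len(own)
            e2 = np.searchsorted(rest, grid, side="right") / len(rest)
            assert ka[col] == pytest.approx(np.abs(e1 - e2).max(), abs=1e-12)


class TestRosnerEsd:
    def test_flags_obvious_outlier(self):
        vals = pd.Series([2.0, 2.1, 2.2, 2.3, 10.0])
        flagged = rosner_esd(vals, max_outliers=1, alpha=0.05)
        assert flagged == [4]
        # oracle: direct R1 vs lambda1 at n=5
        r1 = (10.0 - vals.mean()) / vals.std(ddof=1)
        p = 1 - 0.05 / (2 * 5)
        t = stats.t.ppf(p, 3)
        lam1 = 4 * t / np.sqrt((3 + t**2) * 5)
        assert r1 > lam1

    def test_constant_values_flag_nothing(self):
        assert rosner_esd(pd.Series([1.0] * 10), 2) == []

    def test_matches_independent_esd_decision_rule(self, rng):
        x = pd.Series(rng.standard_normal(50))
        x.iloc[3] += 6.0
        flagged = rosner_esd(x, max_outliers=3, alpha=0.05)
        # independent re-derivation: compute all (R_i, lambda_i) explicitly
        work = x.copy()
        rs, lams, order = [], [], []
        n = 50
        for i in range(1, 4):
            dev = (work - work.mean()).abs()
            idx = dev.idxmax()
            rs.append(dev[idx] / work.std(ddof=1))
            ni = n - i + 1
            t = stats.t.ppf(1 - 0.05 / (2 * ni), ni - 2)
            lams.append((ni - 1) * t / np.sqrt((ni - 2 + t**2) * ni))
            order.append(idx)
            work = work.drop(idx)
        j = max((i for i in range(1, 4) if rs[i - 1] > lams[i - 1]), default=0)
        assert flagged == order[:j]
        assert 3 in flagged


class TestDixonQ:
    def test_statistic_arithmetic(self):
        flagged, q = dixon_q(pd.Series([1.0, 2.0, 3.0, 4.0, 10.0]), 0.05)
        assert q == pytest.approx((10 - 4) / (10 - 1), abs=1e-12)
        # published two-sided critical value at n=5, alpha=0.05 is 0.710
        assert flagged is None

    def test_clear_outlier_flagged(self):
        flagged, q = dixon_q(pd.Series([1.0, 1.1, 1.2, 1.3, 9.0]), 0.05)
        assert flagged == 4

    def test_all_equal_undefined_no_flag(self):
        flagged, q = dixon_q(pd.Series([2.0, 2.0, 2.0]), 0.05)
        assert flagged is None and q == 0.0

    @pytest.mark.parametrize("n", [2, 31])
    def test_out_of_range_n(self, n):
        with pytest.raises(UsageError):
            dixon_q(pd.Series(np.arange(n, dtype=float)), 0.05)


class TestAssessDataset:
    def test_shuffled_outlier_and_duplicate_flagged(self):
        cfg = SimulationConfig(seed=5, n_outlier_arrays=1, n_duplicate_pairs=1)
        datasets, truth = generate_multiset(cfg)
        flagged, pairs = set(), set()
        for d in datasets:
            r = assess_dataset(d)
            flagged |= r.flagged_outliers
            pairs |= {frozenset((a, b)) for a, b, _ in r.doppelganger_pairs}
        assert truth.outlier_samples <= flagged
        assert {frozenset(p) for p in truth.duplicate_pairs} <= pairs

    def test_flagged_samples_exist_in_dataset(self, default_bundle):
        datasets, _ = default_bundle
        for d in datasets:
            r = assess_dataset(d)
            assert r.flagged_outliers <= set(d.samples)
            assert all(r.ka.index.equals(d.samples) for _ in [0])
            assert ((r.ka >= 0) & (r.ka <= 1)).all()
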