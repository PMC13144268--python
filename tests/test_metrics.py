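"""PSNR/SSIM and the Friedman / Dunn-Holm statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fastdat.metrics import (
    MetricTable,
    dunn_holm,
    evaluate_stats,
    friedman_test,
    psnr,
    ssim,
    summarize,
)

# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the implementation path)
# ---------------------------------------------------------------------------


def ssim_oracle(ref, test, max_val=1.0, sigma=1.5, win=11, K1=0.01, K2=0.03):
    """Direct local-statistics SSIM: explicit Gaussian-weighted moments at
    every position where the full window fits, averaged."""
    half = win // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1]
    w = np.exp(-(x**2 + y**2) / (2 * sigma**2))
    w /= w.sum()
    C1, C2 = (K1 * max_val) ** 2, (K2 * max_val) ** 2
    H, W = ref.shape
    vals = []
    for i in range(half, H - half):
        for j in range(half, W - half):
            a = ref[i - half : i + half + 1, j - half : j + half + 1]
            b = test[i - half : i + half + 1, j - half : j + half + 1]
            mu_a, mu_b = (w * a).sum(), (w * b).sum()
            var_a = (w * a * a).sum() - mu_a**2
            var_b = (w * b * b).sum() - mu_b**2
            cov = (w * a * b).sum() - mu_a * mu_b
            vals.append(
                ((2 * mu_a * mu_b + C1) * (2 * cov + C2))
                / ((mu_a**2 + mu_b**2 + C1) * (var_a + var_b + C2))
            )
    return float(np.mean(vals))


def friedman_oracle(data):
    """Tie-corrected Friedman chi-square from first principles."""
    n, k = data.shape
    ranks = np.array([stats.rankdata(row) for row in data])
    rank_sums = ranks.sum(axis=0)
    A = (ranks**2).sum()
    C = n * k * (k + 1) ** 2 / 4.0
    if A == C:
        return 0.0, 1.0
    chi2 = (k - 1) * ((rank_sums - n * (k + 1) / 2.0) ** 2).sum() / (A - C)
    return chi2, stats.chi2.sf(chi2, k - 1)


def dunn_oracle(data, ref_col):
    """Dunn z and two-sided p for ref vs each column, from pooled ranks."""
    n, k = data.shape
    N = n * k
    pooled = stats.rankdata(data.ravel()).reshape(n, k)
    _, counts = np.unique(data.ravel(), return_counts=True)
    ties = (counts**3 - counts).sum() / (12.0 * (N - 1))
    var = (N * (N + 1) / 12.0 - ties) * (2.0 / n)
    out = []
    for j in range(k):
        if j == ref_col:
            continue
        z = (pooled[:, ref_col].mean() - pooled[:, j].mean()) / np.sqrt(var)
        out.append((j, z, min(1.0, 2 * stats.norm.sf(abs(z)))))
    return out


def make_table(data, methods=None):
    methods = methods or [f"m{j}" for j in range(data.shape[1])]
    rows = [
        {"slice_id": f"s{i}", "method_id": methods[j], "psnr": data[i, j], "ssim": 0.5}
        for i in range(data.shape[0])
        for j in range(data.shape[1])
    ]
    return MetricTable(pd.DataFrame(rows), methods=methods, reference_method=methods[0])


# ---------------------------------------------------------------------------
# PSNR
# ---------------------------------------------------------------------------


class TestPsnr:
    def test_identical_images_are_infinite(self, rng):
        img = rng.random((16, 16))
        assert psnr(img, img) == float("inf")

    def test_constant_offset_closed_form(self):
        ref = np.zeros((8, 8))
        test = np.full((8, 8), 10 / 255)
        expected = 10 * np.log10(1.0 / (10 / 255) ** 2)
        assert psnr(ref, test) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(28.131, abs=1e-3)

    def test_halving_error_adds_six_db(self, rng):
        ref = rng.random((16, 16))
        noise = rng.normal(0, 0.05, (16, 16))
        gain = psnr(ref, ref + 0.5 * noise) - psnr(ref, ref + noise)
        assert gain == pytest.approx(20 * np.log10(2), abs=1e-9)

    def test_strictly_decreasing_in_mse(self, rng):
        ref = rng.random((16, 16))
        noise = rng.normal(0, 1, (16, 16))
        vals = [psnr(ref, ref + a * noise) for a in (0.01, 0.02, 0.05, 0.1)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            psnr(np.ones((4, 4)), np.ones((5, 5)))

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            ref, test = rng.random((12, 12)), rng.random((12, 12))
            direct = 10 * np.log10(1.0 / np.mean((ref - test) ** 2))
            assert psnr(ref, test) == pytest.approx(direct, abs=1e-10)


class TestSsim:
    def test_identical_images_give_one(self, rng):
        img = rng.random((32, 32))
        assert ssim(img, img) == pytest.approx(1.0, abs=1e-12)

    def test_constant_images_closed_form(self):
        """For constants 0 and 1: luminance term C1/(1+C1), contrast/structure 1."""
        ref = np.zeros((16, 16))
        test = np.ones((16, 16))
        C1 = 0.01**2
        assert ssim(ref, test) == pytest.approx(C1 / (1 + C1), rel=1e-9)

    def test_symmetry(self, rng):
        a, b = rng.random((16, 16)), rng.random((16, 16))
        assert ssim(a, b) == pytest.approx(ssim(b, a), abs=1e-12)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="window"):
            ssim(np.ones((8, 8)), np.ones((8, 8)))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(8):
            a, b = rng.random((16, 16)), rng.random((16, 16))
            assert ssim(a, b) == pytest.approx(ssim_oracle(a, b), abs=1e-6)


class TestSummarize:
    def test_hand_computed_mean_sd(self):
        table = make_table(np.array([[30.0], [32.0], [34.0]]))
        (row,) = summarize(table, "psnr")
        assert row["mean"] == pytest.approx(32.0)
        assert row["sd"] == pytest.approx(2.0)

    def test_single_slice_sd_flagged_zero(self):
        table = make_table(np.array([[30.0]]))
        (row,) = summarize(table, "psnr")
        assert row["sd"] == 0.0 and not row["sd_defined"]

    def test_shift_invariance_of_sd(self, rng):
        data = rng.random((10, 2)) * 10
        base = summarize(make_table(data), "psnr")
        shifted = summarize(make_table(data + 5.0), "psnr")
        for b, s in zip(base, shifted):
            assert s["mean"] == pytest.approx(b["mean"] + 5.0)
            assert s["sd"] == pytest.approx(b["sd"])

    def test_infinite_rows_excluded_with_count(self):
        data = np.array([[30.0], [np.inf], [34.0]])
        with pytest.warns(UserWarning, match="infinite"):
            (row,) = summarize(make_table(data), "psnr")
        assert row["n_infinite"] == 1 and row["n"] == 2
        assert row["mean"] == pytest.approx(32.0)


class TestFriedman:
    def test_perfectly_ordered_three_methods(self):
        """One method always best, one always worst: chi2 = 6, p ~ 0.0498."""
        data = np.array([[3.0, 2.0, 1.0], [3.1, 2.1, 1.1], [3.2, 2.2, 1.2]])
        stat, p = friedman_test(make_table(data), "psnr")
        assert stat == pytest.approx(6.0, abs=1e-12)
        assert p == pytest.approx(0.0498, abs=1e-4)

    def test_identical_methods_give_zero_statistic(self):
        data = np.tile(np.arange(5.0)[:, None], (1, 3))
        stat, p = friedman_test(make_table(data), "psnr")
        assert stat == 0.0 and p == 1.0

    def test_invariant_under_within_slice_monotone_transform(self, rng):
        data = rng.random((12, 4))
        stat1, _ = friedman_test(make_table(data), "psnr")
        stat2, _ = friedman_test(make_table(np.exp(3 * data)), "psnr")
        assert stat1 == pytest.approx(stat2, abs=1e-10)

    def test_matches_scipy_and_oracle_on_random_tables(self, rng):
        for _ in range(25):
            data = rng.random((8, 4))
            stat, p = friedman_test(make_table(data), "psnr")
            o_stat, o_p = friedman_oracle(data)
            s_stat, s_p = stats.friedmanchisquare(*data.T)
            assert stat == pytest.approx(o_stat, abs=1e-10)
            assert p == pytest.approx(o_p, abs=1e-10)
            assert stat == pytest.approx(s_stat, abs=1e-10)

    def test_missing_cells_rejected(self):
        table = make_table(np.ones((3, 2)))
        table.df = table.df.iloc[:-1]
        with pytest.raises(ValueError, match="missing"):
            friedman_test(table, "psnr")


class TestDunnHolm:
    def test_reference_vs_identical_copy_gives_p_one(self):
        rng = np.random.default_rng(0)
        col = rng.random(10)
        data = np.column_stack([col, col])
        rows = dunn_holm(make_table(data), "psnr")
        assert rows[0]["raw_p"] == pytest.approx(1.0)
        assert rows[0]["holm_p"] == pytest.approx(1.0)

    def test_holm_dominates_raw_and_preserves_order(self, rng):
        data = rng.random((15, 5))
        data[:, 0] += 0.5
        rows = dunn_holm(make_table(data), "psnr")
        for r in rows:
            assert r["holm_p"] >= r["raw_p"] - 1e-15
        by_raw = sorted(rows, key=lambda r: r["raw_p"])
        holms = [r["holm_p"] for r in by_raw]
        assert holms == sorted(holms)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            data = rng.random((10, 3))
            table = make_table(data)
            rows = dunn_holm(table, "psnr")
            oracle = dunn_oracle(data, 0)
            for r, (j, z, p) in zip(rows, oracle):
                assert r["z"] == pytest.approx(z, abs=1e-10)
                assert r["raw_p"] == pytest.approx(p, abs=1e-10)

    def test_absent_reference_rejected(self, rng):
        with pytest.raises(ValueError, match="reference"):
            dunn_holm(make_table(rng.random((4, 2))), "psnr", reference="nope")


class TestPipelineCalibration:
    def test_null_rejection_rate_near_alpha(self, rng):
        """Same-distribution methods: Friedman rejects at ~alpha over replicates."""
        n_tables, alpha = 200, 0.05
        rejections = 0
        for _ in range(n_tables):
            data = rng.normal(size=(20, 4))
            _, p = friedman_test(make_table(data), "psnr")
            rejections += p < alpha
        rate = rejections / n_tables
        se = np.sqrt(alpha * (1 - alpha) / n_tables)
        assert abs(rate - alpha) < 3 * se + 1e-12

    def test_planted_effect_detected(self, rng):
        """One method strictly closer to reference on every slice: tiny p."""
        detected = 0
        for _ in range(20):
            base = rng.normal(size=(250, 4))
            base[:, 0] += 1.0
            _, p = friedman_test(make_table(base), "psnr")
            detected += p < 0.01
        assert detected >= 19

    def test_evaluate_stats_bundles_all_parts(self, rng):
        data = rng.random((10, 3))
        rep = evaluate_stats(make_table(data), "psnr")
        assert len(rep.summary) == 3 and len(rep.posthoc) == 2
        assert 0 <= rep.friedman_p <= 1
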