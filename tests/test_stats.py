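import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rhinoflow.stats import (AgreementSummary, PairedMeasurements,
                             adjusted_correlation, bland_altman,
                             correlation_category, logdiff, paired_ttest,
                             pearson)


def pairs_from(d, **extra):
    """PairedMeasurements whose log-differences are exactly d."""
    d = np.asarray(d, float)
    table = pd.DataFrame({"rhino_value": 10.0 ** d, "sim_value": 1.0, **extra})
    return PairedMeasurements(table)


class TestLogdiff:
    def test_equal_values_zero(self):
        assert logdiff(pairs_from([0.0, 0.0]))[0] == 0.0

    def test_tenfold_is_one(self):
        p = PairedMeasurements(pd.DataFrame({"rhino_value": [10.0],
                                             "sim_value": [1.0]}))
        assert logdiff(p)[0] == pytest.approx(1.0)

    def test_ratio_182_percent_26(self):
        p = PairedMeasurements(pd.DataFrame({"rhino_value": [182.0],
                                             "sim_value": [100.0]}))
        assert logdiff(p)[0] == pytest.approx(np.log10(1.82), abs=1e-12)
        assert logdiff(p)[0] == pytest.approx(0.26, abs=0.003)

    def test_backtransform_identity_row_exact(self):
        rng = np.random.default_rng(3)
        rhino = rng.uniform(1, 500, 50)
        sim = rng.uniform(1, 500, 50)
        p = PairedMeasurements(pd.DataFrame({"rhino_value": rhino,
                                             "sim_value": sim}))
        assert np.allclose(10.0 ** logdiff(p), rhino / sim, rtol=1e-12)

    def test_nonpositive_value_rejected_naming_row(self):
        with pytest.raises(ValueError, match="rows"):
            PairedMeasurements(pd.DataFrame({"rhino_value": [1.0, -2.0],
                                             "sim_value": [1.0, 1.0]}))


def exact_mean_sd(mean, sd, n=4):
    """n values with exactly the requested mean and sample sd."""
    a = sd * np.sqrt((n - 1) / n)
    half = n // 2
    return np.r_[np.full(half, mean + a), np.full(half, mean - a)]


class TestBlandAltman:
    def test_perfect_agreement(self):
        out = bland_altman(pairs_from([0.0] * 4), stratum_keys=())
        s = out[0]
        assert (s.mean_logdiff, s.half_width) == (0.0, 0.0)
        assert (s.ratio_mean, s.ratio_half_width) == (1.0, 1.0)

    @pytest.mark.parametrize("mean,half,ratios", [
        (0.02, 0.47, (1.05, 2.95)),
        (0.26, 0.40, (1.82, 2.51)),
        (0.29, 0.47, (1.95, 2.95)),
        (0.03, 0.40, (1.07, 2.51)),
    ])
    def test_backtransformed_ratio_factors(self, mean, half, ratios):
        d = exact_mean_sd(mean, half / 1.96)
        s = bland_altman(pairs_from(d), stratum_keys=())[0]
        assert s.mean_logdiff == pytest.approx(mean, abs=1e-12)
        assert s.half_width == pytest.approx(half, abs=1e-12)
        assert round(s.ratio_mean, 2) == ratios[0]
        assert round(s.ratio_half_width, 2) == ratios[1]

    def test_strata_partition_rows(self):
        rng = np.random.default_rng(1)
        n = 40
        table = pd.DataFrame({
            "rhino_value": rng.uniform(10, 100, n),
            "sim_value": rng.uniform(10, 100, n),
            "side": rng.choice(["left", "right"], n),
            "phase": rng.choice(["inspiration", "expiration"], n),
        })
        out = bland_altman(PairedMeasurements(table))
        assert sum(s.n for s in out) == n

    def test_small_stratum_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            out = bland_altman(pairs_from([0.1, 0.2], side=["l", "l"]),
                               stratum_keys=("side",), min_n=3)
        assert out == []


class TestAdjustedCorrelation:
    def test_constant_factors_equal_plain_pearson(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(10, 300, 40)
        y = x * rng.uniform(0.8, 1.2, 40)
        table = pd.DataFrame({"rhino_value": x, "sim_value": y,
                              "subject": "s1", "side": "left",
                              "phase": "inspiration"})
        r, p = adjusted_correlation(PairedMeasurements(table))
        r0, p0 = sps.pearsonr(np.log10(x), np.log10(y))
        assert r == pytest.approx(r0, abs=1e-10)

    def test_per_subject_scaling_gives_unit_correlation(self):
        rng = np.random.default_rng(6)
        rows = []
        for subj, c in (("s1", 0.5), ("s2", 2.0), ("s3", 7.0)):
            sim = rng.uniform(10, 300, 12)
            for v in sim:
                rows.append({"subject": subj, "side": "left",
                             "phase": "inspiration",
                             "rhino_value": c * v, "sim_value": v})
        r, p = adjusted_correlation(PairedMeasurements(pd.DataFrame(rows)))
        assert r == pytest.approx(1.0, abs=1e-9)
        assert p < 1e-6

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(7)
        n = 200
        table = pd.DataFrame({
            "subject": rng.choice(["a", "b", "c"], n),
            "side": rng.choice(["left", "right"], n),
            "phase": "inspiration",
            "rhino_value": rng.lognormal(3, 1, n),
            "sim_value": rng.lognormal(3, 1, n),
        })
        r, _ = adjusted_correlation(PairedMeasurements(table))
        assert abs(r) < 0.2

    def test_invariant_to_subject_rescaling(self):
        rng = np.random.default_rng(8)
        n = 30
        table = pd.DataFrame({
            "subject": np.repeat(["a", "b"], n // 2),
            "side": "left", "phase": "inspiration",
            "rhino_value": rng.lognormal(2, 0.5, n),
            "sim_value": rng.lognormal(2, 0.5, n),
        })
        r1, _ = adjusted_correlation(PairedMeasurements(table))
        scaled = table.copy()
        scaled.loc[scaled.subject == "a", "rhino_value"] *= 37.0
        r2, _ = adjusted_correlation(PairedMeasurements(scaled))
        assert r1 == pytest.approx(r2, abs=1e-10)


class TestPearson:
    def test_perfect_linear(self):
        r, p, cat = pearson([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)
        assert cat == "strong"

    def test_against_direct_formula(self):
        x = np.array([1, 2, 3, 4, 5, 6.0])
        y = np.array([2, 1, 3, 2, 4, 5.0])
        r, p, _ = pearson(x, y)
        xm, ym = x - x.mean(), y - y.mean()
        r_direct = (xm * ym).sum() / np.sqrt((xm ** 2).sum() * (ym ** 2).sum())
        assert r == pytest.approx(r_direct, abs=1e-12)

    @pytest.mark.parametrize("r,cat", [
        (0.65, "moderate"), (0.85, "strong"), (0.3, "weak"),
        (0.8, "strong"), (0.6, "moderate"),   # boundaries assigned upward
    ])
    def test_strength_categories(self, r, cat):
        assert correlation_category(r) == cat

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1, 1, 1], [1, 2, 3])


class TestPairedTTest:
    def test_identical_vectors(self):
        out = paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["t"] == 0.0 and out["p"] == 1.0

    def test_constant_nonzero_difference_degenerate(self):
        with pytest.warns(UserWarning, match="infinite"):
            out = paired_ttest([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert np.isinf(out["t"]) and out["p"] == 0.0

    def test_matches_t_distribution_oracle(self):
        rng = np.random.default_rng(9)
        a = rng.normal(1.0, 0.3, 10)
        b = rng.normal(0.9, 0.3, 10)
        out = paired_ttest(a, b)
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p = 2 * sps.t.sf(abs(t), len(d) - 1)
        assert out["t"] == pytest.approx(t, abs=1e-12)
        assert out["p"] == pytest.approx(p, abs=1e-12)
        assert out["rhino_mean"] == pytest.approx(a.mean())
        assert out["sim_sd"] == pytest.approx(b.std(ddof=1))

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0], [2.0])
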