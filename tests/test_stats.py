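"""Group statistics: normality screen, Mann-Whitney, effect sizes, summaries."""

import itertools

import numpy as np
import pytest
import scipy.stats

from phonemark.errors import DegenerateSampleError, InvalidArgumentError
from phonemark.stats import (
    anderson_darling_normal,
    anova_from_summary,
    glass_delta_from_summary,
    group_feature_table,
    mann_whitney_u,
    ttest_from_summary,
)


def mann_whitney_enumeration(x, y):
    """Exact two-sided Mann-Whitney by enumerating all rank assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx = len(x)
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    u_obs = min(u_obs, nx * len(y) - u_obs)
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), nx):
        u = ranks[list(comb)].sum() - nx * (nx + 1) / 2
        u = min(u, nx * len(y) - u)
        count += u <= u_obs
        total += 1
    return u_obs, count / total


class TestAndersonDarling:
    def test_matches_scipy_statistic(self, rng):
        import warnings

        x = rng.standard_normal(200)
        a2, _ = anderson_darling_normal(x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            ref = float(scipy.stats.anderson(x, dist="norm").statistic)
        assert a2 == pytest.approx(ref, rel=1e-9)

    def test_type_i_calibration(self):
        rejections = sum(
            anderson_darling_normal(np.random.default_rng(s).standard_normal(500))[1]
            for s in range(100))
        assert rejections <= 5  # ~5% nominal level

    def test_power_against_exponential(self):
        rejections = sum(
            anderson_darling_normal(np.random.default_rng(s).exponential(size=500))[1]
            for s in range(50))
        assert rejections == 50

    def test_location_scale_invariance(self, rng):
        x = rng.standard_normal(100)
        a2, _ = anderson_darling_normal(x)
        a2b, _ = anderson_darling_normal(3.0 * x - 7.0)
        assert a2b == pytest.approx(a2, rel=1e-9)

    def test_degenerate_sample(self):
        with pytest.raises(DegenerateSampleError):
            anderson_darling_normal(np.ones(20))

    def test_small_sample_rejected(self):
        with pytest.raises(InvalidArgumentError):
            anderson_darling_normal(np.arange(5.0))


class TestMannWhitney:
    def test_separated_small_samples_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert min(u, 9 - u) == 0
        assert p == pytest.approx(0.100, abs=1e-9)

    def test_identical_samples(self):
        _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_exact_branch_matches_enumeration(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            nx = int(rng.integers(2, 6))
            ny = int(rng.integers(2, 6))
            x = rng.standard_normal(nx)
            y = rng.standard_normal(ny) + rng.normal(0, 1)
            _, p = mann_whitney_u(x, y)
            _, p_enum = mann_whitney_enumeration(x, y)
            # the folded-U enumeration mass is the two-sided exact p
            assert p == pytest.approx(p_enum, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidArgumentError):
            mann_whitney_u([], [1.0])


class TestGlassDelta:
    @pytest.mark.parametrize("mc, sc, mp, expected", [
        (3.69e-2, 3.00e-2, 6.50e-2, -0.937),   # noise-to-harmonics, /e/
        (4.03e-2, 1.95e-2, 5.51e-2, -0.759),   # relative shimmer, /o/
        (5.30e-3, 4.21e-3, 7.53e-3, -0.530),   # relative jitter, /o/
        (4.87e1, 4.93e1, 7.41e1, -0.515),      # SD(F1), /a/
    ])
    def test_reference_effect_sizes(self, mc, sc, mp, expected):
        assert glass_delta_from_summary(mc, sc, mp) == pytest.approx(expected,
                                                                     abs=5e-4)

    def test_equal_means_zero(self):
        assert glass_delta_from_summary(1.0, 2.0, 1.0) == 0.0

    def test_zero_sd_rejected(self):
        with pytest.raises(InvalidArgumentError):
            glass_delta_from_summary(1.0, 0.0, 2.0)


class TestSummaryTests:
    @pytest.mark.parametrize("m1, s1, m2, s2, expected_p", [
        (35.92, 22.77, 37.56, 14.03, 0.760),   # motor score
        (2.30, 0.94, 2.28, 0.54, 0.927),       # disease stage
        (8.86, 5.88, 12.58, 11.52, 0.157),     # years since diagnosis
    ])
    def test_reference_cohort_ttests(self, m1, s1, m2, s2, expected_p):
        _, p = ttest_from_summary(m1, s1, 25, m2, s2, 25)
        assert p == pytest.approx(expected_p, abs=5e-4)

    def test_identical_summaries(self):
        t, p = ttest_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_matches_raw_ttest(self, rng):
        x = rng.standard_normal(30) * 2 + 1
        y = rng.standard_normal(40) * 3 - 0.5
        t, p = ttest_from_summary(x.mean(), x.std(ddof=1), len(x),
                                  y.mean(), y.std(ddof=1), len(y))
        ref = scipy.stats.ttest_ind(x, y, equal_var=True)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_anova_two_groups_equals_t_squared(self):
        t, pt = ttest_from_summary(1.0, 1.2, 12, 1.8, 0.9, 15)
        f, pf = anova_from_summary([(1.0, 1.2, 12), (1.8, 0.9, 15)])
        assert f == pytest.approx(t**2, rel=1e-12)
        assert pf == pytest.approx(pt, rel=1e-10)

    def test_anova_equal_means(self):
        f, p = anova_from_summary([(2.0, 1.0, 10), (2.0, 1.0, 10), (2.0, 1.0, 10)])
        assert f == 0.0
        assert p == pytest.approx(1.0)

    def test_anova_matches_reconstructed_samples(self, rng):
        """Summaries of exact-moment samples reproduce scipy's one-way ANOVA."""
        groups = []
        raw = []
        for mean, sd, n in [(0.0, 1.0, 10), (0.5, 1.3, 12), (1.0, 0.8, 9)]:
            g = rng.standard_normal(n)
            g = (g - g.mean()) / g.std(ddof=1) * sd + mean  # exact moments
            raw.append(g)
            groups.append((mean, sd, n))
        f, p = anova_from_summary(groups)
        ref = scipy.stats.f_oneway(*raw)
        assert f == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-8)


class TestGroupTable:
    def test_feature_table_layout(self, rng):
        import pandas as pd

        rows = []
        for g, shift in (("control", 0.0), ("pd", 1.0)):
            for i in range(15):
                rows.append(dict(subject_id=f"{g}{i}", group=g, phoneme="a",
                                 repetition=0, feat_x=rng.normal(shift),
                                 feat_y=rng.normal()))
        table = group_feature_table(pd.DataFrame(rows))
        assert set(table["feature"]) == {"feat_x", "feat_y"}
        row = table[table.feature == "feat_x"].iloc[0]
        assert row.p_value < 0.05
        assert row.effect_size < 0  # disease group shifted upward
        assert row.n_control == 15 and row.n_pd == 15
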