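"""Exonic-imbalance statistics: normalization, z scoring, contrasts, Welch."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fusionwire.exon_imbalance import (
    BALANCED,
    IMBALANCED_3P,
    IMBALANCED_5P,
    ImbalanceError,
    breakpoint_contrast,
    cohort_zscores,
    compare_groups,
    exon_zscores,
    imbalance_score,
    imbalance_table,
    normalize_exon_counts,
)
from fusionwire.synthetic_cohort import CohortSpec, gen_exon_counts


def _mat(counts, lengths, libs):
    df = pd.DataFrame(counts, dtype=float)
    df.columns = [f"s{j}" for j in range(df.shape[1])]
    return df, pd.Series(lengths, index=df.index), pd.Series(libs, index=df.columns)


class TestNormalization:
    def test_zero_counts_pseudocount_one_gives_zero(self):
        df, L, N = _mat(np.zeros((3, 2)), [100, 200, 300], [1e6, 2e6])
        x = normalize_exon_counts(df, L, N, pseudocount=1)
        assert (x.to_numpy() == 0).all()

    def test_rpkm_arithmetic(self):
        df, L, N = _mat([[1000]], [1000], [1e6])
        x = normalize_exon_counts(df, L, N, pseudocount=0)
        assert x.iloc[0, 0] == pytest.approx(np.log2(1000), abs=1e-9)

    def test_depth_invariance(self):
        df, L, N = _mat([[10, 20], [30, 5]], [100, 250], [1e6, 5e5])
        x1 = normalize_exon_counts(df, L, N, pseudocount=1)
        x2 = normalize_exon_counts(df * 2, L, N * 2, pseudocount=1)
        pd.testing.assert_frame_equal(x1, x2)

    def test_zero_library_errors(self):
        df, L, N = _mat([[1]], [100], [0.0])
        with pytest.raises(ImbalanceError):
            normalize_exon_counts(df, L, N)


class TestZScores:
    def test_constant_vector_is_zero(self):
        assert exon_zscores([5, 5, 5]).tolist() == [0, 0, 0]

    def test_one_two_three(self):
        np.testing.assert_allclose(exon_zscores([1, 2, 3]), [-1, 0, 1])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False), min_size=2, max_size=20
        ).filter(lambda v: np.std(v) > 1e-6)
    )
    def test_unit_moments(self, v):
        z = exon_zscores(v)
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1) < 1e-9

    def test_imbalance_score_examples(self):
        assert imbalance_score([0, 0, 0]) == 0
        assert imbalance_score([-1, 0, 1]) == 1
        with pytest.raises(ImbalanceError):
            imbalance_score([])


class TestCohortZScores:
    def test_balanced_samples_score_near_unit_noise(self, rng):
        expr = pd.DataFrame(rng.normal(7, 0.5, (9, 40)),
                            columns=[f"s{j}" for j in range(40)])
        z = cohort_zscores(expr)
        assert abs(float(z.to_numpy().std()) - 1) < 0.15

    def test_level_shift_invariance(self, rng):
        """Uniformly silencing a sample (multiplying expression down) does
        not change its cohort z scores."""
        expr = pd.DataFrame(rng.normal(7, 0.5, (9, 20)),
                            columns=[f"s{j}" for j in range(20)])
        ref = list(expr.columns[:10])
        shifted = expr.copy()
        shifted["s15"] = shifted["s15"] - 3.0  # 8x silenced in log2
        z1 = cohort_zscores(expr, ref)
        z2 = cohort_zscores(shifted, ref)
        np.testing.assert_allclose(z1["s15"], z2["s15"], atol=1e-9)

    def test_step_sample_scores_high(self, rng):
        expr = pd.DataFrame(rng.normal(7, 0.3, (9, 30)),
                            columns=[f"s{j}" for j in range(30)])
        expr.iloc[7:9, 0] -= 3.0  # last two exons lost in sample 0
        z = cohort_zscores(expr, list(expr.columns[1:]))
        assert imbalance_score(z["s0"]) > 3 * imbalance_score(z["s5"])


class TestBreakpointContrast:
    def test_flat_profile_is_balanced(self):
        delta, call = breakpoint_contrast(np.full(9, 4.0), list(range(1, 8)))
        assert delta == 0 and call == BALANCED

    def test_step_arithmetic(self, rng):
        x = np.concatenate([np.full(7, 10.0), np.zeros(2)])
        x += rng.normal(0, 1e-9, 9)
        delta, call = breakpoint_contrast(x, list(range(1, 8)))
        assert delta > 1e6 and call == IMBALANCED_5P

    def test_three_prime_partner_direction(self):
        x = np.array([0.0, 0.1, 8.0, 8.2, 8.1])
        delta, call = breakpoint_contrast(x, [3, 4, 5], role="three_prime_partner")
        assert delta > 1.5 and call == IMBALANCED_3P

    def test_retained_must_be_proper_subset(self):
        with pytest.raises(ImbalanceError):
            breakpoint_contrast([1, 2, 3], [])
        with pytest.raises(ImbalanceError):
            breakpoint_contrast([1, 2, 3], [1, 2, 3])

    def test_sign_recovers_simulated_direction(self, toy_genes, cohort_fusions):
        """At r=10 the contrast sign matches the simulated overexpressed
        side in nearly all fusion-positive samples."""
        sizes = {"FN": 0, "P3F": 200, "P7F": 0, "P3N": 0, "P3I": 0}
        m, _ = gen_exon_counts(
            CohortSpec(group_sizes=sizes, seed=21), toy_genes, cohort_fusions
        )
        tab = imbalance_table(m, "PAX3", retained=list(range(1, 8)),
                              reference_group=None)
        frac = (tab["epistate"] == IMBALANCED_5P).mean()
        assert frac >= 0.99


class TestCompareGroups:
    def test_identical_groups_null(self):
        s = pd.Series([1.0, 2, 3, 1, 2, 3], index=list("abcdef"))
        g = pd.Series(["A"] * 3 + ["B"] * 3, index=list("abcdef"))
        res = compare_groups(s, g, "A", "B")
        assert res.statistic == 0 and res.pvalue == 1

    def test_large_shift_significant_and_matches_permutation_oracle(self, rng):
        a = np.array([1.0, 2.0, 3.0])
        b = a + 10
        s = pd.Series(np.r_[a, b], index=[f"x{i}" for i in range(6)])
        g = pd.Series(["A"] * 3 + ["B"] * 3, index=s.index)
        res = compare_groups(s, g, "A", "B")
        assert res.pvalue < 0.01
        # permutation oracle on |mean difference|
        obs = abs(a.mean() - b.mean())
        pool = np.r_[a, b]
        hits = 0
        n_perm = 2000
        for _ in range(n_perm):
            rng.shuffle(pool)
            hits += abs(pool[:3].mean() - pool[3:].mean()) >= obs - 1e-12
        p_perm = hits / n_perm
        assert res.pvalue < 0.05 and p_perm <= 0.15

    def test_welch_agrees_with_permutation_on_random_data(self, rng):
        """Welch p tracks a permutation-oracle p on small random datasets."""
        for _ in range(20):
            n1, n2 = int(rng.integers(4, 10)), int(rng.integers(4, 10))
            a = rng.normal(0, 1, n1)
            b = rng.normal(rng.normal(0, 1), 1, n2)
            s = pd.Series(np.r_[a, b], index=[f"x{i}" for i in range(n1 + n2)])
            g = pd.Series(["A"] * n1 + ["B"] * n2, index=s.index)
            res = compare_groups(s, g, "A", "B")
            pool = np.r_[a, b]
            stat = abs(a.mean() - b.mean())
            perm = np.empty(2000)
            for k in range(2000):
                rng.shuffle(pool)
                perm[k] = abs(pool[:n1].mean() - pool[n1:].mean())
            p_perm = (perm >= stat - 1e-12).mean()
            assert abs(res.pvalue - p_perm) < 0.12

    def test_too_small_group_errors(self):
        s = pd.Series([1.0, 2, 3], index=list("abc"))
        g = pd.Series(["A", "A", "B"], index=list("abc"))
        with pytest.raises(ImbalanceError):
            compare_groups(s, g, "A", "B")


class TestScaleInvariance:
    def test_sample_scaling_leaves_statistics_unchanged(
        self, toy_genes, cohort_fusions
    ):
        """Multiplying one sample's counts by a constant (with library size
        recomputed) leaves z, Z* and delta unchanged at pseudocount 0."""
        sizes = {"FN": 5, "P3F": 3, "P7F": 0, "P3N": 0, "P3I": 0}
        m, _ = gen_exon_counts(CohortSpec(group_sizes=sizes, seed=5),
                               toy_genes, cohort_fusions)
        t1 = imbalance_table(m, "PAX3", retained=list(range(1, 8)), pseudocount=0)
        scaled = m.counts.copy()
        scaled.iloc[:, 0] *= 7
        from fusionwire.exon_imbalance import ExonCountMatrix
        m2 = ExonCountMatrix(counts=scaled, lengths=m.lengths, groups=m.groups)
        t2 = imbalance_table(m2, "PAX3", retained=list(range(1, 8)), pseudocount=0)
        np.testing.assert_allclose(t1["z_star"], t2["z_star"], rtol=1e-9)
        np.testing.assert_allclose(t1["delta"], t2["delta"], rtol=1e-9)


class TestMonotonicity:
    def test_expected_z_star_and_delta_nondecreasing_in_r(
        self, toy_genes, cohort_fusions
    ):
        """E[Z*] and E[|delta|] rise with the simulated imbalance ratio
        (expectations estimated by averaging over seeds; the fusion group
        is kept a minority so the cohort MAD scale holds)."""
        sizes = {"FN": 45, "P3F": 15, "P7F": 0, "P3N": 0, "P3I": 0}
        genes = {"PAX3": toy_genes["PAX3"], "FOXO1": toy_genes["FOXO1"]}
        z_means, d_means = [], []
        for r in (1, 2, 5, 10, 50):
            zm, dm = [], []
            for seed in range(12):
                m, _ = gen_exon_counts(
                    CohortSpec(
                        group_sizes=sizes,
                        imbalance_ratio=float(r),
                        seed=100 * seed + 13,
                    ),
                    genes,
                    cohort_fusions,
                )
                tab = imbalance_table(m, "PAX3", retained=list(range(1, 8)))
                sub = tab[tab["group"] == "P3F"]
                zm.append(sub["z_star"].mean())
                dm.append(sub["delta"].abs().mean())
            z_means.append(np.mean(zm))
            d_means.append(np.mean(dm))
        assert all(b >= a - 0.2 for a, b in zip(z_means, z_means[1:]))
        assert z_means[-1] > z_means[0] + 1
        assert all(b > a for a, b in zip(d_means, d_means[1:]))
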