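import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retinaspec.stats import (
    build_long_table,
    fdr_two_stage,
    grubbs_screen_subjects,
    grubbs_test,
    ks_normality,
    per_wavelength_posthoc,
    rm_two_way_anova,
    significant_bands,
    _gg_epsilon,
)


# --------------------------------------------------------------- oracles

def mixed_anova_oracle(y: np.ndarray):
    """Brute-force sums-of-squares mixed ANOVA for a balanced design.

    ``y[g, s, k]``: group g, subject s, within-level k. Returns the three
    F statistics (group, within, interaction) from the textbook
    decomposition computed with explicit loops.
    """
    g, n, k = y.shape
    grand = y.mean()
    m_group = y.mean(axis=(1, 2))
    m_subj = y.mean(axis=2)
    m_level = y.mean(axis=(0, 1))
    m_cell = y.mean(axis=1)

    ss_group = n * k * sum((m_group[i] - grand) ** 2 for i in range(g))
    ss_subj = k * sum((m_subj[i, j] - m_group[i]) ** 2
                      for i in range(g) for j in range(n))
    ss_level = g * n * sum((m_level[c] - grand) ** 2 for c in range(k))
    ss_inter = n * sum((m_cell[i, c] - m_group[i] - m_level[c] + grand) ** 2
                       for i in range(g) for c in range(k))
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_group - ss_subj - ss_level - ss_inter

    df_group, df_subj = g - 1, g * (n - 1)
    df_level, df_inter = k - 1, (g - 1) * (k - 1)
    df_err = g * (n - 1) * (k - 1)
    f_group = (ss_group / df_group) / (ss_subj / df_subj)
    f_level = (ss_level / df_level) / (ss_err / df_err)
    f_inter = (ss_inter / df_inter) / (ss_err / df_err)
    return f_group, f_level, f_inter


def bky_oracle(pvals, alpha):
    """Literal two-stage step-up definition: stage 1 at alpha/(1+alpha)
    estimates the null count, stage 2 re-runs the step-up at the adapted
    level. Returns the set of rejected indices."""
    m = len(pvals)
    a1 = alpha / (1 + alpha)

    def stepup(level):
        order = sorted(range(m), key=lambda i: pvals[i])
        r = 0
        for rank in range(m, 0, -1):
            if pvals[order[rank - 1]] <= rank * level / m:
                r = rank
                break
        return set(order[:r])

    r1 = len(stepup(a1))
    if r1 == 0:
        return set()
    if r1 == m:
        return set(range(m))
    return stepup(a1 * m / (m - r1))


def _table_from_array(y: np.ndarray) -> pd.DataFrame:
    g, n, k = y.shape
    rows = []
    for i in range(g):
        for j in range(n):
            for c in range(k):
                rows.append((f"g{i}s{j}", f"g{i}", 400.0 + 10 * c, y[i, j, c]))
    return pd.DataFrame(rows, columns=["subject_id", "group",
                                       "wavelength_nm", "value"])


# --------------------------------------------------------------- KS test

class TestKsNormality:
    def test_exact_normal_quantiles_pass(self):
        from scipy.stats import norm

        x = norm.ppf((np.arange(1, 51) - 0.5) / 50)
        _, p = ks_normality(x)
        assert p > 0.9

    def test_lilliefors_rejects_uniforms_far_above_alpha(self):
        """With estimated parameters the Lilliefors variant rejects uniform
        samples at a rate far above the nominal level (the plain-KS default
        is deliberately conservative)."""
        rng = np.random.default_rng(0)
        rej = sum(ks_normality(rng.uniform(0, 1, 200),
                               method="lilliefors")[1] < 0.05
                  for _ in range(100))
        assert rej >= 80

    def test_deterministic_for_same_sample(self):
        x = np.random.default_rng(1).normal(size=30)
        assert ks_normality(x) == ks_normality(x.copy())

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0, 3.0, 4.0])


# ------------------------------------------------------------ Grubbs test

class TestGrubbs:
    def test_hand_example_g_is_15(self):
        # [1, 1, 1, 10]: mean 3.25, sd 4.5 -> G = 6.75/4.5 = 1.5
        res = grubbs_test([1, 1, 1, 10])
        assert res.statistic == pytest.approx(1.5)
        assert res.outlier_index == 3

    def test_symmetric_triple_not_flagged(self):
        res = grubbs_test([-1.0, 0.0, 1.0])
        assert res.statistic == pytest.approx(1.0)
        assert res.outlier_index is None
        # n=3 critical value is ~1.1543 at alpha=0.05
        assert res.critical == pytest.approx(1.1543, abs=1e-3)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            grubbs_test([2.0, 2.0, 2.0, 2.0])

    @given(a=st.floats(min_value=0.01, max_value=100),
           b=st.floats(min_value=-50, max_value=50))
    @settings(max_examples=30, deadline=None)
    def test_location_scale_invariance(self, a, b):
        x = np.array([0.1, 0.5, -0.3, 2.4, 0.0, -1.1])
        r1 = grubbs_test(x)
        r2 = grubbs_test(a * x + b)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-9)
        assert r1.outlier_index == r2.outlier_index

    def test_profile_level_screening_drops_flagged_subject(self, grid5):
        from retinaspec import SpectralProfile

        n = len(grid5)
        profs = [SpectralProfile(grid5, np.full(n, v))
                 for v in (1.0, 1.1, 0.9, 1.05, 8.0)]
        ctrl = [SpectralProfile(grid5, np.full(n, v))
                for v in (1.0, 1.02, 0.98)]
        table = build_long_table({"amyloid": profs, "control": ctrl})
        filtered, excluded = grubbs_screen_subjects(table)
        assert excluded == ["amyloid:4"]
        assert set(filtered["subject_id"]) == {
            "amyloid:0", "amyloid:1", "amyloid:2", "amyloid:3",
            "control:0", "control:1", "control:2"}


# ----------------------------------------------------------------- ANOVA

class TestMixedAnova:
    def test_identical_groups_give_null_group_effect(self):
        y = np.zeros((2, 4, 3))
        base = np.array([[1.0, 2.0, 3.0], [2.0, 1.0, 4.0],
                         [0.0, 2.0, 2.0], [1.5, 2.5, 3.5]])
        y[0] = base
        y[1] = base
        res = rm_two_way_anova(_table_from_array(y))
        assert res.group.F == pytest.approx(0.0, abs=1e-12)
        assert res.group.p == pytest.approx(1.0)

    def test_matches_bruteforce_oracle_on_random_balanced_designs(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            g = int(rng.integers(2, 4))
            n = int(rng.integers(3, 7))
            k = int(rng.integers(2, 6))
            y = rng.integers(-5, 6, size=(g, n, k)).astype(float)
            # guard against degenerate zero error strata
            y += rng.normal(0, 0.5, size=y.shape)
            fg, fl, fi = mixed_anova_oracle(y)
            res = rm_two_way_anova(_table_from_array(y))
            assert res.group.F == pytest.approx(fg, abs=1e-8, rel=1e-8)
            assert res.wavelength.F == pytest.approx(fl, abs=1e-8, rel=1e-8)
            assert res.interaction.F == pytest.approx(fi, abs=1e-8, rel=1e-8)

    def test_epsilon_near_one_under_compound_symmetry(self):
        """Compound-symmetric (spherical) within-subject covariance should
        give a Greenhouse-Geisser epsilon close to 1 at large n."""
        rng = np.random.default_rng(7)
        n, k = 200, 4
        y = np.empty((2, n, k))
        for gi in range(2):
            subj = rng.normal(0, 1.0, size=(n, 1))
            y[gi] = subj + rng.normal(0, 1.0, size=(n, k))
        eps = _gg_epsilon(_table_from_array(y))
        assert eps > 0.95

    def test_corrected_p_never_smaller_than_uncorrected(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=(2, 6, 5))
        y[1] += np.linspace(0, 1, 5)
        res = rm_two_way_anova(_table_from_array(y))
        assert 0 < res.eps <= 1
        assert res.wavelength.p_gg >= res.wavelength.p
        assert res.interaction.p_gg >= res.interaction.p

    def test_incomplete_design_rejected(self):
        y = np.random.default_rng(9).normal(size=(2, 4, 3))
        table = _table_from_array(y).iloc[:-1]
        with pytest.raises(ValueError, match="wavelength"):
            rm_two_way_anova(table)

    def test_singleton_group_rejected(self):
        y = np.random.default_rng(10).normal(size=(2, 4, 3))
        table = _table_from_array(y)
        table = table[~((table.group == "g1") & (table.subject_id != "g1s0"))]
        with pytest.raises(ValueError, match="two subjects"):
            rm_two_way_anova(table)


# ------------------------------------------------------------------- FDR

class TestFdrTwoStage:
    def test_all_ones_yield_no_discoveries(self):
        reject, q, m0 = fdr_two_stage(np.ones(10))
        assert not reject.any()
        assert m0 == 10

    def test_single_small_p_discovered(self):
        reject, q, _ = fdr_two_stage([0.001])
        assert reject.all()
        assert q[0] <= 0.05

    def test_reference_p_list_matches_literal_oracle(self):
        p = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212,
             0.216]
        reject, q, m0 = fdr_two_stage(p)
        assert set(np.nonzero(reject)[0]) == bky_oracle(p, 0.05)
        # flags and q-values are mutually consistent
        np.testing.assert_array_equal(reject, q <= 0.05)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle_and_statsmodels_on_random_lists(self, seed):
        from statsmodels.stats.multitest import fdrcorrection_twostage

        rng = np.random.default_rng(seed)
        m = int(rng.integers(3, 40))
        p = np.concatenate([rng.uniform(0, 1, m),
                            rng.uniform(0, 0.01, int(rng.integers(0, 5)))])
        rng.shuffle(p)
        reject, q, _ = fdr_two_stage(p)
        assert set(np.nonzero(reject)[0]) == bky_oracle(list(p), 0.05)
        sm_rej, sm_q = fdrcorrection_twostage(p, alpha=0.05, method="bky",
                                              maxiter=1)[:2]
        np.testing.assert_array_equal(reject, sm_rej)
        np.testing.assert_allclose(q, np.clip(sm_q, 0, 1), rtol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_contains_plain_bh_discoveries(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(100 + seed)
        p = np.concatenate([rng.uniform(0, 1, 30), rng.uniform(0, 0.02, 5)])
        reject, _, _ = fdr_two_stage(p)
        bh = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        assert set(np.nonzero(bh)[0]) <= set(np.nonzero(reject)[0])

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fdr_two_stage([])
        with pytest.raises(ValueError):
            fdr_two_stage([0.5, 1.2])


# --------------------------------------------------------------- post hoc

class TestPosthoc:
    def _two_group_table(self, rng, effect, n_a=6, n_b=6, k=20):
        rows = []
        wl = 400 + 5 * np.arange(k)
        for g, n in (("a", n_a), ("b", n_b)):
            for j in range(n):
                vals = rng.normal(0, 1, k)
                if g == "a":
                    vals = vals + effect
                for c in range(k):
                    rows.append((f"{g}{j}", g, float(wl[c]), vals[c]))
        return pd.DataFrame(rows, columns=["subject_id", "group",
                                           "wavelength_nm", "value"])

    def test_identical_groups_no_significant_wavelengths(self):
        rng = np.random.default_rng(11)
        table = self._two_group_table(rng, effect=0.0)
        out = per_wavelength_posthoc(table)
        assert not out["significant"].any()
        assert significant_bands(out) == []

    def test_large_effect_everywhere_detected(self):
        rng = np.random.default_rng(12)
        table = self._two_group_table(rng, effect=5.0)
        out = per_wavelength_posthoc(table)
        assert out["significant"].all()
        assert significant_bands(out) == [(400.0, 495.0)]

    def test_zero_variance_anchor_band_handled(self, grid5):
        from retinaspec import SpectralProfile, normalize_profile

        rng = np.random.default_rng(13)
        groups = {}
        for g in ("a", "b"):
            profs = []
            for _ in range(4):
                vals = 10 + 0.05 * (grid5.wavelengths_nm - 320) \
                    + rng.normal(0, 0.1, len(grid5))
                profs.append(normalize_profile(SpectralProfile(grid5, vals)))
            groups[g] = profs
        out = per_wavelength_posthoc(build_long_table(groups))
        anchor = out[out.wavelength_nm.isin([380.0, 670.0])]
        assert (anchor["p"] == 1.0).all()
        assert np.isfinite(out["p"]).all()

    def test_band_grouping_of_significance_runs(self):
        df = pd.DataFrame({
            "wavelength_nm": [400.0, 405.0, 410.0, 415.0, 420.0],
            "t": 0.0, "p": 1.0, "q": 1.0,
            "significant": [True, True, False, True, True],
        })
        assert significant_bands(df) == [(400.0, 405.0), (415.0, 420.0)]
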