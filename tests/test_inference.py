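import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dynecm.inference import (
    DesignMatrix,
    fit_cognition_interaction,
    fit_variability_model,
    fit_voxelwise_glm,
    make_design,
    permutation_fwe,
    tfce,
)
from dynecm.io_volumes import AnalysisMask, VolumeGeometry
from tests.oracles import tfce_bruteforce


@pytest.fixture
def grid_mask():
    geom = VolumeGeometry(shape=(8, 8, 8), affine=np.eye(4))
    idx = np.argwhere(np.ones(geom.shape, dtype=bool))
    return AnalysisMask(geometry=geom, voxel_indices=idx)


def _group_design(n, rng, covariates=True):
    group = (np.arange(n) < n // 2).astype(float)
    cols = {"group": group}
    if covariates:
        cols["age"] = rng.normal(65, 7, n)
        cols["sex"] = rng.integers(0, 2, n).astype(float)
    df = pd.DataFrame(cols)
    return make_design(df, list(cols)), group


class TestDesignMatrix:
    def test_requires_intercept_and_full_rank(self, rng):
        with pytest.raises(ValueError, match="intercept"):
            DesignMatrix(rng.standard_normal((10, 2)), names=("a", "b"))
        x = rng.standard_normal(10)
        with pytest.raises(ValueError, match="rank"):
            DesignMatrix(
                np.column_stack([np.ones(10), x, 2 * x]), names=("i", "a", "b")
            )

    def test_contrast_builder(self, rng):
        design, _ = _group_design(10, rng)
        c = design.contrast({"group": 1.0})
        assert c.tolist() == [0.0, 1.0, 0.0, 0.0]


class TestVoxelwiseGlm:
    def test_reduces_to_classical_two_sample_t(self, rng):
        n, V = 30, 50
        maps = rng.standard_normal((n, V))
        design, group = _group_design(n, rng, covariates=False)
        _, t = fit_voxelwise_glm(maps, design, design.contrast({"group": 1.0}))
        ref = stats.ttest_ind(maps[group == 1], maps[group == 0], equal_var=True)
        assert np.allclose(t, ref.statistic, atol=1e-10)

    def test_constant_shift_moves_intercept_not_group_t(self, rng):
        n, V = 24, 20
        maps = rng.standard_normal((n, V))
        design, _ = _group_design(n, rng)
        c = design.contrast({"group": 1.0})
        _, t1 = fit_voxelwise_glm(maps, design, c)
        _, t2 = fit_voxelwise_glm(maps + 100.0, design, c)
        assert np.allclose(t1, t2, atol=1e-8)

    def test_null_t_follows_student_t(self, rng):
        n, V = 20, 4000
        maps = rng.standard_normal((n, V))
        design, _ = _group_design(n, rng)
        _, t = fit_voxelwise_glm(maps, design, design.contrast({"group": 1.0}))
        ks = stats.kstest(t, stats.t(df=n - design.values.shape[1]).cdf)
        assert ks.pvalue > 0.01


class TestTfce:
    def test_all_zero_map(self):
        assert np.array_equal(tfce(np.zeros((5, 5, 5))), np.zeros((5, 5, 5)))

    def test_single_voxel_converges_to_cubic_third(self):
        v = 2.0
        m = np.zeros((5, 5, 5))
        m[2, 2, 2] = v
        enhanced = tfce(m, E=0.5, H=2.0, dh=v / 1000)
        assert abs(enhanced[2, 2, 2] - v**3 / 3) / (v**3 / 3) < 0.01

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_labelling_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.standard_normal((10, 10, 10))
        dh = m.max() / 40
        assert np.allclose(tfce(m, dh=dh), tfce_bruteforce(m, 0.5, 2.0, dh), atol=1e-10)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="finite"):
            tfce(np.full((3, 3, 3), np.nan))
        with pytest.raises(ValueError):
            tfce(np.ones((3, 3, 3)), E=0.0)
        with pytest.raises(ValueError):
            tfce(np.ones((3, 3)))


class TestPermutationFwe:
    def test_massive_effect_reaches_smallest_attainable_p(self, grid_mask, rng):
        n = 24
        maps = rng.standard_normal((n, grid_mask.n_voxels))
        design, group = _group_design(n, rng, covariates=False)
        bump = np.zeros(grid_mask.n_voxels)
        bump[:40] = 8.0  # contiguous strong effect in the first voxels
        maps += np.outer(group, bump)
        res = permutation_fwe(
            maps, design, design.contrast({"group": 1.0}), grid_mask,
            n_permutations=100, seed=0,
        )
        assert res.fwe_p.min() == pytest.approx(1.0 / 101)

    def test_null_data_gives_large_p(self, grid_mask, rng):
        n = 20
        maps = rng.standard_normal((n, grid_mask.n_voxels))
        design, _ = _group_design(n, rng)
        res = permutation_fwe(
            maps, design, design.contrast({"group": 1.0}), grid_mask,
            n_permutations=100, seed=1,
        )
        assert res.fwe_p.min() >= 1.0 / 101
        assert res.fwe_p.max() <= 1.0
        assert (res.tfce_values >= 0).all()

    def test_seed_reproducibility(self, grid_mask, rng):
        n = 16
        maps = rng.standard_normal((n, grid_mask.n_voxels))
        design, _ = _group_design(n, rng)
        c = design.contrast({"group": 1.0})
        a = permutation_fwe(maps, design, c, grid_mask, n_permutations=100, seed=42)
        b = permutation_fwe(maps, design, c, grid_mask, n_permutations=100, seed=42)
        assert np.array_equal(a.fwe_p, b.fwe_p)
        assert np.array_equal(a.perm_max, b.perm_max)

    def test_warns_when_b_cannot_resolve_alpha(self, grid_mask, rng):
        n = 16
        maps = rng.standard_normal((n, grid_mask.n_voxels))
        design, _ = _group_design(n, rng)
        with pytest.warns(UserWarning, match="alpha"):
            permutation_fwe(
                maps, design, design.contrast({"group": 1.0}), grid_mask,
                n_permutations=100, seed=0, alpha=0.005,
            )

    def test_too_few_permutations_rejected(self, grid_mask, rng):
        maps = rng.standard_normal((16, grid_mask.n_voxels))
        design, _ = _group_design(16, rng)
        with pytest.raises(ValueError, match="100"):
            permutation_fwe(
                maps, design, design.contrast({"group": 1.0}), grid_mask,
                n_permutations=50, seed=0,
            )


def _scalar_cohort(rng, n=700, effect=0.0):
    group = (rng.random(n) < 0.33).astype(float)
    df = pd.DataFrame(
        {
            "amyloid_pos": group,
            "age": rng.normal(65, 7, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "education": rng.normal(14, 4, n),
        }
    )
    df["outcome"] = rng.standard_normal(n) + effect * group
    return df


class TestVariabilityModel:
    def test_recovers_planted_group_shift(self):
        """Unbiased recovery of a -0.3 SD planted shift at n=700.

        Averaged over 10 replicate cohorts so the check targets estimator
        accuracy rather than single-draw sampling luck.
        """
        betas = []
        for seed in range(10):
            df = _scalar_cohort(np.random.default_rng(seed), n=700, effect=-0.3)
            res = fit_variability_model(df, "outcome", "amyloid_pos")
            betas.append(res.term("amyloid_pos")["estimate"])
        assert all(b < 0 for b in betas)
        assert abs(np.mean(betas) - (-0.3)) < 0.1

    def test_null_p_uniform_over_replications(self):
        rng = np.random.default_rng(6)
        pvals = []
        for _ in range(500):
            n = 60
            group = np.r_[np.zeros(40), np.ones(20)]
            y = rng.standard_normal(n)
            df = pd.DataFrame(
                {
                    "amyloid_pos": group,
                    "age": rng.normal(65, 7, n),
                    "sex": rng.integers(0, 2, n).astype(float),
                    "outcome": y,
                }
            )
            pvals.append(
                fit_variability_model(df, "outcome", "amyloid_pos").term(
                    "amyloid_pos"
                )["p"]
            )
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_three_level_at_factor_with_reference(self):
        rng = np.random.default_rng(7)
        df = _scalar_cohort(rng, n=300)
        df["at_group"] = np.select(
            [df.index % 3 == 0, df.index % 3 == 1], ["A-T-", "A+T-"], "A+T+"
        )
        res = fit_variability_model(df, "outcome", "at_group")
        names = set(res.terms["term"])
        assert "at_group[A+T-]" in names and "at_group[A+T+]" in names
        assert "at_group[A-T-]" not in names  # reference level

    def test_duplicated_outcome_as_covariate_rejected(self):
        rng = np.random.default_rng(8)
        df = _scalar_cohort(rng, n=100)
        df["dup"] = df["outcome"]
        with pytest.raises(ValueError, match="rank"):
            fit_variability_model(df, "outcome", "amyloid_pos", covariates=("dup",))

    def test_small_group_rejected(self):
        rng = np.random.default_rng(9)
        df = _scalar_cohort(rng, n=50)
        df["amyloid_pos"] = 0.0
        df.loc[0, "amyloid_pos"] = 1.0
        with pytest.raises(ValueError, match="3 subjects"):
            fit_variability_model(df, "outcome", "amyloid_pos")


class TestCognitionInteraction:
    def _cohort_with_slopes(self, rng, n, slope_pos, slope_neg):
        df = _scalar_cohort(rng, n=n)
        df["score"] = rng.standard_normal(n)
        slope = np.where(df["amyloid_pos"] == 1.0, slope_pos, slope_neg)
        df["outcome"] = slope * df["score"] + rng.standard_normal(n)
        return df

    def test_detects_group_specific_slope(self):
        rng = np.random.default_rng(10)
        df = self._cohort_with_slopes(rng, 700, slope_pos=-0.3, slope_neg=0.0)
        res = fit_cognition_interaction(df, "outcome", "score")
        assert res.term("score:amyloid")["p"] < 0.05
        slopes = res.simple_slopes.set_index("group")["estimate"]
        assert slopes["A+"] < 0

    def test_interaction_p_invariant_to_amyloid_coding(self):
        rng = np.random.default_rng(11)
        df = self._cohort_with_slopes(rng, 300, slope_pos=-0.2, slope_neg=0.1)
        p1 = fit_cognition_interaction(df, "outcome", "score").term("score:amyloid")["p"]
        df2 = df.assign(amyloid_pos=df["amyloid_pos"] + 1.0)  # 1/2 coding
        p2 = fit_cognition_interaction(df2, "outcome", "score").term("score:amyloid")["p"]
        assert p1 == pytest.approx(p2, abs=1e-10)

    def test_constant_score_rejected(self):
        rng = np.random.default_rng(12)
        df = _scalar_cohort(rng, n=50)
        df["score"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_cognition_interaction(df, "outcome", "score")
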