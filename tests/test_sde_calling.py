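import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dimorph import (
    SdeCriteria,
    bh_fdr,
    call_sde_all,
    call_sde_tissue,
    group_means,
    join_and_validate,
    student_t_two_tailed,
)
from tests.conftest import make_dataset


class TestGroupMeans:
    def test_log_scale_means(self, demo_sim):
        cols = demo_sim.dataset.group_columns("Liver", "M")
        got = group_means(demo_sim.matrix, cols)
        want = demo_sim.matrix[cols].to_numpy().mean(axis=1)
        np.testing.assert_allclose(got.to_numpy(), want)

    def test_single_sample_group(self):
        m = pd.DataFrame({"s1": [7.2]}, index=["p"])
        assert group_means(m, ["s1"]).iloc[0] == 7.2

    def test_empty_group_error(self, demo_sim):
        with pytest.raises(ValueError, match="empty"):
            group_means(demo_sim.matrix, [])


class TestStudentT:
    def test_hand_example(self):
        # pooled variance 1, se = sqrt(2/3), t = 2/se, df = 4
        res = student_t_two_tailed([8, 9, 10], [6, 7, 8])
        assert res.t_stat == pytest.approx(2.449489742783178)
        assert res.p_value == pytest.approx(0.0704845, abs=1e-6)
        assert not res.degenerate

    def test_identical_constant_groups(self):
        res = student_t_two_tailed([5, 5, 5], [5, 5, 5])
        assert res.t_stat == 0.0 and res.p_value == 1.0 and not res.degenerate

    def test_zero_variance_unequal_means_flagged(self):
        res = student_t_two_tailed([6, 6], [5, 5])
        assert res.p_value == 0.0 and res.degenerate
        assert np.isinf(res.t_stat) and res.t_stat > 0

    def test_group_too_small(self):
        with pytest.raises(ValueError, match=">=2"):
            student_t_two_tailed([1.0], [2.0, 3.0])

    def test_matches_reference_implementation(self, rng):
        a = rng.normal(8, 1, size=(300, 5))
        b = rng.normal(8, 1.5, size=(300, 5))
        res = student_t_two_tailed(a, b)
        ref_t, ref_p = sps.ttest_ind(a, b, axis=1, equal_var=True)
        np.testing.assert_allclose(res.t_stat, ref_t, atol=1e-10, rtol=0)
        np.testing.assert_allclose(res.p_value, ref_p, atol=1e-10, rtol=0)

    def test_unbalanced_groups(self, rng):
        a = rng.normal(size=(50, 3))
        b = rng.normal(size=(50, 5))
        res = student_t_two_tailed(a, b)
        ref_t, ref_p = sps.ttest_ind(a, b, axis=1, equal_var=True)
        np.testing.assert_allclose(res.t_stat, ref_t, atol=1e-10, rtol=0)
        np.testing.assert_allclose(res.p_value, ref_p, atol=1e-10, rtol=0)


def _bh_oracle(p):
    """Literal step-up definition: q_(i) = min_{j>=i}(p_(j)*m/j), clip 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(rank_pos, m)]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBhFdr:
    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_constant_vectors(self):
        assert bh_fdr([0.3])[0] == 0.3
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])

    def test_nan_propagates_and_shrinks_m(self):
        q = bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        # m = 2: q = min-step-up over [0.01*2/1, 0.04*2/2]
        np.testing.assert_allclose(q[[0, 2]], [0.02, 0.04])

    def test_q_at_least_p_and_order_invariant(self, rng):
        p = rng.random(200)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all()
        perm = rng.permutation(200)
        np.testing.assert_allclose(bh_fdr(p[perm]), q[perm])

    def test_matches_literal_oracle_random(self, rng):
        for _ in range(50):
            p = np.round(rng.random(rng.integers(1, 12)), 3)
            np.testing.assert_allclose(bh_fdr(p), _bh_oracle(p), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(500)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_fdr(p), ref, atol=1e-12)


def _boundary_dataset():
    m5 = [0.2, 0.1, 0.0, -0.1, -0.2]

    def around(center):
        return [center + d for d in m5]

    rows = {
        # clear male-biased SDE: means 9 vs 7
        "sde_male": {"T": (around(9.0), around(7.0))},
        # below the expression floor in both sexes despite tiny p
        "not_expressed": {"T": (around(6.60), around(6.64))},
        # exactly two-fold: log2 difference of exactly 1.0 fails the strict test
        "exact_twofold": {"T": (around(8.0), around(7.0))},
        # clear female-biased SDE
        "sde_female": {"T": (around(7.0), around(9.5))},
        # null filler
        "null_a": {"T": (around(8.0), around(8.0))},
        "null_b": {"T": (around(7.5), around(7.4))},
    }
    return make_dataset(rows)


class TestCallSde:
    def test_three_criteria_and_strict_boundaries(self):
        ds = _boundary_dataset()
        stats = call_sde_tissue(ds, "T")
        assert bool(stats.loc["sde_male", "sde"]) and stats.loc["sde_male", "bias"] == "male"
        assert bool(stats.loc["sde_female", "sde"]) and stats.loc["sde_female", "bias"] == "female"
        assert not stats.loc["not_expressed", "expressed"]
        assert not stats.loc["not_expressed", "sde"]
        assert stats.loc["exact_twofold", "log2_diff"] == pytest.approx(1.0)
        assert not stats.loc["exact_twofold", "sde"]
        assert stats.loc["null_a", "bias"] == "none"

    def test_expression_threshold_is_strict(self):
        ds = _boundary_dataset()
        stats = call_sde_tissue(ds, "T", SdeCriteria(expr_threshold=9.0))
        # mean exactly at the floor does not count as expressed
        assert not stats.loc["sde_male", "expressed_m"]

    def test_sex_label_swap_antisymmetry(self, demo_sim):
        ann = demo_sim.annotation.copy()
        ann["sex"] = ann["sex"].map({"M": "F", "F": "M"})
        ds = join_and_validate(demo_sim.matrix, ann)
        swapped = call_sde_tissue(ds, "Duodenum")
        orig = demo_sim.stats["Duodenum"]
        np.testing.assert_allclose(swapped["log2_diff"], -orig["log2_diff"], atol=1e-12)
        np.testing.assert_allclose(swapped["p_value"], orig["p_value"], atol=1e-12)
        np.testing.assert_allclose(swapped["q_value"], orig["q_value"], atol=1e-12)
        assert (swapped["sde"] == orig["sde"]).all()
        flipped = orig["bias"].map({"male": "female", "female": "male", "none": "none"})
        assert (swapped["bias"] == flipped).all()

    def test_q_never_below_p(self, demo_sim):
        for stats in demo_sim.stats.values():
            assert (stats["q_value"] >= stats["p_value"] - 1e-12).all()

    def test_bh_scope_expressed_restricts_universe(self, demo_sim):
        from dimorph.sde_calling import call_sde_tissue

        stats = call_sde_tissue(demo_sim.dataset, "Duodenum", bh_scope="expressed")
        assert stats.loc[~stats["expressed"], "q_value"].isna().all()
        assert not stats.loc[~stats["expressed"], "sde"].any()

    def test_unknown_tissue_error(self, demo_sim):
        with pytest.raises(KeyError):
            call_sde_tissue(demo_sim.dataset, "Gills")

    def test_all_tissues_requires_two_per_sex(self, demo_sim):
        drop = demo_sim.dataset.groups[("Brain", "F")][:4]
        ds = join_and_validate(
            demo_sim.matrix, demo_sim.annotation, exclude=drop, allow_small_groups=True
        )
        with pytest.raises(ValueError, match="Brain"):
            call_sde_all(ds)

    def test_disjoint_planted_effects_stay_disjoint(self):
        from dimorph import SimulationConfig, generate_dataset

        cfg = SimulationConfig(
            n_probesets=800,
            n_tissues=2,
            per_tissue_sde_rate={"Duodenum": 0.05, "Kidney": 0.05},
            shared_blocks=[],
            attenuation={},
            ubiquitous_female_exclusive=0,
            ubiquitous_male_exclusive=0,
            homolog_compensation_ratio=1.0,
            effect_min=2.5,
            seed=5,
        )
        matrix, ann, truth = generate_dataset(cfg)
        stats = call_sde_all(join_and_validate(matrix, ann))
        planted = truth.sde_true()
        # independently planted effects overlap at most rarely; calls follow
        called_a = set(stats["Duodenum"].index[stats["Duodenum"]["sde"]])
        called_b = set(stats["Kidney"].index[stats["Kidney"]["sde"]])
        planted_both = set(planted.index[planted.all(axis=1)])
        assert called_a & called_b <= planted_both | set()
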