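import numpy as np
import pandas as pd
import pytest

from dimorph import (
    breadth_statistics,
    build_profiles,
    distribution_summary,
    expression_summary,
    gene_profile,
    identify_ubiquitous_sde,
    per_tissue_incidence,
    tissue_count_distribution,
)
from dimorph.cross_tissue import profiles_from_incidence


def _incidence(rows, tissues):
    data = np.zeros((len(rows), len(tissues)), dtype=np.int8)
    for i, assign in enumerate(rows.values()):
        for t, sign in assign.items():
            data[i, tissues.index(t)] = sign
    return pd.DataFrame(data, index=pd.Index(rows.keys(), name="probeset_id"), columns=tissues)


TISSUES = ["Liver", "Kidney", "Duodenum", "Heart", "Brain", "Skin"]


@pytest.fixture()
def toy_profiles():
    rows = {
        "p_liver_m": {"Liver": 1},
        "p_kid_f": {"Kidney": -1},
        "p_heart_m": {"Heart": 1},
        "p_opposite": {"Kidney": 1, "Duodenum": 1, "Liver": -1},
        "p_silent": {},
    }
    return profiles_from_incidence(_incidence(rows, TISSUES))


class TestProfiles:
    def test_bias_classes(self, toy_profiles):
        cls = toy_profiles.bias_class
        assert cls["p_liver_m"] == "always_male"
        assert cls["p_kid_f"] == "always_female"
        assert cls["p_opposite"] == "opposite"
        assert cls["p_silent"] == "none"

    def test_counts_match_brute_force(self, rng):
        data = rng.choice([-1, 0, 1], size=(50, 6), p=[0.15, 0.7, 0.15]).astype(np.int8)
        inc = pd.DataFrame(
            data, index=[f"p{i}" for i in range(50)], columns=TISSUES
        )
        prof = profiles_from_incidence(inc)
        for i, pid in enumerate(inc.index):
            assert prof.n_sde[pid] == np.count_nonzero(data[i])

    def test_universe_mismatch_rejected(self, demo_sim):
        stats = dict(demo_sim.stats)
        stats["Liver"] = stats["Liver"].iloc[:-1]
        with pytest.raises(ValueError, match="universe"):
            build_profiles(stats)

    def test_bias_class_invariant_under_tissue_reordering(self, toy_profiles):
        inc = toy_profiles.bias[list(reversed(TISSUES))]
        reordered = profiles_from_incidence(inc)
        assert (reordered.bias_class == toy_profiles.bias_class).all()


class TestDistribution:
    def test_enumerated_toy(self):
        rows = {
            "a": {"Liver": 1},
            "b": {"Kidney": 1},
            "c": {"Heart": -1},
            "d": {"Liver": 1, "Kidney": -1},
        }
        dist = tissue_count_distribution(profiles_from_incidence(_incidence(rows, TISSUES)))
        assert dist.loc[1, "always_male"] == 2
        assert dist.loc[1, "always_female"] == 1
        assert pd.isna(dist.loc[1, "opposite"])
        assert dist.loc[1, "total"] == 3
        assert list(dist.loc[2]) == [0, 0, 1, 1]

    def test_empty_when_nothing_sde(self):
        prof = profiles_from_incidence(_incidence({"a": {}, "b": {}}, TISSUES))
        dist = tissue_count_distribution(prof)
        assert dist.empty
        summary = distribution_summary(dist)
        assert summary["n_sde_total"] == 0 and np.isnan(summary["frac_single"])

    def test_class_totals_conserved(self, demo_sim):
        dist = tissue_count_distribution(demo_sim.profiles)
        s = distribution_summary(dist)
        n_any = int((demo_sim.profiles.n_sde >= 1).sum())
        assert s["n_sde_total"] == n_any
        assert s["n_always_male"] + s["n_always_female"] + s["n_opposite"] == n_any


class TestUbiquitous:
    def test_majority_rule(self):
        rows = {"wide_f": {t: -1 for t in TISSUES[:4]}, "narrow": {"Liver": 1, "Kidney": 1}}
        prof = profiles_from_incidence(_incidence(rows, TISSUES))
        ub = identify_ubiquitous_sde(prof)  # needs > 3 of 6
        assert list(ub.index) == ["wide_f"]
        assert ub.loc["wide_f", "direction"] == "female"
        assert bool(ub.loc["wide_f", "consistent_bias"])

    def test_planted_exclusive_genes_found(self, demo_sim):
        ub = identify_ubiquitous_sde(demo_sim.profiles)
        labels = demo_sim.truth.labels.loc[ub.index]
        assert set(labels) <= {"ubiquitous_female", "ubiquitous_male"}
        # all six planted sex-exclusive probesets are recovered
        planted = demo_sim.truth.labels.isin(["ubiquitous_female", "ubiquitous_male"])
        assert set(ub.index) == set(demo_sim.truth.labels.index[planted])

    def test_empty_profiles(self):
        prof = profiles_from_incidence(_incidence({"a": {}}, TISSUES))
        assert identify_ubiquitous_sde(prof).empty


class TestIncidenceTable:
    def test_breadth_splits_and_exclusion(self):
        tissues = TISSUES
        rows = {
            "only_liver": {"Liver": 1},       # expressed only in liver
            "everywhere": {"Kidney": -1},      # expressed in all tissues
            "xist_like": {t: -1 for t in tissues},
        }
        inc = _incidence(rows, tissues)
        expressed = inc != 0
        expressed.loc["everywhere"] = True
        expressed.loc["xist_like"] = True
        prof = profiles_from_incidence(inc, expressed)
        table = per_tissue_incidence(prof, exclude=["xist_like"])
        liver = table.loc["Liver"]
        assert liver["n_sde_male"] == 1 and liver["n_single_tissue_male"] == 1
        kidney = table.loc["Kidney"]
        assert kidney["n_sde_female"] == 1 and kidney["n_ubiquitous_elsewhere_female"] == 1
        # the excluded probeset appears only in the exclusion column
        assert (table["n_excluded_ubiquitous_sde"] == 1).all()
        assert table["n_sde_total"].sum() == 2

    def test_multi_tissue_counted_once_per_tissue(self, demo_sim):
        table = per_tissue_incidence(demo_sim.profiles, exclude=[])
        distinct = int((demo_sim.profiles.n_sde >= 1).sum())
        assert table["n_sde_total"].sum() >= distinct

    def test_totals_match_raw_flags_minus_exclusions(self, demo_sim):
        ub = list(identify_ubiquitous_sde(demo_sim.profiles).index)
        table = per_tissue_incidence(demo_sim.profiles, exclude=ub)
        for tissue in demo_sim.profiles.tissues:
            raw = int(demo_sim.profiles.sde[tissue].sum())
            assert (
                table.loc[tissue, "n_sde_total"] + table.loc[tissue, "n_excluded_ubiquitous_sde"]
                == raw
            )


class TestBreadth:
    def test_enumerated_toy(self):
        tissues = TISSUES
        rows = {"ubiq_non_sde": {}, "single_sde": {"Liver": 1}}
        inc = _incidence(rows, tissues)
        expressed = inc != 0
        expressed.loc["ubiq_non_sde"] = True
        prof = profiles_from_incidence(inc, expressed)
        b = breadth_statistics(prof)
        assert b["frac_all_tissues_non_sde"] == 1.0
        assert b["frac_all_tissues_sde"] == 0.0
        assert b["frac_single_tissue_sde"] == 1.0

    def test_all_expressed_everywhere(self):
        rows = {"a": {"Liver": 1}, "b": {}}
        inc = _incidence(rows, TISSUES)
        expressed = inc.copy()
        expressed.loc[:, :] = 1
        prof = profiles_from_incidence(inc, expressed.astype(bool))
        b = breadth_statistics(prof)
        assert b["frac_single_tissue_sde"] == 0.0
        assert b["frac_single_tissue_non_sde"] == 0.0

    def test_fractions_are_probabilities(self, demo_sim):
        b = breadth_statistics(demo_sim.profiles)
        for v in b.values():
            assert np.isnan(v) or 0.0 <= v <= 1.0

    def test_expression_summary_arithmetic(self, demo_sim):
        s = expression_summary(demo_sim.profiles)
        assert s["pct_expressed"] == pytest.approx(100 * s["n_expressed"] / s["n_probesets"])
        assert s["pct_sde_of_expressed"] == pytest.approx(100 * s["n_sde"] / s["n_expressed"])


class TestGeneProfile:
    def test_female_exclusive_gene(self, demo_sim):
        pid = demo_sim.truth.labels.index[demo_sim.truth.labels == "ubiquitous_female"][0]
        prof = gene_profile(demo_sim.dataset, pid, all_stats=demo_sim.stats)
        assert len(prof) == 26
        assert (prof["mean_f"] > 6.65).all()
        assert (prof["mean_m"] < 6.65).all()
        assert prof.attrs["expr_threshold"] == 6.65

    def test_compensated_homolog_ratio(self, demo_sim):
        pid = demo_sim.truth.labels.index[demo_sim.truth.labels == "compensated_homolog"][0]
        prof = gene_profile(demo_sim.dataset, pid, all_stats=demo_sim.stats)
        # female-biased in every tissue, averaging ~1.7-fold
        diffs = prof["mean_f"] - prof["mean_m"]
        assert (diffs > 0).mean() > 0.9
        assert 2 ** diffs.mean() == pytest.approx(1.7, rel=0.15)

    def test_silent_probeset(self, demo_sim):
        silent = demo_sim.truth.expressed.sum(axis=1) == 0
        pid = demo_sim.truth.expressed.index[silent][0]
        prof = gene_profile(demo_sim.dataset, pid, all_stats=demo_sim.stats)
        assert not prof["sde"].any()

    def test_unknown_probeset(self, demo_sim):
        with pytest.raises(KeyError):
            gene_profile(demo_sim.dataset, "nope", all_stats=demo_sim.stats)
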