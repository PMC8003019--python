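"""Niche-association descriptive statistics."""

import math

import numpy as np
import pytest

from dtcfate import (
    NicheObservation,
    classify_niche,
    compare_all_categories,
    compare_groups,
    distance_profile,
    generate_niche_observations,
    per_animal_table,
    summarize,
)

SEED = 20260920


def _obs(dtc_id, subject, group, gp=50.0, vessel=30.0, bone=30.0, vtype="none"):
    return NicheObservation(dtc_id, subject, group, gp, vessel, bone, vtype)


class TestClassify:
    @pytest.mark.parametrize(
        "vessel,bone,expected",
        [
            (2.0, 50.0, "perivascular"),
            (50.0, 2.0, "endosteal"),
            (5.0, 5.0, "overlapping"),
            (30.0, 30.0, "neither"),
            (10.0, 10.0, "overlapping"),  # boundary: contact radius inclusive
        ],
    )
    def test_categories(self, vessel, bone, expected):
        obs = _obs("d1", "m1", "g", vessel=vessel, bone=bone)
        assert classify_niche(obs, contact_radius=10.0) == expected

    def test_missing_distance_is_an_error(self):
        obs = _obs("d1", "m1", "g", vessel=math.nan)
        with pytest.raises(ValueError):
            classify_niche(obs)


class TestSummarize:
    def test_one_animal_direct_counts(self):
        obs = [
            _obs("d1", "m1", "g", vessel=1.0, bone=50.0, vtype="H"),
            _obs("d2", "m1", "g", vessel=1.0, bone=50.0, vtype="L"),
            _obs("d3", "m1", "g", vessel=50.0, bone=1.0),
            _obs("d4", "m1", "g", vessel=1.0, bone=1.0, vtype="H"),
        ]
        summary = summarize(obs)["g"]
        assert summary.n_animals == 1
        assert summary.proportions["perivascular"] == (0.5, 0.0)
        assert summary.proportions["endosteal"] == (0.25, 0.0)
        assert summary.proportions["overlapping"] == (0.25, 0.0)
        assert sum(m for m, _ in summary.proportions.values()) == pytest.approx(1.0)

    def test_two_identical_animals_zero_sem(self):
        obs = []
        for m in ("m1", "m2"):
            obs += [
                _obs(f"{m}-d1", m, "g", vessel=1.0, bone=50.0),
                _obs(f"{m}-d2", m, "g", vessel=50.0, bone=1.0),
            ]
        summary = summarize(obs)["g"]
        assert summary.proportions["perivascular"] == (0.5, 0.0)

    def test_record_order_and_animal_duplication_invariance(self):
        obs = generate_niche_observations("outgrowth", 100, n_animals=3, seed=SEED)
        base = per_animal_table(obs).set_index("subject_id")["perivascular"]
        shuffled = per_animal_table(list(reversed(obs))).set_index("subject_id")["perivascular"]
        assert (base == shuffled).all()
        # duplicating every record of one animal leaves its proportions unchanged
        dup_subject = obs[0].subject_id
        duplicated = obs + [o for o in obs if o.subject_id == dup_subject]
        dup = per_animal_table(duplicated).set_index("subject_id")["perivascular"]
        assert dup[dup_subject] == pytest.approx(base[dup_subject])

    def test_invalid_records_excluded_with_log(self, caplog):
        obs = [
            _obs("d1", "m1", "g", vessel=1.0, bone=50.0),
            _obs("d2", "m1", "g", vessel=math.nan),
        ]
        with caplog.at_level("WARNING"):
            table = per_animal_table(obs)
        assert table["n_dtcs"].sum() == 1
        assert any("excluded" in r.message for r in caplog.records)

    def test_generator_proportions_recovered(self):
        obs = generate_niche_observations("outgrowth", 800, n_animals=5, seed=SEED)
        summary = summarize(obs)["outgrowth"]
        mean, sem = summary.proportions["perivascular"]
        assert abs(mean - 0.334) <= max(3 * sem, 0.02)


class TestCompareGroups:
    def test_identical_groups_p_one(self):
        obs = []
        for group in ("a", "b"):
            for m in ("m1", "m2", "m3"):
                obs += [
                    _obs(f"{group}-{m}-d1", f"{group}-{m}", group, vessel=1.0, bone=50.0),
                    _obs(f"{group}-{m}-d2", f"{group}-{m}", group, vessel=50.0, bone=1.0),
                ]
        result = compare_groups(obs, "perivascular")
        assert result.statistic == 0.0
        assert result.pvalue == pytest.approx(1.0)

    def test_two_tailed_p_symmetric_under_group_swap(self):
        obs = generate_niche_observations("outgrowth", 200, n_animals=5, seed=SEED)
        obs += generate_niche_observations("indolence", 200, n_animals=5, seed=SEED + 1)
        fwd = compare_groups(obs, "perivascular", group_a="outgrowth", group_b="indolence")
        rev = compare_groups(obs, "perivascular", group_a="indolence", group_b="outgrowth")
        assert fwd.pvalue == pytest.approx(rev.pvalue)
        assert fwd.statistic == pytest.approx(-rev.statistic)

    def test_detects_the_perivascular_contrast(self):
        obs = generate_niche_observations("outgrowth", 200, n_animals=5, seed=SEED)
        obs += generate_niche_observations("indolence", 200, n_animals=5, seed=SEED + 1)
        result = compare_groups(obs, "perivascular")
        assert result.pvalue < 0.05
        assert result.df == 8

    def test_too_few_animals_rejected(self):
        obs = [
            _obs("d1", "m1", "a", vessel=1.0),
            _obs("d2", "m2", "b", vessel=1.0),
        ]
        with pytest.raises(ValueError):
            compare_groups(obs, "perivascular")

    def test_holm_adjustment_is_at_least_raw_p(self):
        obs = generate_niche_observations("outgrowth", 200, n_animals=4, seed=SEED)
        obs += generate_niche_observations("indolence", 200, n_animals=4, seed=SEED + 1)
        table = compare_all_categories(obs)
        assert (table["pvalue_holm"] >= table["pvalue"] - 1e-12).all()
        assert set(table["category"]) == {"perivascular", "endosteal", "overlapping", "neither"}


class TestDistanceProfile:
    def test_counts_land_in_expected_bins(self):
        obs = [
            _obs("d1", "m1", "g", gp=5.0),
            _obs("d2", "m1", "g", gp=15.0),
            _obs("d3", "m1", "g", gp=195.0),
        ]
        profile = distance_profile(obs, bin_width=10.0)
        counts = profile.set_index("bin_left")["count"]
        assert counts[0.0] == 1 and counts[10.0] == 1 and counts[190.0] == 1
        assert counts.sum() == 3

    def test_distance_of_exactly_200_is_counted(self):
        obs = [_obs("d1", "m1", "g", gp=200.0)]
        profile = distance_profile(obs, bin_width=30.0)
        assert profile["count"].sum() == 1

    def test_empty_input_all_zero(self):
        profile = distance_profile([], bin_width=20.0)
        assert profile["count"].sum() == 0

    def test_nonpositive_bin_width_rejected(self):
        with pytest.raises(ValueError):
            distance_profile([], bin_width=0.0)

    def test_indolent_dtcs_sit_closer_to_growth_plate(self):
        out = generate_niche_observations("outgrowth", 2000, seed=SEED)
        ind = generate_niche_observations("indolence", 2000, seed=SEED + 1)
        med_out = np.median([o.distance_to_growth_plate for o in out])
        med_ind = np.median([o.distance_to_growth_plate for o in ind])
        assert med_ind < med_out
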