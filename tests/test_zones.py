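import numpy as np
import pytest

from okcrp import (ChangeProfile, MissingDataError, SubjectCPC, ZoneDefinition,
                   asymmetry_test, center_change, center_paracentral_correlation,
                   change_profile, cohort_cpc, cpc_ratio, location_tests,
                   max_relative_paracentral)
from okcrp.crp import PROFILE_POSITIONS, MeridianProfile
from okcrp.zones import RegionCPC


def make_delta(values, subject="s", meridian="horizontal"):
    return ChangeProfile(subject, meridian, PROFILE_POSITIONS.copy(),
                         np.asarray(values, dtype=float))


def delta_from_map(mapping, subject="s", meridian="horizontal", fill=0.0):
    vals = np.full(16, fill)
    for pos, v in mapping.items():
        vals[np.flatnonzero(np.isclose(PROFILE_POSITIONS, pos))[0]] = v
    return make_delta(vals, subject, meridian)


class TestZoneDefinition:
    def test_defaults_match_chord_definitions(self):
        z = ZoneDefinition()
        absx = np.abs(PROFILE_POSITIONS)
        assert (absx <= z.center_max).sum() == 2        # 1 mm chord
        assert (absx <= z.central_max).sum() == 8       # 4 mm chord
        para = (absx >= z.paracentral_min) & (absx <= z.paracentral_max)
        assert para.sum() == 8                          # 4 per side
        assert (para & (PROFILE_POSITIONS > 0)).sum() == 4

    def test_bad_ordering_rejected(self):
        with pytest.raises(ValueError):
            ZoneDefinition(center_max=3.0, central_max=2.0)

    def test_off_grid_boundary_rejected(self):
        with pytest.raises(ValueError):
            ZoneDefinition(center_max=0.3)


class TestChangeProfile:
    def test_identical_visits_give_zero(self):
        p = MeridianProfile("horizontal", PROFILE_POSITIONS.copy(),
                            np.linspace(41, 45, 16))
        d = change_profile(p, p, subject="a")
        assert np.all(d.delta_crp == 0)

    def test_signed_difference(self):
        pre = MeridianProfile("horizontal", PROFILE_POSITIONS.copy(),
                              np.full(16, 43.0))
        post = MeridianProfile("horizontal", PROFILE_POSITIONS.copy(),
                               np.full(16, 41.5))
        assert np.allclose(change_profile(pre, post).delta_crp, -1.5)

    def test_missing_propagates(self):
        a = np.full(16, 43.0)
        b = a.copy()
        b[4] = np.nan
        pre = MeridianProfile("horizontal", PROFILE_POSITIONS.copy(), a)
        post = MeridianProfile("horizontal", PROFILE_POSITIONS.copy(), b)
        assert np.isnan(change_profile(pre, post).delta_crp[4])

    def test_meridian_mismatch(self):
        h = MeridianProfile("horizontal", PROFILE_POSITIONS.copy(), np.zeros(16))
        v = MeridianProfile("vertical", PROFILE_POSITIONS.copy(), np.zeros(16))
        with pytest.raises(ValueError):
            change_profile(h, v)


class TestCenterChange:
    def test_mean_of_two_locations(self):
        assert center_change(delta_from_map({-0.5: -2.0, 0.5: -2.0})) == -2.0
        assert center_change(delta_from_map({-0.5: -1.5, 0.5: -2.5})) == -2.0

    def test_missing_center_is_error(self):
        d = delta_from_map({0.5: -2.0})
        d.delta_crp[7] = np.nan  # -0.5 mm
        with pytest.raises(MissingDataError):
            center_change(d)


class TestMaxRelativeParacentral:
    def test_arithmetic_example(self):
        d = delta_from_map({-0.5: -2.0, 0.5: -2.0,
                            2.5: 0.5, 3.0: 1.0, 3.5: 0.8, 4.0: -0.2})
        assert max_relative_paracentral(d, side="positive") == (3.0, 3.0)

    def test_tie_breaks_toward_smaller_offset(self):
        d = delta_from_map({-0.5: -2.0, 0.5: -2.0,
                            2.5: -2.0, 3.0: -2.0, 3.5: -2.0, 4.0: -2.0})
        assert max_relative_paracentral(d, side="positive") == (0.0, 2.5)

    def test_signed_maximum_can_be_negative(self):
        d = delta_from_map({-0.5: 0.0, 0.5: 0.0,
                            2.5: -1.0, 3.0: -0.8, 3.5: -1.2, 4.0: -1.5})
        rel, pos = max_relative_paracentral(d, side="positive")
        assert rel == -0.8 and pos == 3.0

    def test_dominates_single_locations(self):
        d = delta_from_map({-0.5: -1.0, 0.5: -1.0, 2.5: 0.3, 3.0: 2.0,
                            3.5: 0.1, 4.0: 0.9})
        rel, _ = max_relative_paracentral(d, side="positive")
        c = center_change(d)
        for pos in (2.5, 3.0, 3.5, 4.0):
            idx = np.flatnonzero(np.isclose(PROFILE_POSITIONS, pos))[0]
            assert rel >= d.delta_crp[idx] - c

    def test_all_missing_side_errors(self):
        d = delta_from_map({-0.5: -2.0, 0.5: -2.0}, fill=np.nan)
        with pytest.raises(MissingDataError):
            max_relative_paracentral(d, side="positive")


class TestCpcRatio:
    def test_simple_ratio(self):
        d = delta_from_map({-0.5: -2.0, 0.5: -2.0, 3.0: 2.0})
        cpc = cpc_ratio(d)
        assert cpc.regions["nasal"].cpc_ratio == pytest.approx(2.0)
        assert cpc.center_change == -2.0

    def test_printed_cohort_means_vertical(self):
        """Cohort-mean arithmetic: centre -2.16 D with a +4.52 D relative
        maximum gives a CPC ratio of 2.09 at two decimals."""
        d = delta_from_map({-0.5: -2.16, 0.5: -2.16, 3.0: -2.16 + 4.52},
                           meridian="vertical")
        cpc = cpc_ratio(d)
        assert round(cpc.regions["superior"].cpc_ratio, 2) == 2.09

    def test_non_responder_reported_missing(self):
        d = delta_from_map({-0.5: -0.1, 0.5: -0.1, 3.0: 1.0})
        with pytest.warns(UserWarning, match="non-responder"):
            cpc = cpc_ratio(d)
        assert cpc.regions["nasal"].cpc_ratio is None
        assert cpc.regions["nasal"].max_relative_change == pytest.approx(1.1)

    def test_scale_invariance(self):
        """Multiplying every change by k > 0 leaves the ratios unchanged."""
        base = delta_from_map({-0.5: -2.0, 0.5: -1.6, 2.5: 0.7, 3.0: 2.2,
                               3.5: 1.1, -3.0: 1.9, -2.5: 0.2})
        r1 = cpc_ratio(base)
        for k in (0.5, 3.0):
            scaled = make_delta(base.delta_crp * k)
            r2 = cpc_ratio(scaled)
            for name in r1.regions:
                assert r2.regions[name].cpc_ratio == pytest.approx(
                    r1.regions[name].cpc_ratio)

    def test_region_names_by_meridian(self):
        d = delta_from_map({-0.5: -2.0, 0.5: -2.0}, meridian="vertical")
        cpc = cpc_ratio(d)
        assert set(cpc.regions) == {"superior", "inferior"}


class TestCohortCpc:
    def _subject(self, sid, ratio, meridian="horizontal"):
        s = SubjectCPC(sid, meridian, -2.0)
        s.regions["nasal"] = RegionCPC("nasal", ratio * 2.0, 3.0, ratio)
        return s

    def test_mean_and_sd(self):
        subs = [self._subject(f"s{i}", 2.0) for i in range(3)]
        df = cohort_cpc(subs)
        row = df.iloc[0]
        assert row["mean"] == 2.0 and row["sd"] == 0.0 and row["n"] == 3

    def test_mean_of_ratios(self):
        subs = [self._subject("a", 1.5), self._subject("b", 2.5)]
        assert cohort_cpc(subs).iloc[0]["mean"] == pytest.approx(2.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            cohort_cpc([])


class TestLocationTests:
    def test_all_zero_not_significant(self):
        profiles = [make_delta(np.zeros(16), subject=f"s{i}") for i in range(8)]
        df = location_tests(profiles)
        assert not df.significant.any()
        assert (df.test == "degenerate").all()
        assert (df.p_raw == 1.0).all()

    def test_programmed_change_detected(self):
        rng = np.random.default_rng(0)
        profiles = []
        for i in range(19):
            vals = rng.normal(0, 0.15, 16)
            vals[7] += -2.0  # -0.5 mm
            vals[8] += -2.0  # +0.5 mm
            profiles.append(make_delta(vals, subject=f"s{i}"))
        df = location_tests(profiles).set_index("position_mm")
        assert df.loc[-0.5, "significant"] and df.loc[0.5, "significant"]
        assert not df.loc[4.0, "significant"]

    def test_bonferroni_is_sixteen_fold(self):
        rng = np.random.default_rng(1)
        profiles = [make_delta(rng.normal(0.3, 1.0, 16), subject=f"s{i}")
                    for i in range(10)]
        df = location_tests(profiles)
        tested = df[df.test != "insufficient-n"]
        assert np.allclose(tested.p_adj, np.minimum(1.0, tested.p_raw * 16))

    def test_insufficient_subjects_skipped(self):
        profiles = [make_delta(np.zeros(16)), make_delta(np.zeros(16))]
        df = location_tests(profiles)
        assert (df.test == "insufficient-n").all()
        assert not df.significant.any()


class TestAsymmetry:
    def test_symmetric_changes_not_significant(self):
        profiles = []
        rng = np.random.default_rng(2)
        for i in range(10):
            half = rng.normal(0.5, 0.3, 8)
            vals = np.concatenate([half[::-1], half])  # mirror symmetric
            profiles.append(make_delta(vals, subject=f"s{i}"))
        res = asymmetry_test(profiles)
        assert res["mean_difference"] == pytest.approx(0.0, abs=1e-12)
        assert res["p_value"] == 1.0
        assert res["positive_region"] == "nasal"

    def test_lateralised_changes_detected(self):
        rng = np.random.default_rng(3)
        profiles = []
        for i in range(19):
            vals = rng.normal(0, 0.2, 16)
            vals[7] = vals[8] = -2.0
            vals[PROFILE_POSITIONS == 3.0] += 2.5   # nasal annulus
            vals[PROFILE_POSITIONS == -3.0] += 1.5  # weaker temporal
            profiles.append(make_delta(vals, subject=f"s{i}"))
        res = asymmetry_test(profiles)
        assert res["mean_difference"] > 0.5
        assert res["p_value"] < 0.05

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            asymmetry_test([make_delta(np.zeros(16)), make_delta(np.zeros(16))])


class TestCorrelation:
    def _subjects(self, centers, rels):
        out = []
        for i, (c, r) in enumerate(zip(centers, rels)):
            s = SubjectCPC(f"s{i}", "horizontal", c)
            s.regions["nasal"] = RegionCPC("nasal", r, 3.0, r / abs(c))
            out.append(s)
        return out

    def test_exact_line_gives_minus_one(self):
        centers = np.array([-1.0, -2.0, -3.0, -2.5])
        rels = -2.2 * centers
        df = center_paracentral_correlation(self._subjects(centers, rels))
        assert df.iloc[0]["pearson_r"] == pytest.approx(-1.0)

    def test_zero_variance_errors(self):
        centers = np.array([-1.0, -2.0, -3.0])
        rels = np.full(3, 4.0)
        with pytest.raises(ValueError, match="zero variance"):
            center_paracentral_correlation(self._subjects(centers, rels))

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            center_paracentral_correlation(self._subjects([-1.0, -2.0], [2.0, 4.0]))
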