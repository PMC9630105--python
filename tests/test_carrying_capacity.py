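"""Allometric carrying-capacity model, minimum census and rarefaction."""
import itertools
import math

import numpy as np
import pytest

from paleotrophic import carrying_capacity as cc
from paleotrophic.carrying_capacity import (AllometryModel, LFARecord,
                                            SpeciesMass, damuth_constant,
                                            expected_richness, fit_thb_model,
                                            minimum_census, partition_biomass,
                                            predict_thb, propagate_ci,
                                            rarefy_richness, size_class,
                                            validate_model)
from paleotrophic.npp import Phase, PhaseTable


def community(*masses):
    return [SpeciesMass(taxon=f"sp{i}", W=float(w))
            for i, w in enumerate(masses)]


class TestFit:
    def test_two_exact_points_recovered(self):
        model = fit_thb_model([10.0, 100.0], [5.0, 50.0])
        assert model.slope == pytest.approx(1.0, abs=1e-9)
        assert model.intercept == pytest.approx(np.log10(0.5), abs=1e-9)

    def test_nonpositive_values_named(self):
        with pytest.raises(cc.CarryingCapacityError, match=r"\[1\]"):
            fit_thb_model([10.0, -1.0, 5.0], [1.0, 1.0, 1.0])

    def test_recovers_planted_coefficients(self, scenario):
        from paleotrophic.synthetic import gen_modern_density_dataset
        sites, truth = gen_modern_density_dataset(scenario, seed=7)
        thb = [sum(s.observed_density[sp.taxon] * sp.W for sp in s.species)
               for s in sites]
        model = fit_thb_model([s.npp for s in sites], thb)
        assert model.slope_ci[0] <= truth["slope"] <= model.slope_ci[1]
        assert model.slope == pytest.approx(truth["slope"], abs=0.05)

    def test_robust_fit_beats_ols_under_gross_outliers(self, scenario):
        from paleotrophic.synthetic import gen_modern_density_dataset
        scenario.allometry.n_sites = 200
        sites, truth = gen_modern_density_dataset(scenario, seed=13)
        npp = np.array([s.npp for s in sites])
        thb = np.array([sum(s.observed_density[sp.taxon] * sp.W
                            for sp in s.species) for s in sites])
        rng = np.random.default_rng(13)
        bad = rng.choice(len(thb), size=len(thb) // 10, replace=False)
        thb[bad] *= 10 ** rng.uniform(1.5, 2.5, size=len(bad))
        robust = fit_thb_model(npp, thb)
        ols = fit_thb_model(npp, thb, method="ols")
        assert abs(robust.slope - truth["slope"]) < \
            abs(ols.slope - truth["slope"])

    def test_coefficients_inside_own_ci_at_nominal_rate(self):
        """Planted (slope, intercept) fall inside the fit's 95% CI in at
        least 90 of 100 seeded replicates (n = 200 sites each)."""
        from paleotrophic.synthetic import (SyntheticScenario,
                                            gen_modern_density_dataset)
        hits = 0
        for seed in range(100):
            sc = SyntheticScenario(seed=seed)
            sc.allometry.n_sites = 200
            sites, truth = gen_modern_density_dataset(sc)
            thb = [sum(s.observed_density[sp.taxon] * sp.W
                       for sp in s.species) for s in sites]
            m = fit_thb_model([s.npp for s in sites], thb)
            if (m.slope_ci[0] <= truth["slope"] <= m.slope_ci[1]
                    and m.intercept_ci[0] <= truth["intercept"]
                    <= m.intercept_ci[1]):
                hits += 1
        assert hits >= 90


class TestPredict:
    def test_unit_npp_gives_ten_to_intercept(self):
        model = AllometryModel()
        assert predict_thb(1.0, model) == pytest.approx(10 ** -0.642,
                                                        rel=1e-9)
        assert predict_thb(1.0, model) == pytest.approx(0.228, abs=0.001)

    def test_log_linearity(self):
        model = AllometryModel()
        assert predict_thb(10.0, model) == pytest.approx(
            predict_thb(1.0, model) * 10 ** model.slope, rel=1e-9)

    def test_identity_model(self):
        model = AllometryModel(slope=1.0, intercept=0.0)
        assert predict_thb(7.3, model) == pytest.approx(7.3, rel=1e-12)

    def test_nonpositive_npp_rejected(self):
        with pytest.raises(cc.CarryingCapacityError):
            predict_thb(0.0, AllometryModel())


class TestDamuthPartition:
    def test_quarter_power_arithmetic(self):
        assert damuth_constant(100.0, community(16, 81)) == pytest.approx(20.0)

    def test_single_species(self):
        assert damuth_constant(42.0, community(1.0)) == pytest.approx(42.0)
        res = partition_biomass(42.0, community(2.0))
        assert res.B["sp0"] == pytest.approx(42.0)
        assert res.D["sp0"] == pytest.approx(21.0)

    def test_zero_thb(self):
        assert damuth_constant(0.0, community(5, 9)) == 0.0

    def test_hand_partition(self):
        res = partition_biomass(100.0, community(16, 81))
        assert res.B["sp0"] == pytest.approx(40.0)
        assert res.B["sp1"] == pytest.approx(60.0)
        assert res.D["sp0"] == pytest.approx(2.5)
        assert res.D["sp1"] == pytest.approx(20.0 / 27.0, rel=1e-9)

    def test_equal_masses_split_evenly(self):
        res = partition_biomass(90.0, community(50, 50, 50))
        assert all(b == pytest.approx(30.0) for b in res.B.values())

    def test_duplicate_taxa_rejected(self):
        sp = [SpeciesMass("same", 10.0), SpeciesMass("same", 20.0)]
        with pytest.raises(cc.CarryingCapacityError, match="duplicate"):
            partition_biomass(10.0, sp)

    def test_closure_on_random_communities(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(1, 20)
            masses = 10 ** rng.uniform(-1, 3.5, n)
            thb = 10 ** rng.uniform(-2, 3)
            res = partition_biomass(thb, community(*masses))
            assert sum(res.B.values()) == pytest.approx(thb, rel=1e-9)

    def test_scaling_exponents_exact(self):
        masses = 10 ** np.linspace(-1, 3, 12)
        res = partition_biomass(50.0, community(*masses))
        logW = np.log10(masses)
        slope_D = np.polyfit(logW, np.log10(list(res.D.values())), 1)[0]
        slope_B = np.polyfit(logW, np.log10(list(res.B.values())), 1)[0]
        assert slope_D == pytest.approx(-0.75, abs=1e-9)
        assert slope_B == pytest.approx(0.25, abs=1e-9)


class TestSizeClasses:
    @pytest.mark.parametrize("mass,cls", [
        (5.0, "small"), (9.999, "small"), (10.0, "medium"),
        (50.0, "medium"), (100.0, "medium_large"), (200.0, "medium_large"),
        (499.9, "medium_large"), (500.0, "large"), (800.0, "large")])
    def test_half_open_boundaries(self, mass, cls):
        assert size_class(mass) == cls

    def test_class_totals_partition_thb(self):
        res = partition_biomass(80.0, community(5, 50, 200, 800))
        totals = res.size_class_totals
        assert set(k for k, v in totals.items() if v > 0) == \
            {"small", "medium", "medium_large", "large"}
        assert sum(totals.values()) == pytest.approx(80.0, rel=1e-9)


class TestValidate:
    def _exact_sites(self, model, rng, n_sites=10, noise=0.0):
        from paleotrophic.carrying_capacity import ModernSiteRecord
        sites = []
        for i in range(n_sites):
            npp = 10 ** rng.uniform(1.8, 3.2)
            thb = predict_thb(npp, model)
            species = community(*(10 ** rng.uniform(0.2, 3, 6)))
            res = partition_biomass(thb, species)
            obs = {t: d * 10 ** rng.normal(0, noise)
                   for t, d in res.D.items()}
            sites.append(ModernSiteRecord(site=f"p{i}", npp=npp,
                                          species=species,
                                          observed_density=obs))
        return sites

    def test_noise_free_round_trip_r_is_one(self):
        model = AllometryModel()
        sites = self._exact_sites(model, np.random.default_rng(3))
        rep = validate_model(sites, model)
        for v in rep["per_site"].values():
            assert v["r"] == pytest.approx(1.0, abs=1e-9)
        assert rep["fraction_significant"] == 1.0

    def test_pooled_r_decreases_along_noise_ladder(self):
        model = AllometryModel()
        rs = []
        for noise in (0.0, 0.2, 0.6):
            sites = self._exact_sites(model, np.random.default_rng(4),
                                      noise=noise)
            rs.append(validate_model(sites, model)["pooled"]["r"])
        assert rs[0] > rs[1] > rs[2]

    def test_pairing_is_by_taxon(self):
        model = AllometryModel()
        sites = self._exact_sites(model, np.random.default_rng(5), n_sites=1)
        # shuffling the observed-density mapping across taxa breaks r = 1
        site = sites[0]
        taxa = list(site.observed_density)
        vals = [site.observed_density[t] for t in taxa]
        site.observed_density = dict(zip(taxa, vals[::-1]))
        rep = validate_model(sites, model)
        assert rep["per_site"][site.site]["r"] < 0.999

    def test_small_sites_skipped(self):
        model = AllometryModel()
        from paleotrophic.carrying_capacity import ModernSiteRecord
        site = ModernSiteRecord(site="tiny", npp=100.0,
                                species=community(10, 20),
                                observed_density={"sp0": 1.0, "sp1": 0.5})
        rep = validate_model([site], model)
        assert rep["skipped_sites"] == ["tiny"]


class TestMinimumCensus:
    phases = PhaseTable([Phase("GS-12", "stadial", 44.23, 43.29),
                         Phase("GI-11", "interstadial", 43.29, 42.19),
                         Phase("GS-11", "stadial", 42.19, 41.41)])

    def test_range_overlap_rule(self):
        # dated within GI-11 but the 95.4% range spans GS-12 through GS-11
        lfas = [LFARecord("l1", "cervus", "Eurosiberian",
                          lower=41500.0, upper=44000.0)]
        out = minimum_census(lfas, self.phases)
        assert set(p for (_, p) in out) == {"GS-12", "GI-11", "GS-11"}

    def test_disjoint_ranges_never_comember(self):
        lfas = [LFARecord("l1", "a", "R", lower=43500.0, upper=44000.0),
                LFARecord("l2", "b", "R", lower=41500.0, upper=42000.0)]
        out = minimum_census(lfas, self.phases)
        for pc in out.values():
            assert not {"a", "b"} <= set(pc.species)

    def test_single_lfa_uses_own_interval(self):
        lfas = [LFARecord("l1", "a", "R", lower=43000.0, upper=43100.0)]
        out = minimum_census(lfas, self.phases)
        assert list(out) == [("R", "GI-11")]
        assert out[("R", "GI-11")].provenance["a"] == ["l1"]

    def test_species_range_pools_across_lfas(self):
        lfas = [LFARecord("l1", "a", "R", lower=43500.0, upper=44000.0),
                LFARecord("l2", "a", "R", lower=41500.0, upper=42000.0)]
        out = minimum_census(lfas, self.phases)
        # pooled range 41500..44000 overlaps all three phases
        assert set(p for (_, p) in out) == {"GS-12", "GI-11", "GS-11"}


class TestRarefaction:
    def test_saturated_matrix_constant(self):
        inc = np.ones((6, 4), dtype=int)
        for h in range(1, 7):
            assert expected_richness(inc, h) == pytest.approx(4.0)
        assert expected_richness(inc, 100) == pytest.approx(4.0)

    def test_endpoint_identity(self):
        rng = np.random.default_rng(8)
        inc = (rng.random((7, 9)) < 0.4).astype(int)
        s_obs = int((inc.sum(axis=0) > 0).sum())
        assert expected_richness(inc, 7) == pytest.approx(float(s_obs))

    def test_interpolation_matches_exhaustive_subsets(self):
        rng = np.random.default_rng(9)
        for T in (2, 4, 5):
            inc = (rng.random((T, 5)) < 0.5).astype(int)
            for h in range(1, T + 1):
                brute = np.mean([
                    (inc[list(rows)].sum(axis=0) > 0).sum()
                    for rows in itertools.combinations(range(T), h)])
                assert expected_richness(inc, h) == pytest.approx(
                    brute, abs=1e-9)

    def test_bootstrap_ci_brackets_estimate_and_is_seeded(self):
        rng = np.random.default_rng(10)
        inc = (rng.random((12, 8)) < 0.4).astype(int)
        a = rarefy_richness(inc, target=100, n_boot=100, seed=3)
        b = rarefy_richness(inc, target=100, n_boot=100, seed=3)
        assert a == b
        assert a["ci95"][0] <= a["expected"] * 1.5
        assert a["expected"] >= a["observed"] - 1e-9

    def test_bad_target_rejected(self):
        with pytest.raises(cc.CarryingCapacityError):
            rarefy_richness(np.ones((3, 2)), target=0)


class TestPropagateCI:
    def _fitted_model(self):
        rng = np.random.default_rng(11)
        npp = 10 ** rng.uniform(1.5, 3.5, 80)
        thb = 10 ** (1.4 * np.log10(npp) - 0.6 + rng.normal(0, 0.1, 80))
        return fit_thb_model(npp, thb)

    def test_zero_covariance_collapses_to_point(self):
        model = AllometryModel(cov=np.zeros((2, 2)), resid_scale=0.0)
        ci = propagate_ci(model, 100.0, community(10, 200))
        assert ci.lower.THB == pytest.approx(ci.point.THB, rel=1e-12)
        assert ci.upper.THB == pytest.approx(ci.point.THB, rel=1e-12)

    def test_endpoints_map_monotonically(self):
        ci = propagate_ci(self._fitted_model(), 150.0, community(5, 50, 700))
        for taxon in ci.point.B:
            assert ci.lower.B[taxon] <= ci.point.B[taxon] <= ci.upper.B[taxon]
            assert ci.lower.D[taxon] <= ci.point.D[taxon] <= ci.upper.D[taxon]

    def test_class_band_is_linear_image_of_thb_band(self):
        model = self._fitted_model()
        species = community(5, 50, 700)
        ci = propagate_ci(model, 150.0, species)
        _, (lo, hi) = predict_thb(150.0, model, with_ci=True)
        for klass, v in ci.point.size_class_totals.items():
            if v == 0:
                continue
            share = v / ci.point.THB
            assert ci.lower.size_class_totals[klass] == pytest.approx(
                share * lo, rel=1e-9)
            assert ci.upper.size_class_totals[klass] == pytest.approx(
                share * hi, rel=1e-9)

    def test_missing_covariance_rejected(self):
        with pytest.raises(cc.CarryingCapacityError):
            propagate_ci(AllometryModel(), 100.0, community(10))
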