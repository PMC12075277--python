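"""Synthetic cohort generator: determinism, defaults, statistical structure."""

import numpy as np
import pandas as pd
import pytest

from cartmap import (
    default_spec,
    fit_biphasic,
    generate_cohort,
    hertz_equilibrium_deflection,
    ligament_cartilage_correlation,
    records_with_truth_fits,
)
from cartmap.stats import GROUPS
from cartmap.synthetic import LigamentParams


class TestDefaults:
    def test_group_vocabulary(self):
        spec = default_spec()
        assert set(g for g, _, _ in spec.cell_means) == set(GROUPS)
        assert GROUPS == ("younger_healthy_early", "elder_healthy_early",
                          "advanced_oa")

    def test_advanced_volar_ulnar_metacarpal_is_thinnest(self):
        spec = default_spec()
        cell = spec.cell_means[("advanced_oa", "metacarpal", "VU")]
        assert cell.thickness_mm == pytest.approx(0.25)

    def test_overall_group_modulus_means(self):
        spec = default_spec()
        for group, expected in [("younger_healthy_early", 0.45),
                                ("elder_healthy_early", 0.41),
                                ("advanced_oa", 0.66)]:
            cells = [c.e_mpa for (g, _, _), c in spec.cell_means.items()
                     if g == group]
            assert np.mean(cells) == pytest.approx(expected, abs=1e-9)

    def test_overall_group_porosity_means(self):
        spec = default_spec()
        for group, expected in [("younger_healthy_early", 0.76),
                                ("elder_healthy_early", 0.80),
                                ("advanced_oa", 0.82)]:
            cells = [c.porosity for (g, _, _), c in spec.cell_means.items()
                     if g == group]
            assert np.mean(cells) == pytest.approx(expected, abs=1e-9)


class TestDeterminism:
    def test_same_seed_reproduces_cohort_exactly(self):
        c1 = generate_cohort(default_spec(seed=11, n_donors_per_group=2))
        c2 = generate_cohort(default_spec(seed=11, n_donors_per_group=2))
        pd.testing.assert_frame_equal(c1.truth, c2.truth, check_exact=True)
        key = next(iter(c1.curves))
        np.testing.assert_array_equal(c1.curves[key].deformation_um,
                                      c2.curves[key].deformation_um)

    def test_growing_the_cohort_keeps_existing_donors(self):
        small = generate_cohort(default_spec(seed=11, n_donors_per_group=2),
                                curves=False).truth
        large = generate_cohort(default_spec(seed=11, n_donors_per_group=4),
                                curves=False).truth
        shared = large[large.donor_id.isin(small.donor_id.unique())]
        pd.testing.assert_frame_equal(
            small.reset_index(drop=True),
            shared.sort_index().reset_index(drop=True), check_exact=True)

    def test_different_seeds_differ(self):
        t1 = generate_cohort(default_spec(seed=1, n_donors_per_group=1),
                             curves=False).truth
        t2 = generate_cohort(default_spec(seed=2, n_donors_per_group=1),
                             curves=False).truth
        assert not np.allclose(t1.e_mpa, t2.e_mpa)


class TestStatisticalStructure:
    def test_noiseless_curves_round_trip_through_the_fitter(self):
        cohort = generate_cohort(default_spec(seed=4, n_donors_per_group=1,
                                              noise_sd_um=0.0))
        truth = cohort.truth.set_index(["donor_id", "bone", "region"])
        for (donor, bone, region), curve in cohort.curves.items():
            row = truth.loc[(donor, bone, region)]
            fit = fit_biphasic(curve, float(row["thickness_mm"]))
            assert fit.converged
            assert fit.eq_modulus_mpa == pytest.approx(row["e_mpa"], rel=0.005)

    def test_healthy_equilibrium_deformations_mostly_in_instrument_window(self):
        # large cohort so the check probes the generating distribution
        cohort = generate_cohort(default_spec(seed=0, n_donors_per_group=20),
                                 curves=False)
        healthy = cohort.truth[cohort.truth.group != "advanced_oa"]
        d_eq = np.array([hertz_equilibrium_deflection(5000.0, 0.5, e)
                         for e in healthy.e_mpa])
        assert np.mean((d_eq >= 50.0) & (d_eq <= 80.0)) >= 0.80

    def test_advanced_group_thinner_and_stiffer_in_volar_ulnar_metacarpal(self):
        truth = generate_cohort(default_spec(seed=8), curves=False).truth
        vu_mc = truth[(truth.bone == "metacarpal") & (truth.region == "VU")]
        adv = vu_mc[vu_mc.group == "advanced_oa"]
        young = vu_mc[vu_mc.group == "younger_healthy_early"]
        assert adv.thickness_mm.mean() < young.thickness_mm.mean()
        assert adv.e_mpa.mean() > young.e_mpa.mean()

    def test_donor_intercept_sd_recovered_from_large_cohort(self):
        spec = default_spec(seed=0, n_donors_per_group=200)
        truth = generate_cohort(spec, curves=False).truth
        young = truth[truth.group == "younger_healthy_early"].copy()
        cell_mean = {(b, r): c.e_mpa for (g, b, r), c in spec.cell_means.items()
                     if g == "younger_healthy_early"}
        young["dev"] = young.e_mpa - [cell_mean[(b, r)] for b, r in
                                      zip(young.bone, young.region)]
        donor_means = young.groupby("donor_id")["dev"].mean()
        within_var = young.groupby("donor_id")["dev"].var(ddof=1).mean()
        n_per_donor = 12
        donor_var = donor_means.var(ddof=1) - within_var / n_per_donor
        assert np.sqrt(donor_var) == pytest.approx(spec.donor_sd_e_mpa, rel=0.10)

    @pytest.mark.parametrize("rho", [-0.8, 0.0, 0.8])
    def test_imposed_ligament_modulus_correlation_recovered(self, rho):
        n_seeds = 40
        hits = 0
        for seed in range(n_seeds):
            spec = default_spec(seed=seed, n_donors_per_group=12)
            lig = dict(spec.ligament_params)
            lig["advanced_oa"] = LigamentParams(34.0, 10.0, rho=rho,
                                                volar_e_donor_sd_mpa=0.25)
            spec = type(spec)(**{**spec.__dict__, "ligament_params": lig})
            cohort = generate_cohort(spec, curves=False)
            res = ligament_cartilage_correlation(
                records_with_truth_fits(cohort), cohort.ligaments,
                "advanced_oa", "trapezium", "eq_modulus_mpa")
            if rho == 0.0:
                hits += abs(res.r) < 0.5
            else:
                hits += (res.r < 0) if rho < 0 else (res.r > 0)
        threshold = 0.80 if rho == 0.0 else 0.90
        assert hits / n_seeds >= threshold

    def test_gravimetry_is_consistent_with_truth_porosity(self):
        from cartmap import porosity
        cohort = generate_cohort(default_spec(seed=6, n_donors_per_group=1),
                                 curves=False)
        truth = cohort.truth.set_index(["donor_id", "bone", "region"])
        for rec in cohort.records:
            row = truth.loc[(rec.donor_id, rec.bone, rec.region)]
            assert porosity(rec.gravimetry) == pytest.approx(
                row["porosity"], rel=1e-9)
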