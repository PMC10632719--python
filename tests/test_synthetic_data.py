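"""Generator fidelity: design counts, clock invertibility, planted structure."""

import numpy as np
import pandas as pd
import pytest

from admixclock import ancestry_scan, clock_engine as ce, synthetic_data as sd


class TestGenCohort:
    def test_design_counts_match_study_layout(self, preset_cohort):
        c = preset_cohort
        by_group = c.groupby("population")
        assert by_group.size().to_dict() == {"groupA": 24, "groupB": 24}
        assert c.groupby(["population", "sex"]).size().eq(12).all()
        assert by_group["infected"].sum().to_dict() == {"groupA": 12, "groupB": 12}
        rural = c[c["paraje"] == "rural"].groupby("population").size()
        assert rural.get("groupA", 0) == 20 and rural.get("groupB", 0) == 0
        # infection balanced by sex
        inf_by_sex = c.groupby(["population", "sex"])["infected"].sum()
        assert inf_by_sex.eq(6).all()

    def test_ages_truncated_and_plausible(self, preset_cohort):
        ages = preset_cohort["age"]
        assert (ages >= 18.0).all()
        assert 25 < ages.mean() < 55

    def test_empty_cohort(self):
        spec = sd.CohortSpec(n_per_group=0, n_female_per_group=0)
        assert len(sd.gen_cohort(spec, seed=0)) == 0

    def test_deterministic_per_seed(self):
        a = sd.gen_cohort(seed=9)
        b = sd.gen_cohort(seed=9)
        pd.testing.assert_frame_equal(a, b)
        c = sd.gen_cohort(seed=10)
        assert not a["age"].equals(c["age"])

    def test_infeasible_infected_count_raises(self):
        spec = sd.CohortSpec(n_per_group=5, n_female_per_group=2,
                             infected_fraction=0.3)
        with pytest.raises(ValueError, match="integer"):
            sd.gen_cohort(spec, seed=0)

    def test_cell_fractions_form_simplex(self, preset_cohort):
        cols = [f"cell_{c}" for c in sd.CELL_TYPES]
        sums = preset_cohort[cols].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)


class TestGenClock:
    def test_single_cpg_clock_is_invertible(self):
        clock = sd.gen_clock(1, seed=1, name="one")
        targets = np.array([25.0, 50.0, 75.0])
        betas = sd.clock_design_betas(clock, targets)
        score = clock.intercept + clock.coefficients.to_numpy() @ betas
        np.testing.assert_allclose(score, targets, atol=1e-10)

    def test_row_count_convention(self):
        assert len(sd.gen_clock(71, seed=2, name="h71").coefficients) == 71

    @pytest.mark.parametrize("transform", ["identity", "horvath"])
    def test_invert_then_apply_round_trip(self, transform, rng):
        clock = sd.gen_clock(40, transform=transform, seed=3, name=f"rt_{transform}")
        targets = rng.uniform(18.0, 90.0, size=12)
        betas = sd.clock_design_betas(clock, targets)
        assert betas.min() >= 0.0 and betas.max() <= 1.0
        bdf = pd.DataFrame(betas, index=clock.coefficients.index,
                           columns=[f"s{i}" for i in range(12)])
        est = ce.clock_estimate(bdf, clock)
        np.testing.assert_allclose(est.to_numpy(), targets, atol=0.1)

    def test_unreachable_target_raises(self):
        clock = sd.gen_clock(10, seed=4, name="small")
        with pytest.raises(ValueError, match="rescale"):
            sd.clock_design_betas(clock, np.array([500.0]))


class TestPlantGroupMedians:
    def test_medians_and_orthogonality(self, rng):
        ages = rng.uniform(20, 70, size=48)
        group_a = np.arange(48) < 24
        r = sd.plant_group_medians(ages, group_a, 0.87, -1.67, 3.0, rng)
        assert np.median(r[group_a]) == pytest.approx(0.87, abs=1e-6)
        assert np.median(r[~group_a]) == pytest.approx(-1.67, abs=1e-6)
        assert abs(r.mean()) < 1e-9
        centered = ages - ages.mean()
        assert abs(r @ centered) / np.linalg.norm(centered) < 1e-9


class TestGenBetas:
    def test_zero_noise_recovers_chronological_age(self, preset_cohort):
        clocks = [sd.gen_clock(30, seed=5, name="k1"),
                  sd.gen_clock(25, transform="horvath", seed=6, name="k2")]
        betas = sd.gen_betas(preset_cohort, clocks, noise_sd=0.0, seed=7)
        for clock in clocks:
            est = ce.clock_estimate(betas, clock)
            err = np.abs(est.to_numpy() - preset_cohort["age"].to_numpy()).max()
            assert err < 0.1

    def test_betas_in_unit_interval(self, preset_bundle):
        vals = preset_bundle["betas"].to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_planted_group_medians_recovered(self, preset_bundle):
        est = preset_bundle["est"]
        groups = preset_bundle["groups"]
        med = est.groupby(groups).median()
        for name, (m_a, m_b) in preset_bundle["spec"].planted_accel_shifts.items():
            assert med.loc["groupA", name] == pytest.approx(m_a, abs=0.3)
            assert med.loc["groupB", name] == pytest.approx(m_b, abs=0.3)


class TestGenAdmixedGenotypes:
    def test_mean_frequency_near_global_fraction_without_excess(self):
        spec = sd.AdmixtureSpec(enriched_region=None)
        _, calls, _, truth = sd.gen_admixed_genotypes(spec, 48, seed=1,
                                                      return_posteriors=False)
        assert len(truth) == 0
        f = ancestry_scan.ancestry_frequency(calls, "AMR")
        # binomial SE of the genome-wide mean over 96 haplotypes x n_snps,
        # inflated for tract autocorrelation by the ~30-SNP tract length
        se = np.sqrt(0.55 * 0.45 / 96 / spec.n_snps * 30)
        assert abs(f.mean() - spec.global_amr_fraction) < 4 * se

    def test_fst_to_zero_panels_converge(self):
        spec = sd.AdmixtureSpec(n_snps=400, n_chroms=2, fst=1e-4,
                                enriched_region=None)
        g, calls, _, _ = sd.gen_admixed_genotypes(spec, 20, seed=2,
                                                  return_posteriors=False)
        # with no divergence the dosage mean cannot depend on local ancestry
        f_amr = ancestry_scan.ancestry_frequency(calls, "AMR").to_numpy()
        dose = g.dosages.mean(axis=0).to_numpy() / 2.0
        r = np.corrcoef(f_amr, dose)[0, 1]
        assert abs(r) < 0.2

    def test_planted_region_raises_local_frequency(self):
        spec = sd.AdmixtureSpec()
        _, calls, _, truth = sd.gen_admixed_genotypes(spec, 48, seed=3,
                                                      return_posteriors=False)
        f = ancestry_scan.ancestry_frequency(calls, "AMR")
        reg = truth.iloc[0]
        inside = calls.snps[(calls.snps["chrom"] == reg["chrom"])
                            & (calls.snps["pos"] >= reg["start"])
                            & (calls.snps["pos"] <= reg["end"])]["snp"]
        outside = calls.snps.loc[~calls.snps["snp"].isin(set(inside)), "snp"]
        assert f.loc[inside].mean() > f.loc[outside].mean() + 0.15

    def test_excess_above_one_rejected(self):
        spec = sd.AdmixtureSpec(global_amr_fraction=0.9,
                                enriched_region=("chr1", 10, 30, 0.25))
        with pytest.raises(ValueError, match="above 1"):
            spec.validate()

    def test_posterior_table_collapses_to_generated_calls(self):
        spec = sd.AdmixtureSpec(n_snps=60, n_chroms=2, enriched_region=None)
        _, calls, post, _ = sd.gen_admixed_genotypes(spec, 4, seed=4)
        collapsed = ancestry_scan.collapse_posteriors(post, threshold=0.9)
        pd.testing.assert_frame_equal(collapsed.calls, calls.calls)

    def test_deterministic_per_seed(self):
        spec = sd.AdmixtureSpec(n_snps=100, n_chroms=2, enriched_region=None)
        g1, c1, _, _ = sd.gen_admixed_genotypes(spec, 6, seed=5, return_posteriors=False)
        g2, c2, _, _ = sd.gen_admixed_genotypes(spec, 6, seed=5, return_posteriors=False)
        pd.testing.assert_frame_equal(g1.dosages, g2.dosages)
        pd.testing.assert_frame_equal(c1.calls, c2.calls)


class TestGenRelatedness:
    def test_no_planted_pairs_all_low(self, preset_cohort):
        kin, f = sd.gen_relatedness(preset_cohort, n_related_pairs=0, seed=6)
        assert (kin["pihat"] < 0.05).all()
        assert len(kin) == 48 * 47 // 2

    def test_planted_pairs_exceed_threshold(self, preset_cohort):
        kin, _ = sd.gen_relatedness(preset_cohort, n_related_pairs=3, seed=7)
        assert (kin["pihat"] > 0.25).sum() == 3

    def test_inbreeding_band(self, preset_cohort):
        _, f = sd.gen_relatedness(preset_cohort, n_inbred=6, seed=8)
        assert ((f >= 0.05) & (f <= 0.15)).sum() == 6
        assert (f < 0.05).sum() == len(f) - 6

    def test_deterministic(self, preset_cohort):
        kin1, f1 = sd.gen_relatedness(preset_cohort, seed=9)
        kin2, f2 = sd.gen_relatedness(preset_cohort, seed=9)
        pd.testing.assert_frame_equal(kin1, kin2)
        pd.testing.assert_series_equal(f1, f2)

    def test_too_many_pairs_rejected(self, preset_cohort):
        with pytest.raises(ValueError, match="pairs"):
            sd.gen_relatedness(preset_cohort, n_related_pairs=10_000, seed=0)


@pytest.fixture(scope="module")
def geno_truth():
    spec = sd.AdmixtureSpec()
    g, _, _, truth = sd.gen_admixed_genotypes(spec, 24, seed=10,
                                              return_posteriors=False)
    snps = g.snps
    reg = truth.iloc[0]
    inside = snps[(snps["chrom"] == reg["chrom"]) & (snps["pos"] >= reg["start"])
                  & (snps["pos"] <= reg["end"])]["snp"]
    return g, truth, list(inside)


class TestGenGwasCatalog:

    def test_causal_effect_is_exact(self, geno_truth):
        g, truth, inside = geno_truth
        causal = inside[len(inside) // 2]
        cat = sd.gen_gwas_catalog(truth, g, causal, effect=0.29, seed=11)
        assert cat.loc[cat["snp"] == causal, "effect_a1"].iloc[0] == 0.29

    def test_wald_p_matches_two_sided_normal(self, geno_truth):
        from scipy import stats
        g, truth, inside = geno_truth
        cat = sd.gen_gwas_catalog(truth, g, inside[0], effect=0.29, seed=12)
        expected = 2.0 * stats.norm.sf(np.abs(cat["effect_a1"] / cat["se"]))
        np.testing.assert_allclose(cat["p"].to_numpy(),
                                   np.clip(expected, 1e-300, 1), rtol=1e-9)

    def test_null_effects_rarely_significant(self, geno_truth):
        g, truth, inside = geno_truth
        causal = inside[0]
        rates = []
        for s in range(20):
            cat = sd.gen_gwas_catalog(truth, g, causal, effect=0.0, seed=s)
            rates.append((cat["p"] < 0.01).mean())
        assert np.mean(rates) < 0.03  # ~1% by chance

    def test_causal_outside_regions_rejected(self, geno_truth):
        g, truth, _ = geno_truth
        outside = g.snps.loc[~g.snps["chrom"].eq(truth.iloc[0]["chrom"]), "snp"].iloc[0]
        with pytest.raises(ValueError, match="outside"):
            sd.gen_gwas_catalog(truth, g, outside, seed=13)
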