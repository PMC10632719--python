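"""Posterior collapse, frequency computation, Z-scan and region calling."""

import numpy as np
import pandas as pd
import pytest

from admixclock import ancestry_scan as asc
from admixclock import synthetic_data as sd
from admixclock.io_formats import LocalAncestryCalls, SchemaError


def make_calls(label_rows, chrom="chr1"):
    """label_rows: list of per-SNP lists of haplotype labels."""
    n_snps = len(label_rows)
    n_haps = len(label_rows[0])
    snps = pd.DataFrame({"chrom": [chrom] * n_snps,
                         "pos": np.arange(1, n_snps + 1) * 1000,
                         "snp": [f"rs{i}" for i in range(n_snps)]})
    haps = [f"s{i // 2}_{'AB'[i % 2]}" for i in range(n_haps)]
    calls = pd.DataFrame(label_rows, index=snps["snp"], columns=haps)
    calls.index.name = None
    return LocalAncestryCalls(snps, calls)


class TestCollapsePosteriors:
    def _post(self, rows):
        """rows: (snp, hap, ancestry, posterior); complements auto-added."""
        recs = []
        for i, (snp, hap, anc, p) in enumerate(rows):
            pos = int(snp[2:]) * 1000 + 1000
            other = "EUR" if anc == "AMR" else "AMR"
            recs.append({"chrom": "chr1", "pos": pos, "snp": snp,
                         "haplotype": hap, "ancestry": anc, "posterior": p})
            recs.append({"chrom": "chr1", "pos": pos, "snp": snp,
                         "haplotype": hap, "ancestry": other, "posterior": 1 - p})
        return pd.DataFrame(recs)

    def test_confident_posterior_assigned(self):
        post = self._post([("rs0", "s0_A", "AMR", 0.95)])
        calls = asc.collapse_posteriors(post)
        assert calls.calls.loc["rs0", "s0_A"] == "AMR"

    def test_boundary_point_nine_is_unknown(self):
        post = self._post([("rs0", "s0_A", "AMR", 0.9)])
        calls = asc.collapse_posteriors(post)
        assert calls.calls.loc["rs0", "s0_A"] == "UNK"

    def test_matches_oracle_on_mixed_table(self, rng):
        rows = []
        for i in range(50):
            for h in ("s0_A", "s0_B", "s1_A", "s1_B"):
                anc = "AMR" if rng.random() < 0.5 else "EUR"
                rows.append((f"rs{i}", h, anc, float(rng.uniform(0.5, 1.0))))
        post = self._post(rows)
        calls = asc.collapse_posteriors(post, threshold=0.9)
        for snp, hap, anc, p in rows:
            expected = anc if p > 0.9 else "UNK"
            assert calls.calls.loc[snp, hap] == expected

    def test_broken_simplex_rejected_with_coordinates(self):
        post = self._post([("rs0", "s0_A", "AMR", 0.95)])
        post.loc[0, "posterior"] = 0.8  # now sums to 0.85
        with pytest.raises(SchemaError, match="rs0.*s0_A"):
            asc.collapse_posteriors(post)


class TestAncestryFrequency:
    def test_unknowns_excluded_from_denominator(self):
        calls = make_calls([["AMR", "AMR", "EUR", "UNK"]])
        f = asc.ancestry_frequency(calls, "AMR")
        assert f.iloc[0] == pytest.approx(2 / 3)

    def test_all_same_ancestry_is_one(self):
        calls = make_calls([["AMR"] * 6])
        assert asc.ancestry_frequency(calls, "AMR").iloc[0] == 1.0

    def test_hand_grid_matches_count_oracle(self, rng):
        labels = ["AMR", "EUR", "UNK"]
        grid = [[labels[rng.integers(3)] for _ in range(6)] for _ in range(5)]
        calls = make_calls(grid)
        f = asc.ancestry_frequency(calls, "AMR")
        for i, row in enumerate(grid):
            known = [x for x in row if x != "UNK"]
            want = np.nan if not known else row.count("AMR") / len(known)
            if np.isnan(want):
                assert np.isnan(f.iloc[i])
            else:
                assert f.iloc[i] == pytest.approx(want)

    def test_all_unknown_snp_masked(self):
        calls = make_calls([["UNK"] * 4, ["AMR", "EUR", "AMR", "EUR"]])
        f = asc.ancestry_frequency(calls, "AMR")
        assert np.isnan(f.iloc[0]) and f.iloc[1] == pytest.approx(0.5)


class TestZscan:
    def test_hand_arithmetic_with_sample_sd(self):
        f = pd.Series([0.5, 0.5, 0.5, 0.9])
        scan = asc.zscan(f)
        assert scan.attrs["mu"] == pytest.approx(0.6)
        assert scan.attrs["sigma"] == pytest.approx(0.2)
        np.testing.assert_allclose(scan["z"], [-0.5, -0.5, -0.5, 1.5], atol=1e-12)

    def test_printed_z_p_pair_consistency(self):
        from scipy import stats
        p = 2.0 * stats.norm.sf(3.88)
        assert p == pytest.approx(1.05e-4, rel=0.02)

    def test_zero_z_gives_p_one(self):
        f = pd.Series([0.5, 0.7, 0.6])
        scan = asc.zscan(f)
        assert scan.loc[2, "p"] == pytest.approx(1.0)

    def test_z_has_mean_zero_sd_one(self, rng):
        f = pd.Series(rng.uniform(0.3, 0.8, size=500))
        scan = asc.zscan(f)
        assert abs(scan["z"].mean()) < 1e-10
        assert scan["z"].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_constant_frequencies_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            asc.zscan(pd.Series([0.5, 0.5, 0.5]))


class TestCallRegions:
    def _scan_from_z(self, z, chrom="chr1"):
        from scipy import stats
        idx = [f"rs{i}" for i in range(len(z))]
        snps = pd.DataFrame({"chrom": [chrom] * len(z),
                             "pos": np.arange(1, len(z) + 1) * 1000,
                             "snp": idx})
        scan = pd.DataFrame({"f_anc": 0.5, "z": z,
                             "p": 2 * stats.norm.sf(np.abs(z))}, index=idx)
        return scan, snps

    def test_rule_trace_example(self):
        scan, snps = self._scan_from_z([1.0, 3.5, 3.6, 2.0, -3.2])
        regions = asc.call_regions(scan, snps)
        assert len(regions) == 1
        reg = regions.iloc[0]
        assert (reg["start"], reg["end"], reg["n_snps"]) == (2000, 3000, 2)
        assert reg["direction"] == "over" and reg["z_max"] == pytest.approx(3.6)

    def test_no_significant_snps_empty(self):
        scan, snps = self._scan_from_z([1.0, -2.0, 2.9, 0.0])
        assert len(asc.call_regions(scan, snps)) == 0

    def test_sign_change_splits_runs(self):
        scan, snps = self._scan_from_z([3.5, 3.5, -3.5, -3.5])
        regions = asc.call_regions(scan, snps)
        assert len(regions) == 2
        assert list(regions["direction"]) == ["over", "under"]

    def test_runs_do_not_span_chromosomes(self):
        from scipy import stats
        z = np.array([3.5, 3.5, 3.5, 3.5])
        idx = [f"rs{i}" for i in range(4)]
        snps = pd.DataFrame({"chrom": ["chr1", "chr1", "chr2", "chr2"],
                             "pos": [1000, 2000, 1000, 2000], "snp": idx})
        scan = pd.DataFrame({"f_anc": 0.5, "z": z,
                             "p": 2 * stats.norm.sf(np.abs(z))}, index=idx)
        regions = asc.call_regions(scan, snps)
        assert len(regions) == 2

    def test_chromosome_order_invariance(self, rng):
        from scipy import stats
        z = rng.normal(size=40) * 2.0
        z[5:9] = 4.0
        z[25:28] = -3.6
        idx = [f"rs{i}" for i in range(40)]
        chroms = ["chrA"] * 20 + ["chrB"] * 20
        snps = pd.DataFrame({"chrom": chroms,
                             "pos": list(np.arange(1, 21) * 100) * 2, "snp": idx})
        scan = pd.DataFrame({"f_anc": 0.5, "z": z,
                             "p": 2 * stats.norm.sf(np.abs(z))}, index=idx)
        fwd = asc.call_regions(scan, snps)
        rev_order = list(range(20, 40)) + list(range(20))
        rev = asc.call_regions(scan.iloc[rev_order], snps.iloc[rev_order]
                               .reset_index(drop=True))
        assert (fwd.sort_values(["chrom", "start"]).reset_index(drop=True)
                .equals(rev.sort_values(["chrom", "start"]).reset_index(drop=True)))


class TestScanAncestry:
    def test_planted_region_called_over(self):
        spec = sd.AdmixtureSpec()
        _, calls, _, truth = sd.gen_admixed_genotypes(spec, 48, seed=21,
                                                      return_posteriors=False)
        res = asc.scan_ancestry(calls, "AMR")
        tr = truth.iloc[0]
        overlap = res.regions[(res.regions["chrom"] == tr["chrom"])
                              & (res.regions["end"] >= tr["start"])
                              & (res.regions["start"] <= tr["end"])
                              & (res.regions["direction"] == "over")]
        assert len(overlap) >= 1

    def test_outlier_exclusion_drops_extreme_sample(self, rng):
        # sample s0 is all-AMR (extreme); the other 25 samples are ~30% AMR
        rows = [["AMR", "AMR"] + ["AMR" if rng.random() < 0.3 else "EUR"
                                  for _ in range(50)]
                for _ in range(60)]
        calls = make_calls(rows)
        res = asc.scan_ancestry(calls, "AMR", exclude_outliers=True)
        full = asc.ancestry_frequency(calls, "AMR")
        # frequencies computed without s0's two haplotypes are lower on average
        assert res.snp_table["f_anc"].mean() < full.mean() - 0.02


class TestGlobalAncestryCorrelation:
    def test_linear_relation_detected(self, rng):
        idx = [f"s{i}" for i in range(30)]
        amr = rng.uniform(0.3, 0.8, size=30)
        props = pd.DataFrame({"anc_AMR": amr, "anc_EUR": 1 - amr}, index=idx)
        est = pd.DataFrame({"acc": 10 * amr + rng.normal(0, 0.01, 30)}, index=idx)
        out = asc.global_ancestry_correlation(props, est)
        row = out[(out["ancestry"] == "anc_AMR") & (out["estimator"] == "acc")].iloc[0]
        assert row["r"] > 0.99 and row["p"] < 1e-10

    def test_null_p_values_roughly_uniform(self, rng):
        idx = [f"s{i}" for i in range(30)]
        pvals = []
        for s in range(60):
            r = np.random.default_rng(s)
            props = pd.DataFrame({"anc_AMR": r.uniform(0.3, 0.8, 30)}, index=idx)
            est = pd.DataFrame({"e": r.normal(size=30)}, index=idx)
            pvals.append(asc.global_ancestry_correlation(props, est)["p"].iloc[0])
        assert 0.2 < np.mean(np.array(pvals) < 0.5) < 0.8

    def test_gate_switches_to_kendall_on_skewed_input(self, rng):
        idx = [f"s{i}" for i in range(40)]
        props = pd.DataFrame({"anc_AMR": rng.exponential(size=40) ** 2}, index=idx)
        props["anc_AMR"] /= props["anc_AMR"].max() + 1.0
        est = pd.DataFrame({"e": rng.normal(size=40)}, index=idx)
        out = asc.global_ancestry_correlation(props, est)
        assert out["method"].iloc[0] == "kendall"

    def test_too_few_pairs_rejected(self, rng):
        idx = ["a", "b", "c"]
        props = pd.DataFrame({"anc_AMR": [0.1, 0.2, 0.3]}, index=idx)
        est = pd.DataFrame({"e": [1.0, 2.0, 3.0]}, index=idx)
        with pytest.raises(ValueError):
            asc.global_ancestry_correlation(props, est)
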