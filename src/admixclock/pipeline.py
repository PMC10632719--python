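"""Stage orchestration: run every analysis stage and write a report bundle.

``run_pipeline`` is deterministic given (inputs, seed): per-stage RNG streams
are spawned from the root seed, and every output table is written in the
canonical TSV layout, so two runs with the same configuration produce
byte-identical bundles.  Any stage failure aborts with the stage name; the
bundle manifest marks which stage outputs were written.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import (ancestry_scan, clock_engine, genotype_qc, group_comparison,
               gwas_replication, kinship_delta, relative_importance,
               synthetic_data)
from .io_formats import PipelineConfig, logger, write_table, write_regions_bed


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def simulate_inputs(config: PipelineConfig, out_dir: Path | None = None) -> dict:
    """Generate the full synthetic input bundle under the study-design preset."""
    seeds = _stage_seeds(config.seed)
    spec, clock_plan = synthetic_data.paper_preset()
    cohort = synthetic_data.gen_cohort(spec, seed=seeds[0])
    cohort = synthetic_data.gen_ancestry_props(cohort, seed=seeds[1])
    clocks = [synthetic_data.gen_clock(name=name, seed=seeds[2] + k, **kw)
              for k, (name, kw) in enumerate(clock_plan.items())]
    betas = synthetic_data.gen_betas(cohort, clocks, spec, seed=seeds[3])
    admix = synthetic_data.AdmixtureSpec()
    genotypes, calls, posteriors, truth = synthetic_data.gen_admixed_genotypes(
        admix, n_samples=spec.n_per_group, seed=seeds[4])
    # the admixed genotypes play the admixed-role (groupB) samples
    group_b = list(cohort.loc[cohort["population"] == "groupB", "sample_id"])
    rename = dict(zip(genotypes.dosages.index, group_b))
    genotypes.dosages.index = [rename[s] for s in genotypes.dosages.index]
    calls.calls.columns = [f"{rename[h.rsplit('_', 1)[0]]}_{h.rsplit('_', 1)[1]}"
                           for h in calls.calls.columns]
    if posteriors is not None:
        posteriors["haplotype"] = [
            f"{rename[h.rsplit('_', 1)[0]]}_{h.rsplit('_', 1)[1]}"
            for h in posteriors["haplotype"]]
    kin, inbreeding = synthetic_data.gen_relatedness(cohort, seed=seeds[5])
    cohort["inbreeding_f"] = inbreeding.loc[cohort["sample_id"]].to_numpy()
    causal = genotypes.snps.loc[
        genotypes.snps["snp"].isin(_region_snps(truth, genotypes)), "snp"]
    catalog = synthetic_data.gen_gwas_catalog(
        truth, genotypes, causal_snp=causal.iloc[len(causal) // 2], seed=seeds[6])
    bundle = {"cohort": cohort, "clocks": clocks, "betas": betas,
              "genotypes": genotypes, "calls": calls, "posteriors": posteriors,
              "truth_regions": truth, "kinship": kin, "catalog": catalog,
              "spec": spec}
    if out_dir is not None:
        inputs = Path(out_dir) / "inputs"
        write_table(cohort, inputs / "samples.tsv", "samples")
        write_table(betas, inputs / "betas.tsv", "betas")
        for clock in clocks:
            write_table(clock, inputs / f"clock_{clock.name}.tsv", "clock")
        write_table(genotypes, inputs / "genotypes.tsv", "genotypes")
        write_table(calls, inputs / "ancestry_calls.tsv", "ancestry_calls")
        write_table(kin, inputs / "kinship.tsv", "kinship")
        write_table(catalog, inputs / "gwas_catalog.tsv", "gwas_catalog")
    return bundle


def _region_snps(truth: pd.DataFrame, genotypes) -> list[str]:
    snps = genotypes.snps
    out = []
    for _, reg in truth.iterrows():
        sel = ((snps["chrom"] == reg["chrom"]) & (snps["pos"] >= reg["start"])
               & (snps["pos"] <= reg["end"]))
        out.extend(snps.loc[sel, "snp"])
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all enabled stages; returns {stage: outputs} and writes the bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    report: dict[str, object] = {}

    def run_stage(name: str, fn):
        if not config.stages.get(name, True):
            logger.info("stage %s disabled", name)
            return None
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            manifest[name] = {"status": "failed", "error": str(exc)}
            _write_manifest(out_dir, manifest, complete=False)
            raise StageError(name, exc) from exc
        logger.info("stage %s finished in %.3fs", name, time.perf_counter() - t0)
        manifest[name] = {"status": "ok"}
        return result

    if not config.synthetic:
        raise NotImplementedError(
            "file-driven mode: supply tables via config.paths and call the stage "
            "functions directly; the orchestrated path currently covers synthetic mode")

    data = simulate_inputs(config, out_dir)
    manifest["simulate"] = {"status": "ok",
                            "n_samples": len(data["cohort"]),
                            "n_snps": data["genotypes"].n_snps}
    cohort = data["cohort"]

    def stage_qc():
        g, kept, qc_report = genotype_qc.run_qc(
            data["genotypes"], mind=config.mind, geno=config.geno,
            hwe_p=config.hwe_p, pihat_max=config.pihat_max,
            ld_window=config.ld_window, ld_step=config.ld_step,
            ld_r2_max=config.ld_r2_max)
        write_table(g, out_dir / "qc_genotypes.tsv", "genotypes")
        (out_dir / "qc_report.json").write_text(
            json.dumps(qc_report.to_dict(), indent=2, sort_keys=True) + "\n")
        (out_dir / "qc_kept_snps.txt").write_text("\n".join(kept) + "\n")
        return {"genotypes": g, "kept": kept, "report": qc_report}

    def stage_clocks():
        est = clock_engine.compute_all(data["betas"], data["clocks"], cohort)
        write_table(est, out_dir / "estimators.tsv", "estimators")
        return est

    qc_out = run_stage("qc", stage_qc)
    report["qc"] = qc_out
    est = run_stage("clocks", stage_clocks)
    if est is None:
        _write_manifest(out_dir, manifest, complete=False)
        raise StageError("clocks", RuntimeError("downstream stages need estimators"))
    report["estimators"] = est
    groups = pd.Series(cohort["population"].to_numpy(), index=cohort["sample_id"])

    def stage_compare():
        comp = group_comparison.compare_all(est, groups, fdr_q=config.fdr_q,
                                            shapiro_alpha=config.shapiro_alpha)
        comp.to_csv(out_dir / "comparison.tsv", sep="\t", index=False)
        clusters = group_comparison.independence_groups(est)
        medians = group_comparison.median_discrepancy(est, groups)
        medians.to_csv(out_dir / "group_medians.tsv", sep="\t")
        (out_dir / "independence_clusters.json").write_text(
            json.dumps(clusters, indent=2) + "\n")
        return {"comparison": comp, "clusters": clusters, "medians": medians}

    def stage_scan():
        calls = (ancestry_scan.collapse_posteriors(data["posteriors"],
                                                   threshold=config.posterior_min)
                 if data["posteriors"] is not None else data["calls"])
        res = ancestry_scan.scan_ancestry(calls, "AMR",
                                          z_threshold=config.z_threshold,
                                          min_snps=config.min_region_snps)
        res.snp_table.to_csv(out_dir / "ancestry_scan.tsv", sep="\t", index=False)
        res.regions.to_csv(out_dir / "ancestry_regions.tsv", sep="\t", index=False)
        if len(res.regions):
            write_regions_bed(res.regions, out_dir / "ancestry_regions.bed")
        props = cohort.set_index("sample_id")[
            [c for c in cohort.columns if c.startswith("anc_")]]
        gb = groups.index[groups == "groupB"]
        corr = ancestry_scan.global_ancestry_correlation(
            props.loc[gb], est.loc[est.index.intersection(gb)],
            shapiro_alpha=config.shapiro_alpha)
        corr.to_csv(out_dir / "global_ancestry_corr.tsv", sep="\t", index=False)
        return {"scan": res, "global_corr": corr}

    compare_out = run_stage("compare", stage_compare)
    report["compare"] = compare_out
    scan_out = run_stage("scan", stage_scan)
    report["scan"] = scan_out

    def stage_replicate():
        regions = (scan_out["scan"].regions if scan_out is not None
                   else data["truth_regions"].rename(columns={})
                   .assign(direction="over"))
        candidates = gwas_replication.discover(regions, data["catalog"],
                                               p_max=config.replication_alpha)
        gb = [s for s in est.index if groups[s] == "groupB"]
        hannum_col = next((c for c in est.columns if "hannum" in c), est.columns[0])
        rep = gwas_replication.replicate(
            data["genotypes"].subset(samples=[s for s in gb
                                              if s in set(data["genotypes"].dosages.index)]),
            est[hannum_col], candidates, alpha=config.replication_alpha)
        candidates.to_csv(out_dir / "discovery.tsv", sep="\t", index=False)
        rep.to_csv(out_dir / "replication.tsv", sep="\t", index=False)
        return {"candidates": candidates, "replication": rep}

    def stage_importance():
        frames = relative_importance.build_model_frames(cohort, est)
        imp = relative_importance.importance_report(frames, est)
        imp.to_csv(out_dir / "importance.tsv", sep="\t", index=False)
        wide = imp[imp["predictor"] != "NA"].pivot_table(
            index=["model", "estimator"], columns="predictor", values="lmg_norm")
        wide.to_csv(out_dir / "importance_heatmap.tsv", sep="\t")
        return imp

    def stage_kinship():
        ga = [s for s in est.index if groups[s] == "groupA"]
        assoc = kinship_delta.kinship_delta_association(
            est.loc[ga], data["kinship"], n_permutations=199, seed=config.seed)
        f = cohort.set_index("sample_id").loc[ga, "inbreeding_f"]
        inb = kinship_delta.inbreeding_association(f, est.loc[ga],
                                                   fdr_q=config.inbreeding_fdr_q)
        assoc.to_csv(out_dir / "kinship_delta.tsv", sep="\t", index=False)
        inb.to_csv(out_dir / "inbreeding_assoc.tsv", sep="\t", index=False)
        return {"delta": assoc, "inbreeding": inb}

    report["replicate"] = run_stage("replicate", stage_replicate)
    report["importance"] = run_stage("importance", stage_importance)
    report["kinship"] = run_stage("kinship", stage_kinship)
    _write_manifest(out_dir, manifest, complete=True)
    report["manifest"] = manifest
    return report


def _write_manifest(out_dir: Path, manifest: dict, complete: bool) -> None:
    payload = {"complete": complete, "stages": manifest}
    (Path(out_dir) / "manifest.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n")
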