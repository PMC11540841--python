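"""End-to-end pipeline: QC -> diversity -> LD/IA -> FST/AMOVA -> PCA/DAPC ->
karyotypes -> haplotypes -> admixture -> LD-pruned re-analysis.

Driven by a single :class:`PipelineConfig` (YAML or dict).  Every random
stage derives its generator from one master seed, so a config + seed pair
reproduces the full report bundle bit-for-bit (timestamps aside).  Outputs
are plain TSV / JSON / Newick files in the configured output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .genotypes import (
    GenotypeMatrix, SampleMetadata, read_genotypes, read_metadata,
    apply_locus_and_individual_qc, write_genotypes, write_metadata,
)
from .simulate import SimulationConfig, simulate_dataset, paper_like_preset
from .diversity import per_sample_diversity, hwe_tests_per_sample, \
    kruskal_wallis_groups
from .linkage import pairwise_ld_fisher, index_of_association, bh_fdr, ld_prune
from .differentiation import weir_cockerham_fst, amova, fst_dendrogram
from .ordination import pca_genotypes, driver_loci_from_loadings, dapc_fit
from .karyotype import (classify_karyotypes, karyotype_frequency_table,
                        haplogroup_frequencies_by_sample, detect_migrants,
                        assignment_memberships, ClassificationRejected)
from .haplotypes import em_phase_haplotypes, haplotype_differentiation
from .admixture import run_replicates, evanno_delta_k, \
    puechmaille_statistics, align_and_average_runs

log = logging.getLogger("lanternpop")

ALL_STAGES = (
    "qc", "diversity", "linkage", "differentiation", "ordination",
    "karyotype", "haplotypes", "admixture", "pruned",
)


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    seed: int = 0
    outdir: str = "lanternpop_out"
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    # input: either a synthetic preset or file paths
    synthetic: dict[str, Any] | None = None  # {"preset": ..., kwargs}
    genotypes: str | None = None
    genotype_format: str = "genepop"
    metadata: str | None = None
    params: dict[str, dict[str, Any]] = field(default_factory=dict)

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.synthetic is None and self.genotypes is None:
            raise ValueError("either synthetic preset or genotype path required")
        for st in self.params:
            if st not in ALL_STAGES:
                raise ValueError(f"parameters given for unknown stage {st!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**d)

    def digest(self) -> str:
        blob = json.dumps(
            {k: v for k, v in self.__dict__.items()}, sort_keys=True,
            default=str,
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class ReportBundle:
    """All tables produced by one pipeline run, plus provenance."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    scalars: dict[str, Any] = field(default_factory=dict)
    files: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _save(df: pd.DataFrame, outdir: Path, name: str, bundle: ReportBundle
          ) -> None:
    path = outdir / f"{name}.tsv"
    df.to_csv(path, sep="\t")
    bundle.tables[name] = df
    bundle.files[name] = str(path)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the configured stages in dependency order and write the bundle."""
    config.validate()
    t_start = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle()
    bundle.provenance = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "stages": list(config.stages),
    }
    p = {st: dict(config.params.get(st, {})) for st in ALL_STAGES}

    # ---- input ------------------------------------------------------------
    if config.synthetic is not None:
        kw = dict(config.synthetic)
        preset = kw.pop("preset", "paper_like")
        if preset != "paper_like":
            raise ValueError(f"unknown preset {preset!r}")
        sim_cfg = paper_like_preset(seed=config.seed, **kw)
        gm, meta, truth = simulate_dataset(sim_cfg)
        truth.to_json(outdir / "truth.json")
        write_genotypes(gm, outdir / "simulated.genepop", "genepop",
                        metadata=meta)
        write_metadata(meta, outdir / "simulated_metadata.tsv")
        log.info("simulated %d individuals x %d loci", gm.n_individuals,
                 gm.n_loci)
    else:
        gm, meta0 = read_genotypes(config.genotypes, config.genotype_format)
        meta = (read_metadata(config.metadata) if config.metadata else meta0)
        meta.check_against(gm)

    # ---- qc ---------------------------------------------------------------
    if "qc" in config.stages:
        t0 = time.time()
        gm, qc_report = apply_locus_and_individual_qc(gm, meta,
                                                      **p["qc"])
        meta = meta.subset(gm.individuals)
        qc_report.to_json(outdir / "qc_report.json")
        bundle.scalars["qc"] = qc_report.summary()
        log.info("qc: %s (%.1fs)", qc_report.summary(), time.time() - t0)

    # ---- diversity --------------------------------------------------------
    if "diversity" in config.stages:
        t0 = time.time()
        div = per_sample_diversity(gm, meta, by="site")
        _save(div.table, outdir, "diversity_by_site", bundle)
        hwe = hwe_tests_per_sample(gm, meta, by="site")
        q, sig = bh_fdr(hwe["p"])
        hwe["q"] = q
        hwe["significant"] = sig
        _save(hwe.set_index(["sample", "locus"]), outdir, "hwe_tests", bundle)
        grp_of = meta.group_of_site()
        grouping = [grp_of[s] for s in div.table.index]
        if len(set(grouping)) > 1:
            h, pval = kruskal_wallis_groups(
                div.table["uhe_mean"].to_numpy(), grouping)
            bundle.scalars["kruskal_wallis_uhe"] = {"H": h, "p": pval}
        log.info("diversity done (%.1fs)", time.time() - t0)

    # ---- linkage ----------------------------------------------------------
    ld = None
    if "linkage" in config.stages or "pruned" in config.stages:
        t0 = time.time()
        lk = p["linkage"]
        ld = pairwise_ld_fisher(
            gm, scope="pooled",
            mc_draws=lk.get("mc_draws", 20_000),
            seed=_stage_seed(config.seed, "linkage"),
        )
        _save(ld.to_frame(), outdir, "ld_pvalues", bundle)
        ia_loci = lk.get("ia_loci")  # optional subset (e.g. driver block)
        sub = gm.subset(loci=ia_loci) if ia_loci else gm
        ia = index_of_association(
            sub, n_perm=lk.get("n_perm", 99),
            seed=_stage_seed(config.seed, "ia"))
        bundle.scalars["index_of_association"] = {
            "IA": ia.ia, "rbar_d": ia.rbar_d, "p_IA": ia.p_ia,
            "p_rbar_d": ia.p_rbar_d,
        }
        log.info("linkage done (%.1fs)", time.time() - t0)

    # ---- differentiation --------------------------------------------------
    if "differentiation" in config.stages:
        t0 = time.time()
        dp = p["differentiation"]
        n_perm = dp.get("n_perm", 1000)
        fst = weir_cockerham_fst(
            gm, meta, by="site", n_perm=n_perm,
            seed=_stage_seed(config.seed, "fst"))
        _save(fst.to_frame(), outdir, "fst_pairwise", bundle)
        newick, order = fst_dendrogram(fst)
        (outdir / "fst_dendrogram.nwk").write_text(newick + "\n")
        bundle.files["fst_dendrogram"] = str(outdir / "fst_dendrogram.nwk")
        bundle.scalars["fst_leaf_order"] = order
        am = amova(gm, meta, by="site", groups="group",
                   n_perm=dp.get("amova_perm", 200),
                   seed=_stage_seed(config.seed, "amova"))
        _save(am.to_frame().set_index("level"), outdir, "amova", bundle)
        bundle.scalars["amova"] = {**am.f_statistics, "p": am.p_values}
        log.info("differentiation done (%.1fs)", time.time() - t0)

    # ---- ordination -------------------------------------------------------
    pca = None
    drivers: list[str] = []
    if {"ordination", "karyotype", "haplotypes", "pruned"} & set(config.stages):
        t0 = time.time()
        pca = pca_genotypes(gm, n_axes=p["ordination"].get("n_axes", 10))
        _save(pca.scores, outdir, "pca_scores", bundle)
        _save(pca.loadings, outdir, "pca_loadings", bundle)
        bundle.scalars["pca_explained_variance"] = list(
            map(float, pca.explained_variance_ratio[:10]))
        drv = driver_loci_from_loadings(pca, axis=1)
        drivers = list(drv["locus"])
        _save(drv.set_index("locus"), outdir, "driver_loci", bundle)
        if "ordination" in config.stages:
            dapc = dapc_fit(
                gm, meta.group_of(),
                xval_reps=p["ordination"].get("xval_reps", 10),
                seed=_stage_seed(config.seed, "dapc"))
            _save(dapc.coordinates, outdir, "dapc_coordinates", bundle)
            _save(dapc.xval_table.set_index("n_pcs"), outdir, "dapc_xval",
                  bundle)
            bundle.scalars["dapc"] = {
                "n_pcs": dapc.n_pcs, "n_da": dapc.n_da,
                "assignment_success": dapc.assignment_success,
            }
        log.info("ordination done (%.1fs)", time.time() - t0)

    # ---- karyotype --------------------------------------------------------
    calls = None
    if {"karyotype", "haplotypes"} & set(config.stages) and drivers:
        t0 = time.time()
        try:
            calls = classify_karyotypes(
                pca, gm, drivers, metadata=meta,
                seed=_stage_seed(config.seed, "karyotype"))
        except ClassificationRejected as e:
            bundle.scalars["karyotype"] = f"rejected: {e}"
            calls = None
        if calls is not None:
            out = pd.DataFrame({
                "site": meta.site_of().loc[calls.labels.index],
                "group": meta.group_of().loc[calls.labels.index],
                "karyotype": calls.labels,
                "quality": calls.quality,
            })
            _save(out, outdir, "karyotype_calls", bundle)
            kft = karyotype_frequency_table(gm, calls, loci=drivers,
                                            metadata=meta)
            _save(kft.table, outdir, "karyotype_frequencies", bundle)
            _save(haplogroup_frequencies_by_sample(calls, meta), outdir,
                  "haplogroup_by_sample", bundle)
        log.info("karyotype done (%.1fs)", time.time() - t0)

    # ---- haplotypes -------------------------------------------------------
    if "haplotypes" in config.stages and calls is not None:
        t0 = time.time()
        kft = karyotype_frequency_table(gm, calls, loci=drivers,
                                        metadata=meta)
        diag = list(kft.diagnostic[kft.diagnostic].index) or drivers
        hp = p["haplotypes"]
        hapset = em_phase_haplotypes(
            gm, loci=diag, restarts=hp.get("restarts", 5),
            seed=_stage_seed(config.seed, "haplotypes"))
        _save(hapset.frequency_table().set_index("haplotype"), outdir,
              "haplotype_frequencies", bundle)
        _save(hapset.phases, outdir, "haplotype_phases", bundle)
        ham = haplotype_differentiation(
            hapset, meta, n_perm=hp.get("n_perm", 200),
            seed=_stage_seed(config.seed, "hap_amova"))
        _save(ham.to_frame().set_index("level"), outdir, "haplotype_amova",
              bundle)
        bundle.scalars["haplotype_amova"] = {
            **ham.f_statistics, "p": ham.p_values}
        log.info("haplotypes done (%.1fs)", time.time() - t0)

    # ---- admixture --------------------------------------------------------
    if "admixture" in config.stages:
        t0 = time.time()
        ap = p["admixture"]
        k_max = ap.get("k_max", 4)
        runs = run_replicates(
            gm, range(1, k_max + 1), n_runs=ap.get("n_runs", 2),
            burn_in=ap.get("burn_in", 500), n_iter=ap.get("n_iter", 1500),
            seed=_stage_seed(config.seed, "admixture"))
        ev = evanno_delta_k(runs)
        _save(ev.table, outdir, "evanno", bundle)
        bundle.scalars["evanno_best_k"] = ev.best_k
        top_runs = [r for r in runs if r.K == k_max]
        pm = puechmaille_statistics(top_runs, meta.site_of())
        bundle.scalars["puechmaille"] = {
            "MedMedK": pm.med_med_k, "MedMeanK": pm.med_mean_k,
            "MaxMedK": pm.max_med_k, "MaxMeanK": pm.max_mean_k,
        }
        if ev.best_k is not None:
            best_runs = [r for r in runs if r.K == ev.best_k]
            if len(best_runs) >= 2:
                q_avg, _, gsim = align_and_average_runs(best_runs)
                _save(q_avg, outdir, "admixture_q_bestk", bundle)
                bundle.scalars["clumpp_g"] = gsim
        log.info("admixture done (%.1fs)", time.time() - t0)

    # ---- pruned re-analysis ----------------------------------------------
    if "pruned" in config.stages and ld is not None:
        t0 = time.time()
        pr = p["pruned"]
        retained, comp = ld_prune(gm, ld,
                                  p_threshold=pr.get("p_threshold", 0.01))
        _save(comp.set_index("locus"), outdir, "ld_prune_components", bundle)
        (outdir / "pruned_loci.txt").write_text("\n".join(retained) + "\n")
        bundle.files["pruned_loci"] = str(outdir / "pruned_loci.txt")
        gm_p = gm.subset(loci=retained)
        pca_p = pca_genotypes(gm_p, n_axes=5)
        _save(pca_p.scores, outdir, "pruned_pca_scores", bundle)
        fst_p = weir_cockerham_fst(
            gm_p, meta, by="site", n_perm=pr.get("n_perm", 200),
            seed=_stage_seed(config.seed, "pruned_fst"))
        _save(fst_p.to_frame(), outdir, "pruned_fst_pairwise", bundle)
        am_p = amova(gm_p, meta, by="site", groups="group",
                     n_perm=pr.get("amova_perm", 200),
                     seed=_stage_seed(config.seed, "pruned_amova"))
        _save(am_p.to_frame().set_index("level"), outdir, "pruned_amova",
              bundle)
        mem = assignment_memberships(gm_p, meta, by="group")
        mig = detect_migrants(mem, meta, calls=calls)
        _save(mig.set_index("individual") if not mig.empty else mig, outdir,
              "migrants", bundle)
        comparison = pd.DataFrame({
            "full": {
                "n_loci": gm.n_loci,
                "pc1_var": float(pca.explained_variance_ratio[0])
                if pca is not None else np.nan,
            },
            "pruned": {
                "n_loci": gm_p.n_loci,
                "pc1_var": float(pca_p.explained_variance_ratio[0]),
            },
        })
        _save(comparison, outdir, "full_vs_pruned", bundle)
        log.info("pruned re-analysis done (%.1fs)", time.time() - t0)

    bundle.provenance["wall_time_s"] = round(time.time() - t_start, 2)
    (outdir / "provenance.json").write_text(
        json.dumps(bundle.provenance, indent=2, default=str))
    scalars_path = outdir / "summary.json"
    scalars_path.write_text(json.dumps(bundle.scalars, indent=2, default=str))
    bundle.files["summary"] = str(scalars_path)
    return bundle
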