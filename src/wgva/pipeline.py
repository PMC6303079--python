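"""End-to-end orchestration: simulate -> filter -> qc -> associate -> scan ->
segregate, with a manifest that records every parameter, the variant
accounting at each stage (input = removed by missingness + removed by MAF +
tested) and output file hashes, so a run is reproducible from the manifest
alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import association, filters, qc, scan, segregation, vcfio
from .containers import CohortDesign, GenotypeMatrix
from .simulate import CausalSpec, SimulationConfig, simulate_cohort

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat run configuration; every field echoes into the manifest."""

    seed: int = 0
    out_prefix: str = "wgva_run"
    # stage toggles
    do_filter: bool = True
    do_prune: bool = True
    do_ibs: bool = True
    do_mendel: bool = True
    do_scan: bool = True
    do_segregate: bool = True
    write_outputs: bool = True
    # variant filters
    max_missing: float = 0.10
    min_maf: float = 0.01
    prune_max_missing: float = 0.05   # pruning subset: genotyped in > 95%
    prune_min_maf: float = 0.05       # pruning subset: MAF > 5%
    # pruning
    window_size: int = 50
    step_size: int = 5
    vif_threshold: float = 2.0
    # association
    gc_mode: str = "mean"
    alpha: float = 0.05
    # scan
    min_allelic_diff: float = 0.9
    max_gap: int = 1_000_000
    min_region_variants: int = 10
    # simulation (used when no input VCF is given)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self):
        if isinstance(self.simulation, dict):
            sim = dict(self.simulation)
            if isinstance(sim.get("causal"), dict):
                sim["causal"] = CausalSpec(**sim["causal"])
            for key in ("breed_sizes", "case_breeds", "breed_names"):
                if isinstance(sim.get(key), list):
                    sim[key] = tuple(sim[key])
            self.simulation = SimulationConfig(**sim)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig,
            matrix: GenotypeMatrix | None = None,
            design: CohortDesign | None = None) -> dict:
    """Execute the pipeline and return the manifest.

    With no input matrix/design a cohort is simulated under
    ``config.simulation`` (re-seeded from ``config.seed``).  Stage outputs
    land next to ``config.out_prefix`` when ``write_outputs`` is set; they
    are also returned in the manifest under ``"tables"`` for programmatic
    use.
    """
    cfg = config
    manifest: dict = {"parameters": _jsonable(asdict(cfg)), "counts": {}, "outputs": {}}
    tables: dict = {}
    prefix = cfg.out_prefix
    outdir = os.path.dirname(prefix)
    if cfg.write_outputs and outdir:
        os.makedirs(outdir, exist_ok=True)

    # -- stage: cohort -----------------------------------------------------
    if matrix is None or design is None:
        sim = cfg.simulation
        if sim.seed != cfg.seed:
            sim = SimulationConfig(**{**asdict(sim), "seed": cfg.seed,
                                      "causal": sim.causal,
                                      "breed_sizes": sim.breed_sizes,
                                      "case_breeds": sim.case_breeds,
                                      "breed_names": sim.breed_names})
        matrix, design = simulate_cohort(sim)
        manifest["counts"]["simulated_variants"] = matrix.n_variants
        manifest["counts"]["samples"] = matrix.n_samples
        if cfg.write_outputs:
            vcfio.write_vcf(matrix, prefix + ".vcf", design)
            vcfio.write_pedigree(design, prefix + ".fam")
            manifest["outputs"]["vcf"] = prefix + ".vcf"
            manifest["outputs"]["fam"] = prefix + ".fam"
    manifest["counts"]["input_variants"] = matrix.n_variants

    # -- stage: site filters ----------------------------------------------
    if cfg.do_filter:
        pass_mask, labels = filters.apply_hard_filters(matrix.variants)
        matrix.variants["FILTER"] = labels.to_numpy()
        kept = np.flatnonzero(pass_mask)
        manifest["counts"]["failed_hard_filters"] = matrix.n_variants - len(kept)
        matrix = matrix.take_variants(kept)
        bi = filters.select_biallelic(matrix.variants)
        manifest["counts"]["multiallelic_removed"] = matrix.n_variants - len(bi)
        matrix = matrix.take_variants(bi)
        chroms = sorted(set(matrix.variants["CHROM"]))
        placed = filters.drop_unplaced(matrix.variants, chroms)
        matrix = matrix.take_variants(placed)
        matrix.variants = filters.recode_indels(matrix.variants)
        manifest["counts"]["after_site_filters"] = matrix.n_variants
        log.info("site filters: %d variants pass", matrix.n_variants)

    # -- stage: qc ---------------------------------------------------------
    n_before = matrix.n_variants
    keep_missing = qc.filter_missingness(matrix.dosages, cfg.max_missing)
    removed_missing = n_before - len(keep_missing)
    matrix = matrix.take_variants(keep_missing)
    keep_maf = qc.filter_maf(matrix.dosages, cfg.min_maf)
    removed_maf = len(keep_missing) - len(keep_maf)
    matrix = matrix.take_variants(keep_maf)
    manifest["counts"].update({
        "qc_input": n_before,
        "removed_missingness": removed_missing,
        "removed_maf": removed_maf,
        "tested": matrix.n_variants,
    })
    assert n_before == removed_missing + removed_maf + matrix.n_variants
    log.info("qc: %d removed by missingness, %d by MAF, %d tested",
             removed_missing, removed_maf, matrix.n_variants)

    n_tests = matrix.n_variants
    if cfg.do_prune:
        subset = qc.filter_missingness(matrix.dosages, cfg.prune_max_missing)
        sub_matrix = matrix.take_variants(subset)
        subset2 = qc.filter_maf(sub_matrix.dosages, cfg.prune_min_maf)
        sub_matrix = sub_matrix.take_variants(subset2)
        pruned = qc.vif_prune(sub_matrix, qc.PruneConfig(
            window_size=cfg.window_size, step_size=cfg.step_size,
            vif_threshold=cfg.vif_threshold))
        n_tests = max(len(pruned), 1)
        manifest["counts"]["pruned_set"] = len(pruned)
        tables["prune_in"] = sub_matrix.variants.iloc[pruned][["CHROM", "POS"]]
        if cfg.write_outputs:
            tables["prune_in"].to_csv(prefix + ".prune.in", sep="\t", index=False)
            manifest["outputs"]["prune_in"] = prefix + ".prune.in"

    if cfg.do_ibs:
        dist = qc.ibs_distance(matrix.dosages, list(matrix.samples))
        newick, _ = qc.dendrogram(dist)
        tables["ibs"] = dist
        tables["newick"] = newick
        if cfg.write_outputs:
            dist.to_csv(prefix + ".ibs.tsv", sep="\t")
            with open(prefix + ".tree.nwk", "w") as fh:
                fh.write(newick + "\n")
            manifest["outputs"]["ibs"] = prefix + ".ibs.tsv"
            manifest["outputs"]["tree"] = prefix + ".tree.nwk"

    if cfg.do_mendel and design.trios:
        mendel = qc.mendel_errors(matrix, design)
        tables["mendel"] = mendel
        manifest["counts"]["mendel_mean_rate"] = float(mendel["per_meiosis_rate"].mean())
        if cfg.write_outputs:
            mendel.to_csv(prefix + ".mendel.tsv", sep="\t", index=False)
            manifest["outputs"]["mendel"] = prefix + ".mendel.tsv"

    # -- stage: association ------------------------------------------------
    assoc_cfg = association.AssocConfig(gc_mode=cfg.gc_mode, n_tests=n_tests,
                                        alpha=cfg.alpha)
    results, qq, model = association.run_association(matrix, design, assoc_cfg)
    manifest["counts"]["lambda"] = model.lambda_
    manifest["counts"]["n_tests_bonferroni"] = n_tests
    tables["assoc"] = results
    tables["qq"] = qq
    if cfg.write_outputs:
        results.to_csv(prefix + ".assoc.tsv", sep="\t", index=False)
        qq.to_csv(prefix + ".qq.tsv", sep="\t", index=False)
        manifest["outputs"]["assoc"] = prefix + ".assoc.tsv"
        manifest["outputs"]["qq"] = prefix + ".qq.tsv"

    # -- stage: fixation scan ----------------------------------------------
    if cfg.do_scan:
        passing = scan.fixation_filter(results, cfg.min_allelic_diff)
        regions = scan.rank_regions(scan.build_regions(
            passing, cfg.max_gap, cfg.min_region_variants))
        tables["regions"] = regions
        manifest["counts"]["fixation_passing"] = len(passing)
        manifest["counts"]["candidate_regions"] = len(regions)
        if cfg.write_outputs:
            regions.to_csv(prefix + ".regions.tsv", sep="\t", index=False)
            with open(prefix + ".regions.bed", "w") as fh:
                fh.write(scan.regions_to_bed(regions))
            manifest["outputs"]["regions"] = prefix + ".regions.tsv"
            manifest["outputs"]["regions_bed"] = prefix + ".regions.bed"

    # -- stage: segregation on the top hit ----------------------------------
    if cfg.do_segregate and len(results):
        top = int(results["CHISQ"].idxmax())
        counts = segregation.genotype_counts(matrix, design, top)
        status_of_breed = {design.breed_of[s]: design.status_of[s]
                           for s in design.sample_ids}
        seg_rows = []
        for r in counts.itertuples():
            affected = status_of_breed.get(r.BREED) == "case"
            for g, n in (("HOM_REF", r.HOM_REF), ("HET", r.HET), ("HOM_ALT", r.HOM_ALT)):
                seg_rows.append({"BREED": r.BREED, "GENOTYPE": g,
                                 "AFFECTED": n if affected else 0,
                                 "UNAFFECTED": 0 if affected else n})
        seg_table = pd.DataFrame(seg_rows)
        p_seg = segregation.segregation_test(seg_table, collapse="recessive")
        tables["genotype_counts"] = counts
        manifest["counts"]["top_variant"] = {
            "CHR": str(results.loc[top, "CHR"]), "POS": int(results.loc[top, "POS"]),
            "P": float(results.loc[top, "P"]),
            "P_GC": float(results.loc[top, "P_GC"]),
            "P_BONF": float(results.loc[top, "P_BONF"]),
        }
        manifest["counts"]["segregation_p"] = p_seg
        if cfg.write_outputs:
            counts.to_csv(prefix + ".genotypes.tsv", sep="\t", index=False)
            manifest["outputs"]["genotypes"] = prefix + ".genotypes.tsv"

    if cfg.write_outputs:
        manifest["hashes"] = {k: _sha256(v) for k, v in manifest["outputs"].items()}
        with open(prefix + ".manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    manifest["tables"] = tables
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
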