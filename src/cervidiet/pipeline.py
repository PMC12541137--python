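"""End-to-end runner: simulate/load -> host ID -> diet QC -> metrics ->
ordination -> overlap drivers, with plain-TSV stage outputs and a run
manifest (config hash, seed, versions, per-stage attrition counts)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, diet_quant, drivers, host_id, niche_metrics, \
    partitioning, synthetic
from .io_model import (AvailabilityTable, CovariateTable, DietProfile,
                       MOTUCatalog, PelletCountTable, ReadCountTable,
                       SampleMetadata, read_table, write_table)

log = logging.getLogger("cervidiet")


@dataclass
class RunConfig:
    """Thresholds and choices for one pipeline run.

    Input tables may be given as paths; when absent, a synthetic dataset
    is generated from the default community spec with ``seed``.
    """

    out_dir: str = "results"
    seed: int = 0
    counts_path: str | None = None
    catalog_path: str | None = None
    metadata_path: str | None = None
    availability_path: str | None = None
    pellets_path: str | None = None
    covariates_path: str | None = None
    category_map_path: str | None = None  # TSV motu_id -> category
    # mammal-marker thresholds
    mammal_min_share: float = 0.01
    mammal_min_length: int = 40
    mammal_min_reads: int = 500
    # plant-marker thresholds
    plant_min_reads: int = 1000
    qc_quantile: float = 0.05
    min_similarity: float = 95.0
    min_max_rra: float = 0.025
    knn_k: int = 5
    qc_threshold: float | None = None     # overrides the fitted threshold
    # analysis choices
    n_perm: int = 10_000
    collapse_rank: str | None = None      # None = MOTU resolution
    min_transects_betareg: int = 8
    run_selectivity: bool = True
    run_drivers: bool = True

    def validate(self) -> None:
        if not (0 < self.mammal_min_share < 1):
            raise ValueError("mammal_min_share must be in (0, 1)")
        if not (0 < self.qc_quantile < 0.5):
            raise ValueError("qc_quantile must be in (0, 0.5)")
        if not (0 <= self.min_max_rra < 1):
            raise ValueError("min_max_rra must be in [0, 1)")
        if not (0 <= self.min_similarity <= 100):
            raise ValueError("min_similarity must be in [0, 100]")
        if self.n_perm < 1 or self.knn_k < 1:
            raise ValueError("n_perm and knn_k must be >= 1")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    out_dir: Path
    manifest: dict
    profile: DietProfile
    assignments: pd.DataFrame
    overlaps: pd.DataFrame | None = None
    tables: dict = field(default_factory=dict)


def _load_inputs(config: RunConfig):
    if config.counts_path is None:
        log.info("no input tables given: simulating the default community "
                 "(seed %d)", config.seed)
        sim = synthetic.simulate_dataset(synthetic.make_default_spec(),
                                         seed=config.seed)
        return (sim.read_counts, sim.catalog, sim.metadata,
                sim.availability, sim.pellets, sim.covariates,
                sim.category_map)
    needed = {"catalog_path": config.catalog_path,
              "metadata_path": config.metadata_path}
    missing = [k for k, v in needed.items() if v is None]
    if missing:
        raise ValueError("counts_path given but missing: "
                         + ", ".join(missing))
    counts = read_table(config.counts_path, ReadCountTable)
    catalog = read_table(config.catalog_path, MOTUCatalog)
    metadata = read_table(config.metadata_path, SampleMetadata)
    avail = (read_table(config.availability_path, AvailabilityTable)
             if config.availability_path else None)
    pellets = (read_table(config.pellets_path, PelletCountTable)
               if config.pellets_path else None)
    cov = (read_table(config.covariates_path, CovariateTable)
           if config.covariates_path else None)
    cmap = None
    if config.category_map_path:
        mf = pd.read_csv(config.category_map_path, sep="\t")
        cmap = dict(zip(mf["motu_id"], mf["category"]))
    if config.run_selectivity and avail is None:
        raise ValueError("selectivity requested but no availability table "
                         "given (set run_selectivity: false or provide "
                         "availability_path)")
    if config.run_selectivity and cmap is None:
        raise ValueError("selectivity requires a category map "
                         "(category_map_path) matching the availability "
                         "categories")
    return counts, catalog, metadata, avail, pellets, cov, cmap


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage, writing one TSV per result plus a manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("thresholds: mammal %g%% share / %d bp / %d reads; plant "
             "%d reads / %g quantile / %g%% similarity / %g max RRA",
             100 * config.mammal_min_share, config.mammal_min_length,
             config.mammal_min_reads, config.plant_min_reads,
             config.qc_quantile, config.min_similarity, config.min_max_rra)
    (counts, catalog, metadata, avail, pellets, covariates,
     category_map) = _load_inputs(config)
    manifest: dict = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__, "pandas": pd.__version__,
        "seed": config.seed, "config_hash": config.config_hash(),
        "counts": {},
    }
    n_samples_in = metadata.frame["sample_id"].nunique()
    manifest["counts"]["samples_in"] = int(n_samples_in)

    # --- host species assignment -----------------------------------------
    assignments = host_id.assign_hosts(counts, catalog)
    write_table(assignments, out / "host_assignments.tsv")
    assigned = assignments.frame[assignments.frame["status"] == "assigned"]
    species = assigned.set_index("sample_id")["assigned_species"]
    manifest["counts"]["hosts_assigned"] = int(len(assigned))
    log.info("host ID: %d / %d samples assigned", len(assigned),
             len(assignments.frame))

    # --- plant replicate QC + diet profile --------------------------------
    plant = ReadCountTable(
        counts.frame[counts.frame["marker"] == "plant"])
    rank = config.collapse_rank
    cmap = category_map if rank == "category" else None
    profile, qc_report, motu_table = diet_quant.build_diet_profile(
        plant, catalog, threshold=config.qc_threshold, rank=rank,
        category_map=cmap, min_reads=config.plant_min_reads,
        knn_k=config.knn_k, min_similarity=config.min_similarity,
        min_max_rra=config.min_max_rra)
    # restrict to samples with an assigned host
    keep = profile.frame["sample_id"].isin(species.index)
    profile = DietProfile(profile.frame[keep])
    motu_table = motu_table[motu_table["sample_id"].isin(
        species.index)].reset_index(drop=True)
    write_table(qc_report, out / "replicate_qc.tsv")
    write_table(profile, out / "diet_profile.tsv")
    manifest["counts"]["replicates_kept"] = int(
        (qc_report.frame["status"] == "kept").sum())
    manifest["counts"]["samples_profiled"] = int(len(profile))
    log.info("diet QC: %d samples with >=2 concordant replicates and an "
             "assigned host", len(profile))

    # --- richness, Dunn, DNW ----------------------------------------------
    rich = niche_metrics.richness(motu_table, metadata, species=species)
    rich.to_csv(out / "richness.tsv", sep="\t", index=False)
    dunn_frames = []
    for (lsc, sea), grp in rich.groupby(["landscape", "season"]):
        ok = grp.dropna(subset=["species"])
        if ok["species"].nunique() >= 2:
            d = niche_metrics.dunn_bh(ok["S"], ok["species"])
            d.insert(0, "landscape", lsc)
            d.insert(1, "season", sea)
            dunn_frames.append(d)
    dunn = pd.concat(dunn_frames, ignore_index=True) if dunn_frames \
        else pd.DataFrame()
    dunn.to_csv(out / "dunn.tsv", sep="\t", index=False)
    dnw = niche_metrics.dnw_table(profile, metadata, species)
    dnw.to_csv(out / "dnw.tsv", sep="\t", index=False)

    # --- ordination per landscape x season --------------------------------
    meta_small = metadata.frame[["sample_id", "landscape", "season"]]
    joined = profile.frame.merge(meta_small, on="sample_id")
    joined["species"] = joined["sample_id"].map(species)
    pair_rows, vec_rows, score_rows, eig_rows = [], [], [], []
    for (lsc, sea), grp in joined.groupby(["landscape", "season"]):
        sub = DietProfile(grp[["sample_id"] + profile.taxa]
                          .reset_index(drop=True))
        labels = grp["species"].to_numpy()
        if len(sub) < 5 or len(set(labels)) < 2:
            continue
        res = partitioning.ordinate(sub, labels, n_perm=config.n_perm,
                                    seed=config.seed)
        pt = res.pair_tests.copy()
        pt.insert(0, "landscape", lsc)
        pt.insert(1, "season", sea)
        pt["letters_a"] = pt["species_a"].map(res.letters)
        pt["letters_b"] = pt["species_b"].map(res.letters)
        pair_rows.append(pt)
        tv = res.taxon_vectors.copy()
        tv.insert(0, "landscape", lsc)
        tv.insert(1, "season", sea)
        vec_rows.append(tv)
        sc = pd.DataFrame(res.scores[:, :2], columns=["axis1", "axis2"])
        sc.insert(0, "sample_id", res.sample_ids)
        sc.insert(1, "landscape", lsc)
        sc.insert(2, "season", sea)
        score_rows.append(sc)
        eig_rows.append(pd.DataFrame({
            "landscape": lsc, "season": sea,
            "axis": np.arange(1, len(res.eigenvalues) + 1),
            "eigenvalue": res.eigenvalues}))
    pair_tests = pd.concat(pair_rows, ignore_index=True) if pair_rows \
        else pd.DataFrame()
    pair_tests.to_csv(out / "pairtests.tsv", sep="\t", index=False)
    if vec_rows:
        pd.concat(vec_rows, ignore_index=True).to_csv(
            out / "vectors.tsv", sep="\t", index=False)
    if score_rows:
        pd.concat(score_rows, ignore_index=True).to_csv(
            out / "scores.tsv", sep="\t", index=False)
    if eig_rows:
        pd.concat(eig_rows, ignore_index=True).to_csv(
            out / "eigenvalues.tsv", sep="\t", index=False)

    # --- overlap + selectivity --------------------------------------------
    overlaps = niche_metrics.overlap_table(profile, metadata, species)
    write_table(overlaps, out / "overlap.tsv")
    niche_metrics.overlap_summary(overlaps).to_csv(
        out / "overlap_summary.tsv", sep="\t", index=False)
    if config.run_selectivity and avail is not None:
        cat_profile = profile
        if category_map is not None and rank != "category":
            collapsed = diet_quant.collapse_taxa(
                motu_table, catalog, rank="category",
                category_map=category_map, fallback="other")
            cat_profile = diet_quant.to_rra(collapsed)
        sel = niche_metrics.selectivity_table(cat_profile, avail,
                                              metadata, species)
        sel.to_csv(out / "selectivity.tsv", sep="\t", index=False)
        niche_metrics.selectivity_summary(sel).to_csv(
            out / "selectivity_summary.tsv", sep="\t", index=False)

    # --- drivers of overlap -----------------------------------------------
    coef = None
    if config.run_drivers and covariates is not None:
        coef, skipped, flags = drivers.drivers_analysis(
            overlaps, covariates, min_n=config.min_transects_betareg)
        coef.to_csv(out / "betareg_fits.tsv", sep="\t", index=False)
        skipped.to_csv(out / "betareg_skipped.tsv", sep="\t", index=False)
        flags.to_csv(out / "collinearity.tsv", sep="\t", index=False)
        if len(coef):
            sig = coef[coef["significant"]]
            sig.to_csv(out / "significant_coefficients.tsv", sep="\t",
                       index=False)

    manifest["counts"]["overlap_records"] = int(len(overlaps.frame))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(out_dir=out, manifest=manifest, profile=profile,
                          assignments=assignments.frame,
                          overlaps=overlaps.frame,
                          tables={"richness": rich, "dunn": dunn,
                                  "dnw": dnw, "pair_tests": pair_tests,
                                  "betareg": coef})
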