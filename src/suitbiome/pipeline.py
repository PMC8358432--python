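"""End-to-end orchestration: simulate -> filter -> diversity -> rarefaction
-> differential abundance -> strain matching -> AMR -> consolidated report.

All randomness flows from one master seed through per-stage derived seeds
(stable hash of the stage name), so adding or re-ordering stages never
perturbs another stage's draws and a rerun with the same config is
byte-identical. Stage wall-clock timings live on the in-memory RunReport
only; serialized outputs are deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import amr as amr_mod
from . import diff_abundance as da_mod
from . import diversity as div_mod
from . import profiles as prof_mod
from . import rarefaction as rare_mod
from . import simulate as sim_mod
from . import strain_match as strain_mod

__all__ = ["RunConfig", "RunReport", "run_pipeline", "consolidated_report",
           "derive_seed"]

STAGES = ("simulate", "filter", "diversity", "rarefaction",
          "diff_abundance", "strains", "amr", "report")


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "suitbiome_out"
    sim: sim_mod.SimulationConfig = field(default_factory=sim_mod.SimulationConfig)
    filters: prof_mod.FilterConfig = field(default_factory=prof_mod.FilterConfig)
    da: da_mod.DAConfig = field(default_factory=da_mod.DAConfig)
    ani: strain_mod.AniParams = field(default_factory=strain_mod.AniParams)
    min_ani: float = 99.0
    min_coverage: float = 0.5
    n_background_genomes: int = 40
    genome_length: int = 150_000
    clone_groups: tuple = ()        # CloneGroupSpec; default scenario if empty
    rarefaction_draws: int = 16
    da_group_by: str = "pma"
    pma_only: bool = True
    suit_subset: str | None = "EMU"
    exclude_kitome: bool = False
    embed: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "sim" in kwargs:
            kwargs["sim"] = sim_mod.SimulationConfig(**kwargs["sim"])
        if "filters" in kwargs:
            kwargs["filters"] = prof_mod.FilterConfig(**kwargs["filters"])
        if "da" in kwargs:
            kwargs["da"] = da_mod.DAConfig(**kwargs["da"])
        if "ani" in kwargs:
            kwargs["ani"] = strain_mod.AniParams(**kwargs["ani"])
        return cls(**kwargs)

    def echo(self) -> dict:
        return json.loads(json.dumps(dataclasses.asdict(self), default=str))


@dataclass
class RunReport:
    config: dict
    version: str
    stages: dict = field(default_factory=dict)   # name -> summary dict
    timings: dict = field(default_factory=dict)  # name -> seconds (not serialized)

    def to_dict(self) -> dict:
        return {"version": self.version, "config": self.config,
                "stages": self.stages}


def _default_clone_groups(genome_length: int) -> tuple:
    """Two planted shared strains mirroring the study's two MAG groups:
    a 7-member group spread over several sets and a 5-member group
    confined to one suit set."""
    g7 = sim_mod.CloneGroupSpec(
        group_id="groupA", n_members=7, divergence=0.005,
        genome_length=genome_length,
        member_sites=((6, "R", "WJ"), (6, "L", "IG"), (6, "L", "OG"),
                      (1, "L", "WJ"), (1, "R", "OG"), (3, "L", "WJ"),
                      (4, "R", "IG")))
    g5 = sim_mod.CloneGroupSpec(
        group_id="groupB", n_members=5, divergence=0.005,
        genome_length=genome_length,
        member_sites=((7, "R", "WJ"), (7, "R", "IG"), (7, "R", "OG"),
                      (7, "L", "WJ"), (7, "L", "IG")))
    return (g7, g5)


def _select(meta: pd.DataFrame, config: RunConfig, controls: bool = False) -> pd.Index:
    sel = meta["component"] != "" if controls else meta["component"] != "CONTROL"
    if config.pma_only:
        sel &= meta["pma"].astype(bool)
    if config.suit_subset:
        sel &= (meta["suit_type"] == config.suit_subset) | (meta["component"] == "CONTROL")
    return meta.index[sel]


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in dependency order, writing outputs to outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.echo(), version=__version__)

    def _stage(name):
        t0 = time.perf_counter()

        def done(**summary):
            report.timings[name] = time.perf_counter() - t0
            report.stages[name] = summary
        return done

    # ---- simulate ----------------------------------------------------
    done = _stage("simulate")
    sim_cfg = dataclasses.replace(config.sim,
                                  seed=derive_seed(config.seed, "simulate"))
    data = sim_mod.simulate_profiles(sim_cfg)
    meta = data.metadata
    if config.pma_only and not meta["pma"].any():
        raise ValueError("pma_only requested but the dataset has no PMA samples")
    matrix = prof_mod.ProfileMatrix(counts=data.counts, markers=data.markers,
                                    metadata=meta, taxa=data.taxa)
    meta.to_csv(outdir / "metadata.tsv", sep="\t", index=False, na_rep="NA")
    prof_mod.write_profiles(matrix, outdir / "profiles.tsv")
    done(n_samples=int(len(meta)), n_taxa=int(matrix.counts.shape[1]),
         n_controls=int((meta["component"] == "CONTROL").sum()))

    # ---- filter ------------------------------------------------------
    done = _stage("filter")
    kitome_report, matrix = prof_mod.flag_kitome(
        matrix, meta, config.filters.kitome_min_reads)
    filtered = prof_mod.filter_by_markers(matrix, config.filters.min_unique_markers)
    filtered = prof_mod.filter_by_abundance(filtered, config.filters.min_rel_abundance)
    if config.exclude_kitome:
        keep = [t for t in filtered.taxon_ids
                if not kitome_report.present_in_controls.get(t, False)]
        filtered = dataclasses.replace(
            filtered, counts=filtered.counts[keep],
            markers=filtered.markers[keep] if filtered.markers is not None else None)
    kitome_report.flagged.to_csv(outdir / "kitome.tsv", sep="\t", index=False)
    prof_mod.write_profiles(filtered, outdir / "profiles_filtered.tsv")
    done(taxa_in=int(matrix.counts.shape[1]), taxa_out=int(filtered.counts.shape[1]),
         kitome_flagged=int(len(kitome_report.flagged)))

    # ---- diversity ---------------------------------------------------
    done = _stage("diversity")
    sel = _select(meta, config, controls=True)
    suit_sel = [s for s in sel if meta.loc[s, "component"] != "CONTROL"]
    sub = filtered.subset_samples(sel).drop_empty_taxa()
    alpha = sub.counts.loc[suit_sel].apply(
        lambda r: div_mod.shannon_entropy(r.to_numpy()), axis=1)
    dmat = div_mod.jsd_matrix(sub.counts)
    triplets = div_mod.build_triplets(meta.loc[suit_sel])
    wb = div_mod.within_between_comparison(dmat, triplets)
    # the marker filter reduces low-biomass controls to kitome taxa only,
    # so control-vs-component structure is assessed on the raw profiles
    raw_dmat = div_mod.jsd_matrix(matrix.counts.loc[sel])
    ctrl_cmp = div_mod.control_distance_comparison(raw_dmat, meta)
    rich = prof_mod.richness(sub.counts.loc[suit_sel])
    rich_groups = {c: rich[meta.loc[suit_sel, "component"] == c].to_numpy()
                   for c in ("WJ", "IG", "OG")}
    anova_f, anova_p = div_mod.richness_anova(rich_groups)
    dmat.to_frame().to_csv(outdir / "jsd_matrix.tsv", sep="\t")
    alpha.rename("shannon").rename_axis("sample_id").to_csv(
        outdir / "alpha_diversity.tsv", sep="\t")
    comparisons = {
        "within_between": wb.to_dict(),
        **{k: v.to_dict() for k, v in ctrl_cmp.items()},
        "richness_anova": {"F": anova_f, "p": anova_p},
    }
    with open(outdir / "comparisons.json", "w") as fh:
        json.dump(comparisons, fh, indent=2, sort_keys=True)
    if config.embed:
        coords = div_mod.embed(dmat, derive_seed(config.seed, "embed"))
        coords.rename_axis("sample_id").to_csv(outdir / "embedding.tsv", sep="\t")
    done(n_triplets=len(triplets), mean_within=wb.mean_within,
         mean_between=wb.mean_between, welch_p=wb.p_value)

    # ---- rarefaction -------------------------------------------------
    done = _stage("rarefaction")
    suit_meta = meta.loc[suit_sel]
    groups = {g: list(idx) for g, idx in suit_meta.groupby("set_id").groups.items()}
    rare_seed = derive_seed(config.seed, "rarefaction")
    curves = {}
    for mode in ("union", "intersection"):
        curve = rare_mod.rarefy(sub.counts.loc[suit_sel], groups, mode=mode,
                                n_draws=config.rarefaction_draws, seed=rare_seed)
        rare_mod.fit_log_model(curve)
        curves[mode] = curve
    prev = rare_mod.prevalence_report(sub.counts.loc[suit_sel],
                                      config.filters.prevalence_core)
    pd.concat([c.to_frame() for c in curves.values()]).to_csv(
        outdir / "rarefaction.tsv", sep="\t", index=False)
    with open(outdir / "rarefaction_fit.json", "w") as fh:
        json.dump({m: {"a": c.fit[0], "b": c.fit[1], "rss": c.fit_rss,
                       "flattened": c.flattened} for m, c in curves.items()},
                  fh, indent=2, sort_keys=True)
    prev.prevalence.rename_axis("taxon_id").to_csv(outdir / "prevalence.tsv", sep="\t")
    done(union_total=float(curves["union"].mean[-1]),
         intersection_asymptote=float(curves["intersection"].mean[-1]),
         union_flattened=curves["union"].flattened,
         intersection_flattened=curves["intersection"].flattened,
         core_size=len(prev.core), high_prevalence=len(prev.high_prevalence))

    # ---- differential abundance -------------------------------------
    done = _stage("diff_abundance")
    da_meta = meta.loc[meta["component"] != "CONTROL"]
    if config.da_group_by != "pma" and config.pma_only:
        da_meta = da_meta[da_meta["pma"].astype(bool)]
    if config.suit_subset:
        da_meta = da_meta[da_meta["suit_type"] == config.suit_subset]
    da_counts = filtered.counts.loc[da_meta.index]
    da_counts = da_counts.loc[:, (da_counts > 0).any(axis=0)]
    da_cfg = dataclasses.replace(config.da,
                                 seed=derive_seed(config.seed, "diff_abundance"))
    da_table = da_mod.run_da(da_counts, da_meta[config.da_group_by].to_numpy(),
                             da_cfg)
    da_table.to_csv(outdir / "differential_abundance.tsv", sep="\t")
    done(group_by=config.da_group_by, n_taxa=int(len(da_table)),
         n_called=int(da_table["called"].sum()))

    # ---- strains -----------------------------------------------------
    done = _stage("strains")
    clone_groups = config.clone_groups or _default_clone_groups(config.genome_length)
    sim_genomes = sim_mod.simulate_genomes(
        clone_groups, config.n_background_genomes,
        seed=derive_seed(config.seed, "strains"),
        genome_length=config.genome_length)
    retained, rejections = strain_mod.qc_gate(sim_genomes.genomes)
    edges = strain_mod.all_pairs_ani(retained, config.ani)
    kept = strain_mod.filter_edges(edges, config.min_ani, config.min_coverage)
    comps = strain_mod.strain_components(retained, kept, metadata=meta)
    pd.DataFrame([dataclasses.asdict(e) for e in kept]).to_csv(
        outdir / "ani_edges.tsv", sep="\t", index=False)
    comp_json = [{
        "members": c.members, "sites": [list(s) for s in c.sites],
        "fully_connected": c.fully_connected,
        "spans_multiple_samples": c.spans_multiple_samples,
        "in_control": c.in_control,
    } for c in comps]
    with open(outdir / "strain_components.json", "w") as fh:
        json.dump(comp_json, fh, indent=2, sort_keys=True)
    multi = [c for c in comps if len(c.members) > 1]
    done(n_genomes=len(sim_genomes.genomes), n_retained=len(retained),
         n_rejected=len(rejections), n_edges_kept=len(kept),
         n_multi_components=len(multi),
         multi_component_sizes=sorted((len(c.members) for c in multi), reverse=True))

    # ---- AMR ---------------------------------------------------------
    done = _stage("amr")
    amr_records = sim_mod.simulate_amr(meta, seed=derive_seed(config.seed, "amr"))
    totals = meta["total_reads"]
    amr_rpkm = amr_mod.rpkm_table(amr_records, totals)
    incidence = amr_mod.class_incidence(amr_records)
    amr_sel = meta.loc[amr_records["sample_id"].unique()]
    amr_groups = {g: list(idx) for g, idx
                  in amr_sel.groupby("set_id").groups.items()}
    amr_curve = amr_mod.amr_rarefaction(
        amr_records, amr_groups, n_draws=config.rarefaction_draws,
        seed=derive_seed(config.seed, "amr_rarefaction"))
    rare_mod.fit_log_model(amr_curve)
    amr_rpkm.to_csv(outdir / "amr_rpkm.tsv", sep="\t", index=False)
    incidence.rename_axis("gene_class").to_csv(outdir / "amr_incidence.tsv", sep="\t")
    amr_curve.to_frame().to_csv(outdir / "amr_rarefaction.tsv", sep="\t", index=False)
    done(n_genes=int(amr_records["gene_id"].nunique()),
         gene_richness_endpoint=float(amr_curve.mean[-1]),
         curve_flattened=amr_curve.flattened,
         n_classes=int(len(incidence)))

    # ---- report ------------------------------------------------------
    done = _stage("report")
    done(stages_completed=len(report.stages))
    consolidated = consolidated_report(report.stages)
    with open(outdir / "report.json", "w") as fh:
        json.dump(consolidated, fh, indent=2, sort_keys=True)
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    return report


def consolidated_report(stage_outputs: dict) -> dict:
    """Single JSON object with the headline analysis results per stage."""
    if not stage_outputs:
        raise ValueError("no stage outputs to consolidate")
    headline = {}
    if "diversity" in stage_outputs:
        d = stage_outputs["diversity"]
        headline["beta_diversity"] = {
            "mean_within_set_jsd": d["mean_within"],
            "mean_between_set_jsd": d["mean_between"],
            "welch_p": d["welch_p"], "n_triplets": d["n_triplets"]}
    if "rarefaction" in stage_outputs:
        r = stage_outputs["rarefaction"]
        headline["core_community"] = {
            "core_size": r["core_size"],
            "intersection_asymptote": r["intersection_asymptote"],
            "union_total": r["union_total"],
            "union_flattened": r["union_flattened"],
            "intersection_flattened": r["intersection_flattened"]}
    if "diff_abundance" in stage_outputs:
        headline["differential_abundance"] = dict(stage_outputs["diff_abundance"])
    if "strains" in stage_outputs:
        s = stage_outputs["strains"]
        headline["strains"] = {
            "n_multi_components": s["n_multi_components"],
            "multi_component_sizes": s["multi_component_sizes"],
            "n_retained_genomes": s["n_retained"]}
    if "amr" in stage_outputs:
        headline["amr"] = dict(stage_outputs["amr"])
    if "filter" in stage_outputs:
        headline["kitome_flagged"] = stage_outputs["filter"]["kitome_flagged"]
    return headline
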