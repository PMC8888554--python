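"""End-to-end orchestration of the holobiont depth-gradient analysis.

`run_full_pipeline` simulates (or loads) the per-species data sets and
executes the stages in order: metabolome filtering, depth response,
ecotype detection, community statistics, the OPLS model battery over
experiment x species x filter combinations, the consensus co-occurrence
network, and the inter-omics comparisons. Every stage writes its result
files under the output directory and logs the thresholds it applied;
the whole run is a pure function of the configuration (seeded), so a
rerun with the same config reproduces every output byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import community as comm
from . import depth as depthmod
from . import ecotypes as ecomod
from . import interomics as inter
from . import io as hio
from . import metabolome as metab
from . import network as netmod
from . import opls as oplsmod
from . import synthetic as synth
from .config import RunConfig

log = logging.getLogger("holodepth")


@dataclass
class ResultBundle:
    """Per-stage outputs keyed by stage name, plus provenance."""

    stages: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {"provenance": self.provenance, "stages": self.stages}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _profile_of(species: str) -> str:
    return "LMA" if species.endswith("LMA") else "HMA"


def simulate_dataset(config: RunConfig, outdir: Path) -> dict:
    """Generate metadata, ASV tables, sequences and metabolomes for every
    species and experiment; write them and return the in-memory objects."""
    data: dict = {"species": {}}
    for sp_index, species in enumerate(config.species):
        seed = (config.seed * 31 + sp_index) % (2**31)
        meta = synth.simulate_metadata(
            config.n_samples_per_species,
            collinearity=config.metadata_collinearity,
            seed=seed,
            species=species,
        )
        meta = meta.assign(sample_id=[f"{species[:2]}{i:03d}"
                                      for i in range(len(meta))])
        profile = _profile_of(species)
        n_asvs = config.n_asvs_lma if profile == "LMA" else config.n_asvs_hma
        asv, seqs, truth = synth.simulate_asv_table(
            meta,
            profile=profile,
            n_asvs=n_asvs,
            frac_responsive=config.frac_responsive_asv,
            n_sister_pairs=config.n_sister_pairs,
            effect_size=config.asv_effect_size,
            identity_target=config.sister_min_identity,
            seed=seed,
            n_assoc_pairs=5 if sp_index == 0 else 0,
        )
        metabolomes = {}
        for mode_index, mode in enumerate(config.experiments):
            mtab, mtruth = synth.simulate_metabolome(
                meta,
                n_features=config.n_features,
                n_pc_groups=config.n_pc_groups,
                frac_void=config.frac_void,
                frac_high_cv=config.frac_high_cv,
                frac_responsive=config.frac_responsive_feature,
                n_qc=config.n_qc,
                seed=(seed + 101 * mode_index) % (2**31),
                mode=tuple(mode),
            )
            metabolomes[tuple(mode)] = (mtab, mtruth)
        data["species"][species] = {
            "metadata": meta,
            "asv": asv,
            "sequences": seqs,
            "truth": truth,
            "metabolomes": metabolomes,
        }
        hio.write_metadata(meta, outdir / f"metadata_{species}.tsv")
        hio.write_asv_table(asv, outdir / f"asv_{species}.tsv")
        hio.write_sequences(seqs, outdir / f"sequences_{species}.fasta")
        hio.write_truth(truth, outdir / f"truth_asv_{species}.json")
        for (chrom, pol), (mtab, mtruth) in metabolomes.items():
            stem = f"{chrom}_{pol}_{species}"
            hio.write_feature_table(mtab, outdir / f"metabolome_{stem}.csv")
            hio.write_truth(mtruth, outdir / f"truth_metabolome_{stem}.json")
    return data


def _stage_filtering(config: RunConfig, data: dict, outdir: Path) -> dict:
    out: dict = {}
    for species, d in data["species"].items():
        for mode, (mtab, _) in d["metabolomes"].items():
            chrom, pol = mode
            log.info(
                "filtering %s %s/%s: void RT < %.0f s, QC CV > %.2f",
                species, chrom, pol, config.void_rt_max, config.qc_cv_max,
            )
            cleaned, rep_c = metab.filter_cleaned(
                mtab, void_rt_max=config.void_rt_max, qc_cv_max=config.qc_cv_max
            )
            pc, rep_p = metab.filter_pc_group(cleaned)
            ion, rep_i = metab.filter_ion(cleaned)
            key = f"{chrom}_{pol}_{species}"
            d.setdefault("filtered", {})[mode] = {
                "cleaned": cleaned, "pc_group": pc, "ion": ion,
            }
            out[key] = {
                "cleaned": len(cleaned.feature_ids),
                "pc_group": len(pc.feature_ids),
                "ion": len(ion.feature_ids),
                "removed_void": len(rep_c.removed["void"]),
                "removed_qc_cv": len(rep_c.removed["qc_cv"]),
            }
    hio.write_json(out, outdir / "filter_reports.json")
    return out


def _stage_depth_response(config: RunConfig, data: dict, outdir: Path) -> dict:
    out: dict = {}
    for species, d in data["species"].items():
        depths = d["metadata"]["depth"].to_numpy()
        rel = d["asv"].relative_abundance().data.T  # ASVs x samples
        trends = depthmod.classify_depth_trends(rel, depths, alpha=config.trend_alpha)
        ttests = depthmod.water_mass_ttest(rel, depths, split=config.water_mass_split)
        common = depthmod.classify_common(d["asv"], threshold=config.common_threshold)
        summary = depthmod.summarize_depth_response(trends, d["asv"])
        d["trends"], d["ttests"], d["common"] = trends, ttests, common
        trends.to_csv(outdir / f"depth_trends_{species}.tsv", sep="\t")
        ttests.to_csv(outdir / f"water_mass_ttest_{species}.tsv", sep="\t")
        out[species] = {
            "n_increasing": summary.n_increasing,
            "n_decreasing": summary.n_decreasing,
            "fraction_responsive": summary.fraction_responsive,
            "mean_abundance_responsive": summary.mean_abundance_responsive,
            "n_common": len(common.common_ids),
            "common_read_fraction": common.read_fraction,
        }
        log.info("depth response %s: %s", species, out[species])
    hio.write_json(out, outdir / "depth_response.json")
    return out


def _stage_ecotypes(config: RunConfig, data: dict, outdir: Path) -> dict:
    out: dict = {}
    for species, d in data["species"].items():
        identity = ecomod.pairwise_identity(d["sequences"])
        pairs = ecomod.find_sister_pairs(
            identity,
            d["trends"],
            ttest_results=d["ttests"],
            min_identity=config.sister_min_identity,
            basis="correlation",
            stringency="raw_p",
            alpha=config.trend_alpha,
        )
        frame = ecomod.sister_pairs_frame(pairs)
        frame.to_csv(outdir / f"sister_pairs_{species}.tsv", sep="\t", index=False)
        d["sister_pairs"] = pairs
        out[species] = {"n_pairs": len(pairs)}
    hio.write_json(out, outdir / "ecotypes.json")
    return out


def _stage_community(config: RunConfig, data: dict, outdir: Path) -> dict:
    out: dict = {}
    for species, d in data["species"].items():
        asv, meta = d["asv"], d["metadata"]
        alpha = comm.alpha_diversity(asv)
        alpha.to_csv(outdir / f"alpha_{species}.tsv", sep="\t")
        dist = comm.bray_curtis(asv.relative_abundance())
        hio.write_square_tsv(dist.data, outdir / f"bray_curtis_{species}.tsv")
        perm = comm.permanova(
            dist, meta["water_mass"].to_numpy(),
            n_perm=config.permanova_permutations, seed=config.seed,
        )
        scores = comm.ordinate(dist, k=2)
        scores.to_csv(outdir / f"ordination_{species}.tsv", sep="\t")
        d["ordination"] = scores
        d["bray_curtis"] = dist
        env = meta.set_index("sample_id")[
            ["latitude", "longitude", "depth", "salinity", "temperature", "year"]
        ]
        fits = comm.envfit(scores, env, n_perm=config.envfit_permutations,
                           seed=config.seed)
        kept, vifs = comm.vif_screen(env, threshold=config.vif_threshold)
        best, tscores = comm.select_transformation(asv, meta["depth"].to_numpy())
        _, labels = comm.upgma_cluster(dist, n_clusters=2)
        out[species] = {
            "alpha_mean_richness": float(alpha["richness"].mean()),
            "permanova_water_mass": {
                "pseudo_f": perm.pseudo_f, "r2": perm.r2, "p": perm.p,
            },
            "envfit": {
                f.variable: {"r2": f.r2, "p": f.p, "direction": list(f.direction)}
                for f in fits
            },
            "vif_retained": kept,
            "vif": vifs,
            "best_transformation": best,
            "transformation_scores": tscores,
            "upgma_labels": {str(k): int(v) for k, v in labels.items()},
        }
    # Cross-species PERMANOVA on the pooled table.
    tables = [d["asv"].relative_abundance().data for d in data["species"].values()]
    pooled = pd.concat(tables, axis=0).fillna(0.0)
    pooled_rel = pooled.div(pooled.sum(axis=1).where(lambda s: s > 0, 1.0), axis=0)
    labels = np.concatenate(
        [[sp] * len(d["metadata"]) for sp, d in data["species"].items()]
    )
    from .tables import AsvTable

    pooled_dist = comm.bray_curtis(AsvTable(pooled_rel, kind="relabund"))
    perm_species = comm.permanova(
        pooled_dist, labels, n_perm=config.permanova_permutations, seed=config.seed
    )
    out["pooled_species_permanova"] = {
        "pseudo_f": perm_species.pseudo_f, "r2": perm_species.r2, "p": perm_species.p,
    }
    hio.write_json(out, outdir / "community.json")
    return out


def _stage_opls(config: RunConfig, data: dict, outdir: Path) -> dict:
    records = []
    for species, d in data["species"].items():
        y = d["metadata"]["depth"].to_numpy(dtype=float)
        for mode, filtered in d.get("filtered", {}).items():
            chrom, pol = mode
            for filter_name in config.filters:
                table = filtered[filter_name]
                x = np.log1p(table.intensities[table.study_columns]
                             .to_numpy(dtype=float).T)
                if x.shape[1] < 2:
                    records.append({
                        "experiment": f"{chrom}_{pol}", "species": species,
                        "filter": filter_name, "n_features": x.shape[1],
                        "r2x": np.nan, "r2y": np.nan, "q2": np.nan,
                        "pq2": np.nan, "verdict": "empty",
                    })
                    continue
                model = oplsmod.fit_opls_with_validation(
                    x, y,
                    n_ortho=config.opls_n_ortho,
                    k=config.opls_cv_folds,
                    n_perm=config.opls_permutations,
                    seed=config.seed,
                    feature_ids=table.feature_ids,
                )
                records.append({
                    "experiment": f"{chrom}_{pol}", "species": species,
                    "filter": filter_name, "n_features": x.shape[1],
                    "r2x": model.r2x, "r2y": model.r2y,
                    "q2": model.q2, "pq2": model.pq2,
                    "verdict": model.meta["verdict"],
                })
                if mode == tuple(config.experiments[0]) and filter_name == "cleaned":
                    vip = pd.DataFrame(
                        {"feature": table.feature_ids, "vip": model.vip}
                    ).sort_values(["vip", "feature"], ascending=[False, True])
                    vip.to_csv(outdir / f"vip_{chrom}_{pol}_{species}.tsv",
                               sep="\t", index=False)
                    d["opls_cleaned_model"] = model
    battery = pd.DataFrame(records)
    battery.to_csv(outdir / "opls_battery.tsv", sep="\t", index=False)
    n_good = int((battery["verdict"] == "good").sum())
    n_rejected = int((battery["verdict"] == "rejected").sum())
    log.info("OPLS battery: %d models, %d good, %d rejected",
             len(battery), n_good, n_rejected)
    return {"n_models": len(battery), "n_good": n_good, "n_rejected": n_rejected}


def _stage_network(config: RunConfig, data: dict, outdir: Path) -> dict:
    species = config.species[0]
    d = data["species"][species]
    filtered, sparsity, n_eff = netmod.prevalence_filter(
        d["asv"], min_samples=config.prevalence_min_samples
    )
    depths = d["metadata"]["depth"].to_numpy()
    np_ = config.network_permutations
    seed = config.seed
    results = [
        netmod.correlation_assoc(filtered, "pearson", n_perm=np_, seed=seed),
        netmod.correlation_assoc(filtered, "spearman", n_perm=np_, seed=seed),
        netmod.sparcc_assoc(filtered, n_bootstrap=config.sparcc_bootstraps, seed=seed),
        netmod.local_similarity_assoc(filtered, depths, n_perm=np_, seed=seed),
        netmod.mic_assoc(filtered, n_perm=np_, seed=seed),
    ]
    net = netmod.consensus(
        results, p_max=config.edge_p_max, min_votes=config.consensus_min_votes,
        sparsity=sparsity, n_eff=n_eff,
    )
    hio.write_network(net, outdir / "network_edges.tsv", outdir / "network.graphml")
    for r in results:
        hio.write_square_tsv(r.statistic, outdir / f"assoc_{r.method}_stat.tsv")
        hio.write_square_tsv(r.p, outdir / f"assoc_{r.method}_p.tsv")
    d["network"] = net
    out = {
        "species": species,
        "n_asvs_after_prevalence": len(filtered.asv_ids),
        "sparsity": sparsity,
        "n_nodes": net.graph.number_of_nodes(),
        "n_edges": net.graph.number_of_edges(),
    }
    hio.write_json(out, outdir / "network_stats.json")
    return out


def _stage_interomics(config: RunConfig, data: dict, outdir: Path) -> dict:
    species = config.species[0]
    d = data["species"][species]
    mode = tuple(config.experiments[0])
    cleaned = d["filtered"][mode]["cleaned"]
    study = cleaned.intensities[cleaned.study_columns]
    m_dist = inter.metabolome_distance(study)
    b_dist = d["bray_curtis"]
    mantel = inter.mantel_test(b_dist, m_dist, n_perm=config.mantel_permutations,
                               seed=config.seed)
    m_scores = comm.ordinate(m_dist, k=2)
    proc = inter.procrustes_test(
        d["ordination"], m_scores, n_perm=config.procrustes_permutations,
        seed=config.seed,
    )
    # Compound groups: depth-increasing vs depth-decreasing representative
    # features of the pc_group table (proxies for the bioactive compound
    # families tracked in the study).
    pc_table = d["filtered"][mode]["pc_group"]
    signals = pc_table.intensities[pc_table.study_columns]
    trends = depthmod.classify_depth_trends(
        np.log1p(signals), d["metadata"]["depth"].to_numpy()
    )
    inc = trends.index[trends["trend_class"] == "increasing"][:4]
    dec = trends.index[trends["trend_class"] == "decreasing"][:4]
    groups = {}
    if len(inc):
        groups["depth_increasing"] = list(inc)
    if len(dec):
        groups["depth_decreasing"] = list(dec)
    links = None
    if groups:
        links = inter.link_asvs_to_compounds(
            d["asv"], np.log1p(signals), groups, top_k=config.link_top_k
        )
    out = {
        "mantel": {"r": mantel.r, "p": mantel.p},
        "procrustes": {"m2": proc.m2, "p": proc.p},
        "compound_groups": groups,
        "link_intersection": sorted(links.intersection) if links else [],
        "link_top_counts": {
            g: {str(k): int(v) for k, v in s.items()}
            for g, s in (links.group_top_sets.items() if links else [])
        },
    }
    hio.write_json(out, outdir / "interomics.json")
    return out


STAGES = (
    ("filtering", _stage_filtering),
    ("depth_response", _stage_depth_response),
    ("ecotypes", _stage_ecotypes),
    ("community", _stage_community),
    ("opls", _stage_opls),
    ("network", _stage_network),
    ("interomics", _stage_interomics),
)


def run_full_pipeline(config: RunConfig, outdir) -> ResultBundle:
    """Execute every stage on a seeded synthetic holobiont data set.

    Writes all stage outputs under ``outdir`` and returns the bundle.
    A stage failure aborts the run with the stage name and cause.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = ResultBundle(
        provenance={"config_hash": config.hash(), "seed": config.seed}
    )
    config.to_yaml(outdir / "config.yaml")
    try:
        data = simulate_dataset(config, outdir)
    except Exception as exc:
        raise StageError("simulate", exc) from exc
    bundle.stages["simulate"] = {
        sp: {"n_samples": len(d["metadata"]), "n_asvs": len(d["asv"].asv_ids)}
        for sp, d in data["species"].items()
    }
    for name, fn in STAGES:
        log.info("stage %s", name)
        try:
            bundle.stages[name] = fn(config, data, outdir)
        except Exception as exc:
            raise StageError(name, exc) from exc
    hio.write_json(bundle.summary(), outdir / "bundle.json")
    return bundle
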