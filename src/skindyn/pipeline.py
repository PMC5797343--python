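"""End-to-end pipeline: simulate -> qc -> metrics -> beta -> network ->
netdyn -> sourcetrack, with one config, fan-out seeding and a consolidated
JSON report.

Per-stage seeds are derived from the global seed as
``(seed * 2654435761 + crc32(stage_name)) mod 2**31``, so any stage can be
re-run in isolation and reproduce its in-pipeline behaviour exactly.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .beta_diversity import (anosim, correlate_with_occupancy, permanova,
                             relation_distance_summary, time_decay,
                             weighted_unifrac)
from .community_metrics import cv_profiles, mean_sd_correlation, shannon_per_sample
from .data_io import (CountTable, SampleMetadata, write_count_table,
                      write_matrix, write_metadata, write_taxonomy, write_tree)
from .network_inference import StarsSettings, fit_network, network_summaries
from .network_structure import gcd_matrix, mds_embed, natural_connectivity, \
    robustness_curve
from .preprocess import (collapse_to_genus, filter_taxa, remove_contaminants,
                         to_relative_abundance, top_genera)
from .source_tracking import SamplerSettings, cohabitant_aggregation, \
    run_seasonal_design
from .synthetic_cohort import CohortConfig, simulate_cohort, \
    simulate_negative_controls

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "metrics", "beta", "network", "netdyn",
          "sourcetrack")

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """All module settings plus stage toggles and the global seed."""

    out_dir: str = "skindyn_out"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_controls: int = 4
    contaminant_threshold: float = 0.05
    min_total_reads: int = 150
    min_prevalence: float = 0.0
    top_genus_threshold: float = 0.01
    n_permutations: int = 999
    normalized_unifrac: bool = False
    stars: StarsSettings = field(default_factory=StarsSettings)
    edge_threshold: float = 0.05
    network_group_by: tuple[str, ...] = ("individual",)
    sampler: SamplerSettings = field(default_factory=SamplerSettings)
    sourcetrack_min_prevalence: float = 0.10
    sourcetrack_seasons: tuple[int, ...] | None = None

    def stage_seed(self, stage: str) -> int:
        return int((self.seed * 2654435761 + zlib.crc32(stage.encode()))
                   % 2**31)


def validate_config(config: PipelineConfig) -> list[str]:
    """Exhaustive validation; returns the (possibly empty) list of errors."""
    errors = []
    for s in config.stages:
        if s not in STAGES:
            errors.append(f"unknown stage {s!r}")
    try:
        config.cohort.validate()
    except ValueError as e:
        errors.append(f"cohort config: {e}")
    if not 0.0 < config.stars.min_lambda_ratio < 1.0:
        errors.append("StarsSettings: min_lambda_ratio must be in (0, 1)")
    if config.stars.n_subsamples < 2:
        errors.append("StarsSettings: n_subsamples must be >= 2")
    if config.n_permutations < 1:
        errors.append("n_permutations must be >= 1")
    if config.contaminant_threshold <= 0:
        errors.append("contaminant_threshold must be > 0")
    if not 0 <= config.min_prevalence <= 1:
        errors.append("min_prevalence must be in [0, 1]")
    if not 0 <= config.sourcetrack_min_prevalence <= 1:
        errors.append("sourcetrack_min_prevalence must be in [0, 1]")
    if config.sampler.rarefaction_depth < 1:
        errors.append("SamplerSettings: rarefaction_depth must be >= 1")
    if "qc" not in config.stages and "simulate" not in config.stages:
        errors.append("either simulate or qc inputs must be enabled")
    return errors


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order; returns the report dict
    (also written to ``<out_dir>/report.json``)."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION,
                    "version": __version__, "seed": config.seed, "stages": {}}
    state: dict = {}

    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            runner = _STAGE_RUNNERS[stage]
            block = runner(config, state, out)
        except Exception as e:
            raise RuntimeError(f"stage {stage!r} failed: {e}") from e
        block["elapsed_s"] = round(time.perf_counter() - t0, 3)
        report["stages"][stage] = block
        logger.info("stage %s done in %.1fs", stage, block["elapsed_s"])

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report


def _stage_simulate(config, state, out):
    cohort = config.cohort
    cohort.seed = config.stage_seed("simulate")
    counts, metadata, taxonomy, tree, truth = simulate_cohort(cohort)
    controls = simulate_negative_controls(cohort, config.n_controls,
                                          seed=cohort.seed + 1)
    state.update(counts=counts, metadata=metadata, taxonomy=taxonomy,
                 tree=tree, truth=truth, controls=controls)
    write_count_table(counts, out / "counts.tsv")
    write_metadata(metadata, out / "metadata.tsv")
    write_taxonomy(taxonomy, out / "taxonomy.tsv")
    write_tree(tree, out / "tree.nwk")
    write_count_table(controls, out / "controls.tsv")
    return {"n_samples": counts.n_samples, "n_taxa": counts.n_taxa,
            "n_true_edges": len(truth.edges)}


def _stage_qc(config, state, out):
    counts = state["counts"]
    removed = []
    if state.get("controls") is not None and state["controls"].n_samples:
        counts, removed = remove_contaminants(counts, state["controls"],
                                              config.contaminant_threshold)
    counts = filter_taxa(counts, 0, config.min_prevalence)
    state["counts_qc"] = counts
    report = {"removed_contaminants": removed,
              "n_taxa_after": counts.n_taxa}
    with open(out / "filter_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _stage_metrics(config, state, out):
    counts = state["counts_qc"]
    ra = to_relative_abundance(counts)
    genus = collapse_to_genus(ra, state["taxonomy"])
    top = top_genera(genus, config.top_genus_threshold)
    hvals = shannon_per_sample(counts)
    genus_cv, shannon_cv = cv_profiles(genus, hvals, state["metadata"],
                                       genera=top)
    corr = mean_sd_correlation(genus, state["metadata"])
    genus_cv.to_csv(out / "cv_genus.tsv", sep="\t", index=False)
    shannon_cv.to_csv(out / "cv_shannon.tsv", sep="\t", index=False)
    corr.to_csv(out / "mean_sd_corr.tsv", sep="\t", index=False)
    state.update(genus_table=genus, shannon=hvals, shannon_cv=shannon_cv)
    occ_tau = correlate_with_occupancy(
        shannon_cv.rename(columns={"cv": "shannon_cv"})[
            ["individual", "site", "shannon_cv"]],
        state["metadata"])
    occ_tau.to_csv(out / "occupancy_tau_metrics.tsv", sep="\t", index=False)
    return {"n_top_genera": len(top),
            "median_shannon": float(hvals.median()),
            "occupancy_shannon_cv_tau":
                float(occ_tau.loc[0, "tau"]) if len(occ_tau) else None,
            "mean_sd_rho_range": [float(corr["rho"].min()),
                                  float(corr["rho"].max())]}


def _stage_beta(config, state, out):
    counts = state["counts_qc"]
    meta = state["metadata"]
    dm = weighted_unifrac(counts, state["tree"],
                          normalized=config.normalized_unifrac)
    write_matrix(dm, out / "unifrac.tsv")
    seed = config.stage_seed("beta")
    grouping = meta.for_samples(dm.ids)["individual"].tolist()
    perma = permanova(dm, grouping, config.n_permutations, seed)
    anos = anosim(dm, grouping, config.n_permutations, seed)
    decay = time_decay(dm, meta)
    decay.to_csv(out / "time_decay.tsv", sep="\t", index=False)
    grouped, kw, post = relation_distance_summary(dm, meta)
    grouped.quantiles().to_csv(out / "relation_densities.tsv", sep="\t")
    # mean within-individual temporal distance per (individual, site)
    sub = grouped.frame[grouped.frame["relation"] == "same_individual"]
    msub = meta.for_samples(sub["sample_a"].tolist())
    per_cell = (sub.assign(individual=msub["individual"].to_numpy(),
                           site=msub["site"].to_numpy())
                .groupby(["individual", "site"])["distance"].mean()
                .reset_index().rename(columns={"distance": "mean_unifrac"}))
    occ_tau = correlate_with_occupancy(per_cell, meta)
    occ_tau.to_csv(out / "occupancy_tau_unifrac.tsv", sep="\t", index=False)
    state.update(unifrac=dm, grouped_distances=grouped)
    return {
        "permanova_F": perma.statistic, "permanova_p": perma.p_value,
        "anosim_R": anos.statistic, "anosim_p": anos.p_value,
        "median_time_decay_rho": float(decay["rho"].median()),
        "relation_kw_p": kw.p_value if kw else None,
        "relation_medians": {
            rel: float(np.median(grouped.values_for(rel)))
            for rel in grouped.RELATIONS if grouped.values_for(rel).size},
        "occupancy_unifrac_tau": float(occ_tau.loc[0, "tau"]),
    }


def _stage_network(config, state, out):
    counts = state["counts_qc"]
    meta = state["metadata"].for_samples(counts.samples)
    keys = list(config.network_group_by)
    networks = {}
    fractions = []
    rows = []
    for key, sub in meta.groupby(keys, sort=False):
        label = key if isinstance(key, str) else "_".join(map(str, key))
        group = filter_taxa(counts.select_samples(list(sub.index)),
                            config.min_total_reads, 0.0)
        settings = StarsSettings(
            n_lambda=config.stars.n_lambda,
            min_lambda_ratio=config.stars.min_lambda_ratio,
            n_subsamples=config.stars.n_subsamples,
            instability_threshold=config.stars.instability_threshold,
            seed=(config.stage_seed("network")
                  + zlib.crc32(label.encode())) % 2**31,
        )
        net = fit_network(group, settings=settings,
                          edge_threshold=config.edge_threshold)
        networks[label] = net
        summ = network_summaries(net, state["taxonomy"])
        fractions.append(summ["positive_fraction"])
        for (a, b), w in sorted(net.edges.items()):
            rows.append((label, a, b, w, "+" if w > 0 else "-"))
    pd.DataFrame(rows, columns=["network", "node_a", "node_b", "weight",
                                "sign"]).to_csv(
        out / "edges.tsv", sep="\t", index=False)
    state["networks"] = networks
    nonempty = [f for f, net in zip(fractions, networks.values())
                if net.n_edges]
    return {"n_networks": len(networks),
            "mean_positive_fraction": (float(np.mean(nonempty))
                                       if nonempty else None),
            "edges_per_network": {k: networks[k].n_edges for k in networks}}


def _stage_netdyn(config, state, out):
    networks = {k: v for k, v in state["networks"].items() if v.n_edges > 0}
    if len(networks) < 2:
        return {"skipped": "fewer than 2 non-empty networks"}
    dm = gcd_matrix(networks)
    write_matrix(dm, out / "gcd_matrix.tsv")
    k = min(2, len(networks) - 1)
    coords = mds_embed(dm, k=k)
    pd.DataFrame(coords, index=dm.ids,
                 columns=[f"mds{i + 1}" for i in range(k)]).to_csv(
        out / "mds_coords.tsv", sep="\t")
    curves = []
    ncs = {}
    for label, net in networks.items():
        ncs[label] = natural_connectivity(net)
        stride = max(1, len(net.nodes) // 40)  # ~40 spectral evals per curve
        for ordering in ("betweenness", "degree"):
            c = robustness_curve(net, ordering, eval_every=stride)
            for f, v in zip(c["fractions"], c["relative_nc"]):
                curves.append((label, ordering, f, v))
    pd.DataFrame(curves, columns=["network", "ordering", "fraction",
                                  "relative_nc"]).to_csv(
        out / "robustness_curves.tsv", sep="\t", index=False)
    return {"n_networks": len(networks),
            "mean_gcd": float(dm.data[np.triu_indices(len(dm.ids), 1)].mean()),
            "natural_connectivity": {k: float(v) for k, v in ncs.items()}}


def _stage_sourcetrack(config, state, out):
    counts = state["counts_qc"]
    meta = state["metadata"]
    seasons = (list(config.sourcetrack_seasons)
               if config.sourcetrack_seasons else None)
    estimates = run_seasonal_design(
        counts, meta, config.sourcetrack_min_prevalence,
        settings=config.sampler, seed=config.stage_seed("sourcetrack"),
        seasons=seasons)
    frame, tau = cohabitant_aggregation(estimates, meta)
    frame.to_csv(out / "source_aggregated.tsv", sep="\t", index=False)
    with_cohab = frame[frame["n_cohabitants"] > 0]
    return {
        "n_sinks": len(frame),
        "cohabitant_tau": tau.statistic, "cohabitant_tau_p": tau.p_value,
        "mean_unknown": float(frame["unknown"].mean()),
        "cohabitant_range": ([float(with_cohab["cohabitant"].min()),
                              float(with_cohab["cohabitant"].max())]
                             if len(with_cohab) else None),
    }


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "metrics": _stage_metrics,
    "beta": _stage_beta,
    "network": _stage_network,
    "netdyn": _stage_netdyn,
    "sourcetrack": _stage_sourcetrack,
}
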