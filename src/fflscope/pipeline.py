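"""End-to-end pipeline stages over in-memory objects, plus disk-backed
stage runners used by the command line and the analysis scripts.

Stage order: simulate -> degs -> network -> ffl -> score -> survive ->
report. Every disk-backed stage reads its predecessors' outputs from the
run directory and writes plain TSV/JSON, so repeated runs from the same
config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from fflscope import diffexpr, graph_hub, regnet, scoring, survival
from fflscope.config import RunConfig
from fflscope.io import (
    ExpressionDataset,
    GeneSetCollection,
    read_edge_list,
    read_expression,
    read_gmt,
)
from fflscope.synthetic import NORMAL, TARGET_SUBTYPE, SimulationDesign, generate_cohort, write_cohort

logger = logging.getLogger("fflscope")

WDTC_MEMBERS = ("PTC", "FTC", "OTC")
TA_MEMBERS = ("FTA", "OTA")


# ---------------------------------------------------------------- library API

def de_calls_by_subtype(
    mrna: ExpressionDataset,
    config: RunConfig,
    target: str = TARGET_SUBTYPE,
    reference: str = NORMAL,
) -> tuple[dict[str, tuple[set[str], set[str]]], dict[str, diffexpr.DEResult]]:
    """Tumor-subtype-vs-reference moderated DE with threshold calling."""
    subtypes = [s for s in mrna.subtypes().unique() if s != reference]
    calls: dict[str, tuple[set[str], set[str]]] = {}
    results: dict[str, diffexpr.DEResult] = {}
    for st in subtypes:
        de = diffexpr.moderated_de(mrna, st, reference, batch_center=config.batch_center)
        calls[st] = diffexpr.call_degs(de, config.mrna_p_cut, config.mrna_lfc_cut)
        results[st] = de
        logger.info("DE %s vs %s: %d up, %d down", st, reference, len(calls[st][0]), len(calls[st][1]))
    return calls, results


def default_merge_plan(subtypes) -> dict[str, list[str]]:
    """Merge well-differentiated carcinomas (WDTC) and adenomas (TA)."""
    plan = {}
    wdtc = [s for s in WDTC_MEMBERS if s in subtypes]
    ta = [s for s in TA_MEMBERS if s in subtypes]
    if wdtc:
        plan["WDTC"] = wdtc
    if ta:
        plan["TA"] = ta
    return plan


def exclusive_deg_stage(
    mrna: ExpressionDataset,
    config: RunConfig,
    second_cohort_degs: set[str] | None = None,
) -> diffexpr.ExclusivityResult:
    calls, _ = de_calls_by_subtype(mrna, config)
    plan = default_merge_plan(set(calls) - {TARGET_SUBTYPE})
    return diffexpr.exclusive_degs(calls, TARGET_SUBTYPE, plan, second_cohort_degs)


def mirna_down_set(mirna: ExpressionDataset, config: RunConfig) -> set[str]:
    """Down-regulated miRNAs in the target subtype at the miRNA thresholds."""
    de = diffexpr.moderated_de(mirna, TARGET_SUBTYPE, NORMAL)
    _, down = diffexpr.call_degs(de, config.mirna_p_cut, config.mirna_lfc_cut)
    return down


def hub_discovery(
    ppi_edges,
    candidate_genes: set[str],
    config: RunConfig,
) -> tuple[graph_hub.HubRanking, graph_hub.ModuleResult]:
    graph = graph_hub.build_ppi(ppi_edges, config.ppi_min_score, restrict_to=candidate_genes)
    ranking = graph_hub.mcc_ranking(graph, top_k=config.top_k_hubs)
    modules = graph_hub.mcode_modules(
        graph, vwp=config.mcode_vwp, haircut=config.mcode_haircut,
        fluff=config.mcode_fluff, min_module_size=config.mcode_min_size,
    )
    return ranking, modules


def regulatory_pipeline(
    mrna: ExpressionDataset,
    mirna: ExpressionDataset,
    tf_pairs,
    mirna_pairs,
    hub_set: set[str],
    down_mirnas: set[str],
    config: RunConfig,
) -> tuple[regnet.RegulatoryNetwork, list[regnet.FFLTriple]]:
    """Prediction filters, correlation validation, assembly and FFL calling.

    TF->miRNA candidates are the (TF, miRNA) pairs that co-target at least
    one gene in the validated TF and miRNA layers, mirroring the
    TF-for-miRNA prediction step restricted to network members.
    """
    tf_kept = regnet.filter_tf_candidates(tf_pairs, config.nes_min, hub_set)
    mir_kept = regnet.filter_mirna_candidates(
        mirna_pairs, config.min_tools, down_mirnas, hub_set
    )
    if config.tumor_only_correlation:
        samples = [
            s for s, st in mrna.subtypes().items() if st != NORMAL
        ]
    else:
        samples = mrna.sample_ids
    tf_edges = regnet.validate_edges(
        [(p.tf, p.target) for p in tf_kept], mrna, mirna, regnet.TF_MRNA,
        alpha=config.corr_alpha, samples=samples,
    )
    mir_edges = regnet.validate_edges(
        [(p.mirna, p.target) for p in mir_kept], mrna, mirna, regnet.MIRNA_MRNA,
        alpha=config.corr_alpha, samples=samples,
    )
    partial = regnet.assemble_network(tf_edges, mir_edges, [])
    tfmir_candidates = sorted({(tf, m) for tf, _, m in partial.chains()})
    tfmir_edges = regnet.validate_edges(
        tfmir_candidates, mrna, mirna, regnet.TF_MIRNA,
        alpha=config.corr_alpha, samples=samples,
    )
    network = regnet.assemble_network(tf_edges, mir_edges, tfmir_edges)
    return network, regnet.find_ffls(network)


def score_pipeline(
    mrna: ExpressionDataset,
    mirna: ExpressionDataset,
    tf_set: set[str],
    hub_set: set[str],
    mirna_set: set[str],
    immune_sets: GeneSetCollection,
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Signature + immune scores per sample, and the association table."""
    table = scoring.signature_scores(
        mrna, mirna, tf_set, hub_set, mirna_set,
        alpha=config.ssgsea_alpha, normalize=config.ssgsea_normalize,
    )
    est = scoring.estimate_scores(
        mrna, immune_sets["stromal"], immune_sets["immune"], alpha=config.ssgsea_alpha
    )
    table = table.join(est)
    til_names = [n for n in immune_sets.names() if n.startswith("TIL")]
    if til_names:
        tils = scoring.til_abundances(
            mrna, GeneSetCollection({n: immune_sets[n] for n in til_names}),
            alpha=config.ssgsea_alpha,
        )
        table = table.join(tils)
    if "ICG" in immune_sets:
        icgs = sorted(immune_sets["ICG"] & set(mrna.values.index))
        for g in icgs:
            table[f"ICG_{g}"] = mrna.values.loc[g]
    assoc = scoring.immune_associations(table)
    return table, assoc


def survival_pipeline(
    score_table: pd.DataFrame,
    annotations: pd.DataFrame,
    config: RunConfig,
    endpoint: str = "OS",
) -> pd.DataFrame:
    data = score_table.join(annotations[["time", "event"]])
    variables = [c for c in ("tf_score", "hub_score", "mirna_score") if c in data.columns]
    adjustment = [
        c for c in ("stromal_score", "immune_score", "tumor_purity") if c in data.columns
    ]
    return survival.survival_report(
        data, variables, adjustment=adjustment, endpoint=endpoint,
        minprop=config.cutpoint_minprop,
    )


# ------------------------------------------------------------- stage runners

def stage_simulate(config: RunConfig, outdir: Path) -> None:
    cohort = generate_cohort(SimulationDesign(), seed=config.seed)
    write_cohort(cohort, outdir)
    logger.info("simulate: %d genes x %d samples, %d miRNAs",
                cohort.mrna.n_features, cohort.mrna.n_samples, cohort.mirna.n_features)


def _read_cohort(outdir: Path) -> tuple[ExpressionDataset, ExpressionDataset]:
    mrna = read_expression(outdir / "mrna.tsv", outdir / "samples.tsv")
    mirna = read_expression(outdir / "mirna.tsv", outdir / "samples.tsv")
    return mrna, mirna


def stage_degs(config: RunConfig, outdir: Path) -> None:
    mrna, mirna = _read_cohort(outdir)
    second_path = outdir / "second_cohort_degs.txt"
    second = set(second_path.read_text().split()) if second_path.exists() else None
    excl = exclusive_deg_stage(mrna, config, second)
    down_mirnas = mirna_down_set(mirna, config)
    genes = sorted(excl.post_exclusion_up) + sorted(excl.post_exclusion_down)
    pd.DataFrame(
        {
            "gene": genes,
            "direction": ["up"] * len(excl.post_exclusion_up)
            + ["down"] * len(excl.post_exclusion_down),
        }
    ).to_csv(outdir / "exclusive_degs.tsv", sep="\t", index=False)
    with open(outdir / "exclusivity_report.json", "w") as fh:
        json.dump(excl.step_sizes, fh, indent=2, sort_keys=True)
    pd.Series(sorted(down_mirnas), name="mirna").to_csv(
        outdir / "down_mirnas.tsv", sep="\t", index=False
    )
    logger.info("degs: %d exclusive up, %d exclusive down, %d down miRNAs",
                len(excl.post_exclusion_up), len(excl.post_exclusion_down), len(down_mirnas))


def stage_network(config: RunConfig, outdir: Path) -> None:
    edges = read_edge_list(outdir / "ppi.tsv", "ppi")
    degs = pd.read_csv(outdir / "exclusive_degs.tsv", sep="\t")
    candidates = set(degs["gene"])
    ranking, modules = hub_discovery(edges, candidates, config)
    pd.DataFrame(
        {
            "node": ranking.order,
            "mcc_score": [ranking.scores[v] for v in ranking.order],
            "rank": range(1, len(ranking.order) + 1),
        }
    ).to_csv(outdir / "hub_ranking.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"module": i + 1, "score": m.score, "density": m.density,
             "size": len(m.nodes), "members": ",".join(sorted(m.nodes))}
            for i, m in enumerate(modules.modules)
        ]
    ).to_csv(outdir / "modules.tsv", sep="\t", index=False)
    pd.Series(ranking.top, name="gene").to_csv(outdir / "hub_genes.tsv", sep="\t", index=False)
    logger.info("network: %d modules, top hub %s", len(modules.modules),
                ranking.top[0] if ranking.top else "-")


def stage_ffl(config: RunConfig, outdir: Path) -> None:
    mrna, mirna = _read_cohort(outdir)
    tf_pairs = read_edge_list(outdir / "tf_prior.tsv", "tf_prior")
    mirna_pairs = read_edge_list(outdir / "mirna_prior.tsv", "mirna_prior")
    hub_set = set(pd.read_csv(outdir / "hub_genes.tsv", sep="\t")["gene"])
    down = set(pd.read_csv(outdir / "down_mirnas.tsv", sep="\t")["mirna"])
    network, ffls = regulatory_pipeline(
        mrna, mirna, tf_pairs, mirna_pairs, hub_set, down, config
    )
    all_edges = network.tf_edges + network.mirna_edges + network.tfmir_edges
    regnet.edges_to_frame(all_edges).to_csv(outdir / "validated_edges.tsv", sep="\t", index=False)
    pd.DataFrame(network.chains(), columns=["tf", "gene", "mirna"]).to_csv(
        outdir / "chains.tsv", sep="\t", index=False
    )
    regnet.ffls_to_frame(ffls).to_csv(outdir / "ffls.tsv", sep="\t", index=False)
    logger.info("ffl: %d validated edges, %d loops (%d coherent)",
                len(all_edges), len(ffls),
                sum(t.classification == "coherent" for t in ffls))


def stage_score(config: RunConfig, outdir: Path) -> None:
    mrna, mirna = _read_cohort(outdir)
    edges = pd.read_csv(outdir / "validated_edges.tsv", sep="\t")
    tf_set = set(edges.loc[edges["layer"] == regnet.TF_MRNA, "source"])
    hub_set = set(pd.read_csv(outdir / "hub_genes.tsv", sep="\t")["gene"])
    mirna_set = set(edges.loc[edges["layer"] == regnet.MIRNA_MRNA, "source"])
    immune_sets = read_gmt(outdir / "immune_sets.gmt")
    table, assoc = score_pipeline(mrna, mirna, tf_set, hub_set, mirna_set, immune_sets, config)
    table.to_csv(outdir / "score_table.tsv", sep="\t", index_label="sample_id")
    assoc.to_csv(outdir / "immune_associations.tsv", sep="\t", index=False)
    logger.info("score: %d samples scored on %d columns", *table.shape)


def stage_survive(config: RunConfig, outdir: Path) -> None:
    table = pd.read_csv(outdir / "score_table.tsv", sep="\t", index_col=0)
    ann = pd.read_csv(outdir / "samples.tsv", sep="\t", index_col=0)
    report = survival_pipeline(table, ann, config)
    report.to_csv(outdir / "survival_report.tsv", sep="\t", index=False)
    logger.info("survive: %d rows", len(report))


def stage_report(config: RunConfig, outdir: Path) -> None:
    summary: dict = {}
    excl_path = outdir / "exclusivity_report.json"
    if excl_path.exists():
        summary["exclusivity"] = json.loads(excl_path.read_text())
    for name, fname, count_col in (
        ("n_hub_genes", "hub_genes.tsv", "gene"),
        ("n_validated_edges", "validated_edges.tsv", "source"),
        ("n_chains", "chains.tsv", "tf"),
    ):
        p = outdir / fname
        if p.exists():
            summary[name] = int(len(pd.read_csv(p, sep="\t")))
    ffl_path = outdir / "ffls.tsv"
    if ffl_path.exists():
        ffls = pd.read_csv(ffl_path, sep="\t")
        summary["n_ffls"] = int(len(ffls))
        if len(ffls):
            summary["n_coherent_ffls"] = int((ffls["classification"] == "coherent").sum())
        else:
            summary["n_coherent_ffls"] = 0
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)


STAGES = {
    "simulate": stage_simulate,
    "degs": stage_degs,
    "network": stage_network,
    "ffl": stage_ffl,
    "score": stage_score,
    "survive": stage_survive,
    "report": stage_report,
}
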