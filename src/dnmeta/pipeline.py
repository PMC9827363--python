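"""End-to-end pipeline driver.

Stage order mirrors the analysis chain: per-dataset QC (drop or report
outliers and duplicates) -> per-dataset moderated DE -> merge on common
genes + ComBat -> combined DE -> vote-counting consensus with meta
combination and Ward aggregates -> optional enrichment (GMT) -> MI network
on the core/DEG genes -> MCODE complexes. Every stage's parameters land in
``summary.json``; re-running with identical inputs reproduces identical
outputs.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import networkx as nx
import pandas as pd

from . import io
from .consensus import fc_matrix, meta_combine, vote_count, ward_aggregates
from .combat import combat_adjust, merge_common_genes
from .datasets import ExpressionDataset
from .diffexpr import fit_moderated
from .enrich import ora, read_gmt
from .minet import hub_ranking, infer_network, mcode_cluster
from .qc import assess_dataset


def run_pipeline(
    datasets: list[ExpressionDataset],
    out_dir,
    lfc_threshold: float = 1.5,
    fdr_threshold: float = 0.05,
    drop_flagged: bool = True,
    include_combined_vote: bool = False,
    gmt_path=None,
    network_p_threshold: float = 1e-7,
    skip_network: bool = False,
    seed: int | None = None,
    qc_alpha: float = 0.05,
    dopp_cutoff: float = 0.99,
) -> dict:
    """Run every stage over a loaded bundle; returns the summary dict.

    A stage failure aborts with the stage name in the raised error while
    earlier stages' outputs persist in ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = {
        "lfc_threshold": lfc_threshold,
        "fdr_threshold": fdr_threshold,
        "drop_flagged": drop_flagged,
        "include_combined_vote": include_combined_vote,
        "network_p_threshold": network_p_threshold,
        "skip_network": skip_network,
        "qc_alpha": qc_alpha,
        "dopp_cutoff": dopp_cutoff,
    }
    summary: dict = {"stages": [], "config": config, "seed": seed,
                     "version": io.__version__}

    def stage(name):
        summary["stages"].append(name)
        (out / "summary.json").write_text(json.dumps(summary, indent=1))

    try:
        # ---- qc -----------------------------------------------------------
        reports = [assess_dataset(d, alpha=qc_alpha, dopp_cutoff=dopp_cutoff)
                   for d in datasets]
        (out / "qc_report.json").write_text(
            json.dumps([r.to_dict() for r in reports], indent=1)
        )
        summary["qc"] = {
            r.dataset_id: {
                "outliers": sorted(r.flagged_outliers),
                "duplicates_dropped": sorted(r.flagged_duplicates),
            }
            for r in reports
        }
        if drop_flagged:
            cleaned = []
            for d, r in zip(datasets, reports):
                drop = r.flagged_outliers | r.flagged_duplicates
                cleaned.append(d.drop_samples(drop) if drop else d)
            datasets = cleaned
        summary["samples_after_qc"] = {
            d.dataset_id: int(len(d.samples)) for d in datasets
        }
        stage("qc")

        # ---- per-dataset DE ----------------------------------------------
        voting = [d for d in datasets if d.tissue in ("glomerulus", "tubule")]
        fits = []
        for d in voting:
            fit = fit_moderated(d)
            fits.append(fit)
            io.write_table(
                fit.table[["log2FC", "t", "p", "q"]],
                out / f"de_{d.dataset_id}.tsv",
                seed=seed, config=config, index_label="gene",
                float_format="%.6g",
            )
        stage("de_per_dataset")

        # ---- merge + combat ----------------------------------------------
        merged = merge_common_genes(voting)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            adjusted, model = combat_adjust(merged)
        if model is not None:
            (out / "combat_model.json").write_text(
                json.dumps(model.to_dict(), indent=1)
            )
        stage("combat")

        combined_fit = fit_moderated(adjusted)
        io.write_table(
            combined_fit.table[["log2FC", "t", "p", "q"]],
            out / "de_combined.tsv", seed=seed, config=config,
            index_label="gene", float_format="%.6g",
        )
        stage("de_combined")

        # ---- consensus ----------------------------------------------------
        vote_fits = list(fits)
        if include_combined_vote:
            for tissue in ("glomerulus", "tubule"):
                mask = (adjusted.meta["tissue"] == tissue).to_numpy()
                if mask.sum() >= 4:
                    sub = ExpressionDataset(
                        f"combined_{tissue}",
                        adjusted.expr.loc[:, mask],
                        adjusted.meta.loc[mask],
                    )
                    vote_fits.append(fit_moderated(sub))
        votes = vote_count(vote_fits, lfc_threshold, fdr_threshold)
        meta = meta_combine(fits)
        core = votes.index[votes["core_flag"]]
        table = votes.join(meta)
        if len(core) >= 2:
            fc = fc_matrix(fits, core)
            labels = ward_aggregates(fc, meta["meta_log2FC"].reindex(core))
            table["aggregate"] = labels.reindex(table.index)
            io.write_table(fc, out / "heatmap_matrix.tsv", seed=seed,
                           config=config, index_label="gene",
                           float_format="%.4f")
        else:
            table["aggregate"] = pd.NA
        io.write_table(table, out / "vote_table.tsv", seed=seed, config=config,
                       index_label="gene", float_format="%.6g")
        summary["n_core_degs"] = int(votes["core_flag"].sum())
        stage("consensus")

        # ---- enrichment ---------------------------------------------------
        if gmt_path is not None and len(core) > 0:
            collection = read_gmt(gmt_path)
            universe = set(merged.genes)
            result = ora(set(core) & universe, universe, collection)
            io.write_table(result, out / "enrichment.tsv", seed=seed,
                           config=config, index=False, float_format="%.4g")
            summary["n_enriched_sets"] = int(result["passes"].sum())
        stage("enrichment")

        # ---- network + mcode ---------------------------------------------
        if skip_network:
            summary["network"] = "skipped"
            stage("network")
            stage("mcode")
        else:
            net_genes = core if len(core) >= 2 else merged.genes[:0]
            if len(net_genes) >= 2:
                net = infer_network(
                    adjusted.expr.loc[net_genes], p_threshold=network_p_threshold
                )
                io.write_table(net.edges, out / "network_edges.tsv", seed=seed,
                               config=config, index=False, float_format="%.6g")
                for node in net.graph.nodes:
                    net.graph.nodes[node]["degree"] = int(net.graph.degree(node))
                    mlfc = meta["meta_log2FC"].get(node)
                    if mlfc is not None and pd.notna(mlfc):
                        net.graph.nodes[node]["meta_log2FC"] = float(mlfc)
                summary["network"] = {
                    "n_nodes": int(net.graph.number_of_nodes()),
                    "n_edges": int(net.graph.number_of_edges()),
                    "bins": net.bins,
                }
                stage("network")
                complexes = mcode_cluster(net)
                for rank, cx in enumerate(complexes, start=1):
                    for node in cx.members:
                        if node in net.graph:
                            net.graph.nodes[node]["complex"] = rank
                nx.write_graphml(net.graph, out / "network.graphml")
                (out / "complexes.json").write_text(json.dumps(
                    [
                        {"rank": i + 1, "seed": c.seed, "score": round(c.score, 4),
                         "density": round(c.density, 4), "members": c.members}
                        for i, c in enumerate(complexes)
                    ], indent=1,
                ))
                if net.graph.number_of_nodes():
                    hubs = hub_ranking(net)
                    io.write_table(hubs.to_frame(), out / "hubs.tsv", seed=seed,
                                   config=config, index_label="gene")
                summary["n_complexes"] = len(complexes)
            else:
                summary["network"] = {"n_nodes": 0, "n_edges": 0}
                stage("network")
                summary["n_complexes"] = 0
            stage("mcode")
    except Exception as err:
        summary["failed_stage"] = (
            summary["stages"][-1] + "+1" if summary["stages"] else "qc"
        )
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        raise RuntimeError(
            f"pipeline failed after stage "
            f"{summary['stages'][-1] if summary['stages'] else '(none)'}: {err}"
        ) from err

    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
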