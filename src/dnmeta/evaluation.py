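"""End-to-end benchmark computations on synthetic study bundles.

Every function here regenerates its inputs from a seed and runs the
relevant pipeline stages, returning the measured quantity: detection rates
for the QC screen, recovery of planted batch and DE parameters, calibration
of the significance machinery, and Livak pipeline checks. These are the
quantities the analysis drivers and the acceptance script report.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .combat import combat_adjust, merge_common_genes
from .consensus import vote_count
from .datasets import GroundTruth
from .diffexpr import bh_adjust, fit_moderated
from .minet import (
    MIEdge,
    default_bins,
    discretize_equal_frequency,
    _mi_from_codes,
    infer_network,
    mcode_cluster,
    mi_pvalue,
)
from .qc import assess_dataset
from .qpcr import livak
from .simulate import DatasetSpec, SimulationConfig, generate_multiset, generate_qpcr


def recovery_specs() -> list[DatasetSpec]:
    """3 glomerulus + 2 tubule datasets of 10 DN vs 10 control with
    symmetric batch shifts."""
    return [
        DatasetSpec("glomA", "glomerulus", 10, 10, 0.8, 1.1),
        DatasetSpec("glomB", "glomerulus", 10, 10, -0.5, 0.9),
        DatasetSpec("glomC", "glomerulus", 10, 10, 0.3, 1.0),
        DatasetSpec("tubA", "tubule", 10, 10, -0.9, 1.05),
        DatasetSpec("tubB", "tubule", 10, 10, 0.6, 0.95),
    ]


def _recovery_config(seed: int, n_de: int = 50, de_log2fc: float = 2.0,
                     n_genes: int = 600) -> SimulationConfig:
    return SimulationConfig(
        n_genes=n_genes, dataset_specs=recovery_specs(),
        n_de_genes_per_compartment=n_de, de_log2fc=de_log2fc,
        module_size=20, n_outlier_arrays=0, n_duplicate_pairs=0, seed=seed)


def qc_detection_rates(seeds, outlier_mode: str = "shuffle") -> dict:
    """Precision/recall of the outlier + duplicate screen over seeds.

    Outliers are scored per sample, duplicates per unordered pair.
    """
    tp = fp = fn = 0
    for seed in seeds:
        cfg = SimulationConfig(seed=seed, outlier_mode=outlier_mode)
        datasets, truth = generate_multiset(cfg)
        detected, pairs = set(), set()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for d in datasets:
                r = assess_dataset(d)
                detected |= r.flagged_outliers
                pairs |= {frozenset((a, b)) for a, b, _ in r.doppelganger_pairs}
        truth_pairs = {frozenset(p) for p in truth.duplicate_pairs}
        tp += len(detected & truth.outlier_samples) + len(pairs & truth_pairs)
        fp += len(detected - truth.outlier_samples) + len(pairs - truth_pairs)
        fn += len(truth.outlier_samples - detected) + len(truth_pairs - pairs)
    return {
        "precision": tp / (tp + fp) if tp + fp else 1.0,
        "recall": tp / (tp + fn) if tp + fn else 1.0,
    }


def combat_recovery(seed: int, shift: float = 2.0,
                    scales=(1.2, 0.8), n: int = 20) -> dict:
    """Relative error of EB-recovered batch shift and scale vs planted."""
    specs = [
        DatasetSpec("b1", "glomerulus", n // 2, n - n // 2, +shift, scales[0]),
        DatasetSpec("b2", "glomerulus", n // 2, n - n // 2, -shift, scales[1]),
    ]
    cfg = SimulationConfig(
        n_genes=1000, dataset_specs=specs, n_de_genes_per_compartment=50,
        module_size=0, n_outlier_arrays=0, n_duplicate_pairs=0, seed=seed)
    datasets, _ = generate_multiset(cfg)
    merged = merge_common_genes(datasets)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        adjusted, model = combat_adjust(merged)
    sd = np.sqrt(model.sigma2)
    pooled = np.sqrt((scales[0] ** 2 + scales[1] ** 2) / 2)
    shift_err = max(
        abs((model.gamma_star["b1"] * sd).mean() - shift) / shift,
        abs((model.gamma_star["b2"] * sd).mean() + shift) / shift,
    )
    scale_err = max(
        abs(np.sqrt(model.delta2_star["b1"]).mean() - scales[0] / pooled)
        / (scales[0] / pooled),
        abs(np.sqrt(model.delta2_star["b2"]).mean() - scales[1] / pooled)
        / (scales[1] / pooled),
    )
    b1 = (adjusted.meta["batch"] == "b1").to_numpy()
    mean_diff = (
        adjusted.expr.loc[:, b1].mean(axis=1)
        - adjusted.expr.loc[:, ~b1].mean(axis=1)
    ).abs().mean()
    return {"shift_rel_error": float(shift_err),
            "scale_rel_error": float(scale_err),
            "residual_batch_mean_diff": float(mean_diff)}


def _vote_on_bundle(datasets) -> pd.DataFrame:
    fits = [fit_moderated(d) for d in datasets
            if d.tissue in ("glomerulus", "tubule")]
    return vote_count(fits)


def core_deg_recovery(seed: int) -> dict:
    """Recall/precision of vote-counted core genes against planted DE."""
    datasets, truth = generate_multiset(_recovery_config(seed))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        votes = _vote_on_bundle(datasets)
    core = set(votes.index[votes["core_flag"]])
    planted = truth.all_de_genes()
    tp = len(core & planted)
    return {
        "recall": tp / len(planted),
        "precision": tp / len(core) if core else 1.0,
        "n_core": len(core),
    }


def null_core_deg_counts(seeds) -> list[int]:
    """Core-DEG counts on bundles with no planted effects or artifacts."""
    counts = []
    for seed in seeds:
        cfg = SimulationConfig(
            n_genes=400, dataset_specs=recovery_specs(),
            n_de_genes_per_compartment=0, module_size=0,
            n_outlier_arrays=0, n_duplicate_pairs=0, seed=seed)
        datasets, _ = generate_multiset(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            votes = _vote_on_bundle(datasets)
        counts.append(int(votes["core_flag"].sum()))
    return counts


def bh_null_rejection_rate(seeds, n_genes: int = 1000) -> float:
    """Fraction of genes with q < 0.05 across null bundles (no planted DE)."""
    rates = []
    for seed in seeds:
        specs = [DatasetSpec("d", "glomerulus", 10, 10)]
        cfg = SimulationConfig(
            n_genes=n_genes, dataset_specs=specs,
            n_de_genes_per_compartment=0, module_size=0,
            n_outlier_arrays=0, n_duplicate_pairs=0, seed=seed)
        datasets, _ = generate_multiset(cfg)
        fit = fit_moderated(datasets[0])
        rates.append(float((fit.table["q"] < 0.05).mean()))
    return float(np.mean(rates))


def mi_type1_rate(seed: int, n_pairs: int = 10000, n: int = 60,
                  bins: int = 3, alpha: float = 0.01) -> float:
    """G-test rejection rate at nominal alpha over independent pairs."""
    rng = np.random.default_rng(seed)
    reject = 0
    for _ in range(n_pairs):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        mi = _mi_from_codes(
            discretize_equal_frequency(x, bins),
            discretize_equal_frequency(y, bins), bins)
        if mi_pvalue(MIEdge("a", "b", mi, n, bins)) < alpha:
            reject += 1
    return reject / n_pairs


def fisher_null_ks_p(seed: int, n_genes: int = 5000, n_datasets: int = 4) -> float:
    """KS test of Fisher combined p against Uniform(0,1) under the null."""
    rng = np.random.default_rng(seed)
    pv = rng.uniform(size=(n_genes, n_datasets))
    chi2 = -2.0 * np.log(pv).sum(axis=1)
    fisher_p = stats.chi2.sf(chi2, 2 * n_datasets)
    return float(stats.kstest(fisher_p, "uniform").pvalue)


def module_network_recovery(seed: int, n_background: int = 80) -> dict:
    """MI-network recovery of the planted co-expression module, measured on
    the merged + batch-adjusted bundle at the study's cohort size."""
    cfg = SimulationConfig(seed=seed, n_outlier_arrays=0, n_duplicate_pairs=0)
    datasets, truth = generate_multiset(cfg)
    voting = [d for d in datasets if d.tissue != "cortex"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        adjusted, _ = combat_adjust(merge_common_genes(voting))
    module = sorted(truth.module_genes)
    background = [g for g in adjusted.genes
                  if g not in truth.module_genes
                  and g not in truth.all_de_genes()][:n_background]
    net = infer_network(adjusted.expr.loc[module + background])
    mod = set(module)
    within = sum(r.gene_a in mod and r.gene_b in mod
                 for r in net.edges.itertuples())
    n_mod_pairs = len(module) * (len(module) - 1) // 2
    n_total = len(module) + len(background)
    n_bg_pairs = n_total * (n_total - 1) // 2 - n_mod_pairs
    complexes = mcode_cluster(net)
    top_overlap = 0.0
    if complexes:
        top = complexes[0]
        top_overlap = len(set(top.members) & mod) / len(top.members)
    return {
        "within_edge_recall": within / n_mod_pairs,
        "background_edge_rate": (len(net.edges) - within) / n_bg_pairs,
        "top_complex_module_fraction": top_overlap,
        "n_samples": net.n_samples,
        "bins": net.bins,
    }


def livak_toy_treated_rq() -> float:
    """Treated relative expression on the hand-computable four-sample toy."""
    rows = [
        ("c1", "control", "tgt", 24.0), ("c1", "control", "eefa1", 20.0),
        ("c2", "control", "tgt", 24.0), ("c2", "control", "eefa1", 20.0),
        ("t1", "glucose", "tgt", 26.0), ("t1", "glucose", "eefa1", 20.0),
        ("t2", "glucose", "tgt", 27.0), ("t2", "glucose", "eefa1", 21.0),
    ]
    from .qpcr import CtTable

    ct = CtTable(pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"]))
    res = livak(ct)
    return float(res.per_gene.loc["tgt", "rq_mean_glucose"])


def livak_power(seeds, effect: float = -1.0, n: int = 12,
                ct_sd: float = 0.3) -> float:
    """Fraction of seeds where a planted effect yields Wilcoxon p < 0.05."""
    hits = 0
    seeds = list(seeds)
    for seed in seeds:
        ct, _ = generate_qpcr(n, {"tgt": effect}, ct_sd=ct_sd, seed=seed)
        res = livak(ct)
        if res.per_gene.loc["tgt", "wilcoxon_p"] < 0.05:
            hits += 1
    return hits / len(seeds)
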