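"""Vote-counting consensus across datasets, meta fold-change combination,
and two-aggregate splitting of the core-gene heatmap matrix.

A gene earns one signed vote in each dataset where it is both significant
(BH q below the FDR cutoff) and large (|log2FC| at or above the cutoff,
default 1.5 log2 units, raw FC ~ 2.83). A gene is a *core* DEG when it
collects at least two direction-consistent votes within a single renal
compartment (glomerulus or tubulointerstitium). Effect sizes are combined
as the unweighted mean of available per-dataset log2FC, direction agreement
as the sign-consistency count, and evidence by Fisher's method
(chi2 = -2 sum ln p on 2D degrees of freedom).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .datasets import ConfigError, UsageError
from .diffexpr import ModeratedFit

VOTING_COMPARTMENTS = ("glomerulus", "tubule")


def vote_count(
    de_results: list[ModeratedFit],
    lfc_threshold: float = 1.5,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Tally signed votes per compartment and flag core genes.

    Returns a per-gene table with vote counts, the core flag, and the
    number of datasets each gene was measured in. Kidney-cortex datasets do
    not form a voting compartment and must be excluded upstream.
    """
    for fit in de_results:
        if fit.tissue not in VOTING_COMPARTMENTS:
            raise ConfigError(
                f"vote_count: dataset {fit.dataset_id} has non-voting "
                f"compartment {fit.tissue!r}"
            )
    genes = sorted(set().union(*[set(f.table.index) for f in de_results]))
    out = pd.DataFrame(
        0,
        index=pd.Index(genes, name="gene"),
        columns=[
            "votes_glom_up", "votes_glom_down",
            "votes_tub_up", "votes_tub_down", "n_voting_datasets",
        ],
    )
    for fit in de_results:
        t = fit.table
        out.loc[t.index, "n_voting_datasets"] += 1
        sig = t[(t["q"] < fdr_threshold) & (t["log2FC"].abs() >= lfc_threshold)]
        comp = "glom" if fit.tissue == "glomerulus" else "tub"
        up = sig.index[sig["log2FC"] > 0]
        down = sig.index[sig["log2FC"] < 0]
        out.loc[up, f"votes_{comp}_up"] += 1
        out.loc[down, f"votes_{comp}_down"] += 1
    out["core_flag"] = (
        (out["votes_glom_up"] >= 2) | (out["votes_glom_down"] >= 2)
        | (out["votes_tub_up"] >= 2) | (out["votes_tub_down"] >= 2)
    )
    return out


def meta_combine(de_results: list[ModeratedFit], summary: str = "mean") -> pd.DataFrame:
    """Per-gene meta fold-change, sign consistency and Fisher combined p.

    meta_log2FC is the unweighted mean (or median) of per-dataset log2FC
    where the gene is measured; sign_consistency = max(#positive,
    #negative); fisher_chi2 = -2 sum ln p_d ~ chi2 on 2D df.
    """
    if summary not in ("mean", "median"):
        raise UsageError("meta_combine: summary must be 'mean' or 'median'")
    lfc = pd.concat(
        {f.dataset_id: f.table["log2FC"] for f in de_results}, axis=1
    )
    pv = pd.concat({f.dataset_id: f.table["p"] for f in de_results}, axis=1)
    n_measured = lfc.notna().sum(axis=1)
    meta_lfc = lfc.mean(axis=1) if summary == "mean" else lfc.median(axis=1)
    pos = (lfc > 0).sum(axis=1)
    neg = (lfc < 0).sum(axis=1)
    sign_consistency = pd.concat([pos, neg], axis=1).max(axis=1)

    pv_clamped = pv.clip(lower=1e-300)
    if (pv.min(axis=None) == 0):
        import warnings

        warnings.warn("meta_combine: p-values of 0 clamped to 1e-300")
    chi2 = -2.0 * np.log(pv_clamped).sum(axis=1, min_count=1)
    df = 2 * n_measured
    fisher_p = stats.chi2.sf(chi2, df)
    return pd.DataFrame(
        {
            "meta_log2FC": meta_lfc,
            "sign_consistency": sign_consistency,
            "n_measured": n_measured,
            "fisher_chi2": chi2,
            "fisher_df": df,
            "fisher_p": fisher_p,
        },
        index=lfc.index.rename("gene"),
    )


def fc_matrix(de_results: list[ModeratedFit], genes) -> pd.DataFrame:
    """Core-gene x dataset log2FC matrix for the heatmap/aggregate step;
    genes missing from a dataset are imputed as 0 (count is logged by the
    caller via the returned mask)."""
    m = pd.concat(
        {f.dataset_id: f.table["log2FC"] for f in de_results}, axis=1
    ).reindex(genes)
    return m


def ward_aggregates(
    fc: pd.DataFrame,
    meta_log2fc: pd.Series | None = None,
    k: int = 2,
) -> pd.Series:
    """Split the fold-change matrix into k aggregates by Ward.D2 clustering.

    Hierarchical agglomeration with the Ward (D2) criterion on Euclidean
    distances between gene fold-change profiles; the dendrogram is cut into
    ``k`` groups. Group label 1 is assigned to the cluster with the lower
    mean meta log2FC (the downregulated aggregate), label 2 to the higher.
    Missing values are imputed as 0 before clustering.
    """
    if k > len(fc):
        raise UsageError(f"ward_aggregates: k={k} exceeds {len(fc)} genes")
    if len(fc) < 2:
        raise UsageError("ward_aggregates: need >= 2 genes")
    x = fc.fillna(0.0).to_numpy(dtype=float)
    link = hierarchy.linkage(x, method="ward")
    raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=fc.index, name="aggregate")
    score = meta_log2fc.reindex(fc.index) if meta_log2fc is not None \
        else fc.fillna(0.0).mean(axis=1)
    order = (
        score.groupby(labels).mean().sort_values().index
    )
    remap = {old: new for new, old in enumerate(order, start=1)}
    return labels.map(remap)
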