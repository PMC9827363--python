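"""Livak 2^-ddCt relative quantification with rank-sum group comparison.

Each sample's target Ct is normalized to its reference-gene Ct
(dCt = Ct_target - Ct_reference), calibrated against the mean control dCt
(ddCt = dCt - mean control dCt), and expressed as a fold change
rq = 2^-ddCt, so the control group's geometric-mean rq is 1 by
construction. Group differences are tested with the two-sided Wilcoxon
rank-sum test: exact enumeration for small tie-free samples, normal
approximation with tie and continuity corrections otherwise.
Amplification efficiency is fixed at 2 (pure Livak).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .datasets import DataError, UsageError


@dataclass
class CtTable:
    """Long-format replicate Ct values: (sample, group, gene, ct)."""

    table: pd.DataFrame
    reference_gene: str = "eefa1"

    def __post_init__(self) -> None:
        required = {"sample", "group", "gene", "ct"}
        missing = required - set(self.table.columns)
        if missing:
            raise DataError(f"CtTable: missing columns {sorted(missing)}")
        if (self.table["ct"] <= 0).any():
            raise DataError("CtTable: Ct values must be positive")
        with_ref = set(
            self.table.loc[self.table["gene"] == self.reference_gene, "sample"]
        )
        if not with_ref:
            raise DataError(
                f"CtTable: reference gene {self.reference_gene!r} absent"
            )

    @property
    def target_genes(self) -> list[str]:
        return sorted(set(self.table["gene"]) - {self.reference_gene})


@dataclass
class LivakResult:
    per_sample: pd.DataFrame   # sample, group, gene, dct, ddct, rq
    per_gene: pd.DataFrame     # gene, mean/SEM rq per group, wilcoxon_p
    n_dropped: int = 0


def livak(
    ct: CtTable,
    control_label: str = "control",
) -> LivakResult:
    """Relative expression of every target gene, calibrated to the control
    group mean dCt, plus per-gene Wilcoxon rank-sum group comparison.

    Technical replicate Ct rows for the same (sample, gene) are averaged
    before dCt. Samples lacking a reference Ct are dropped (count reported).
    """
    t = ct.table.groupby(["sample", "group", "gene"], as_index=False)["ct"].mean()
    groups = list(dict.fromkeys(ct.table["group"]))
    if control_label not in groups:
        raise UsageError(
            f"livak: no samples labelled {control_label!r} (groups: {groups})"
        )
    ref = t[t["gene"] == ct.reference_gene].set_index("sample")["ct"]
    targets = t[t["gene"] != ct.reference_gene].copy()
    has_ref = targets["sample"].isin(ref.index)
    n_dropped = int((~has_ref).sum())
    if n_dropped:
        warnings.warn(f"livak: dropped {n_dropped} rows lacking a reference Ct")
    targets = targets[has_ref]
    targets["dct"] = targets["ct"] - ref.reindex(targets["sample"]).to_numpy()

    per_sample_parts = []
    gene_rows = []
    for gene, sub in targets.groupby("gene"):
        controls = sub.loc[sub["group"] == control_label, "dct"]
        if len(controls) < 2:
            raise UsageError(f"livak: gene {gene} has < 2 control samples")
        calib = controls.mean()
        sub = sub.assign(ddct=sub["dct"] - calib)
        sub = sub.assign(rq=2.0 ** (-sub["ddct"]))
        per_sample_parts.append(sub)
        row = {"gene": gene}
        for grp, grp_sub in sub.groupby("group"):
            rq = grp_sub["rq"]
            row[f"rq_mean_{grp}"] = rq.mean()
            row[f"rq_sem_{grp}"] = rq.std(ddof=1) / np.sqrt(len(rq)) \
                if len(rq) > 1 else np.nan
        other = [g for g in groups if g != control_label]
        if other:
            a = sub.loc[sub["group"] == control_label, "rq"].to_numpy()
            b = sub.loc[sub["group"] == other[0], "rq"].to_numpy()
            row["wilcoxon_p"] = wilcoxon_rank_sum(a, b)
        gene_rows.append(row)
    per_sample = pd.concat(per_sample_parts, ignore_index=True)
    per_gene = pd.DataFrame(gene_rows).set_index("gene")
    return LivakResult(per_sample, per_gene, n_dropped)


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration of rank-sum arrangements when n_a + n_b <= 12 and the
    pooled data are tie-free; otherwise the normal approximation with tie
    and continuity corrections. Identical constant groups give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise UsageError("wilcoxon_rank_sum: both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= 12 and not ties:
        return _exact_rank_sum_p(a, b)
    from scipy.stats import mannwhitneyu

    return float(
        mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                     use_continuity=True).pvalue
    )


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided p by full enumeration of rank assignments."""
    pooled = np.concatenate([a, b])
    ranks = pooled.argsort().argsort() + 1
    n_a = len(a)
    n = len(pooled)
    w_obs = ranks[:n_a].sum()
    mu = n_a * (n + 1) / 2.0
    dev = abs(w_obs - mu)
    total = comb(n, n_a)
    count = 0
    for idx in combinations(range(1, n + 1), n_a):
        if abs(sum(idx) - mu) >= dev - 1e-9:
            count += 1
    return count / total
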