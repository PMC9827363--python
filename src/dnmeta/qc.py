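"""Array-level quality control: normalization, probe collapse, outlier and
duplicate ("doppelgaenger") screening.

The screening toolkit combines four complementary views of an array's
quality:

* a rank-concordance score — Spearman correlation between an array's
  within-array expression ranks and the element-wise median rank profile of
  the remaining arrays; arrays whose gene ranking disagrees with the cohort
  score low;
* the Ka statistic — two-sample Kolmogorov–Smirnov distance between an
  array's intensity distribution and the pooled remaining arrays, flagged by
  the Tukey upper fence (distribution-shift outliers);
* generalized ESD (Rosner) and Dixon Q tests applied to the concordance
  scores, giving formal small-sample outlier decisions;
* near-duplicate detection by Pearson correlation of sample pairs.

Rank-concordance and distribution distance are deliberately orthogonal: an
array whose values were scrambled within the array keeps its distribution
(invisible to Ka) but loses concordance, while a globally shifted array keeps
concordance but moves its distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import ceil, sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import DataError, ExpressionDataset, UsageError


@dataclass
class QualityReport:
    """Per-dataset QC outcome; flagged ids always exist in the dataset."""

    dataset_id: str
    concordance: pd.Series
    ka: pd.Series
    esd_outliers: set = field(default_factory=set)
    dixon_outlier: str | None = None
    ka_boxplot_outliers: set = field(default_factory=set)
    doppelganger_pairs: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def flagged_outliers(self) -> set:
        return set(self.esd_outliers) | self.ka_boxplot_outliers | (
            {self.dixon_outlier} if self.dixon_outlier else set()
        )

    @property
    def flagged_duplicates(self) -> set:
        """Second member of each duplicate pair (the 'keep first' policy)."""
        return {b for _, b, _ in self.doppelganger_pairs}

    def to_dict(self) -> dict:
        return {
            "dataset_id": self.dataset_id,
            "concordance": self.concordance.round(6).to_dict(),
            "ka": self.ka.round(6).to_dict(),
            "esd_outliers": sorted(self.esd_outliers),
            "dixon_outlier": self.dixon_outlier,
            "ka_boxplot_outliers": sorted(self.ka_boxplot_outliers),
            "doppelganger_pairs": [
                [a, b, round(float(r), 6)] for a, b, r in self.doppelganger_pairs
            ],
            "warnings": list(self.warnings),
        }


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common distribution of row-wise means of
    the column-sorted matrix.

    Ties within a column receive the mean of the reference values their
    (average) ranks span. Idempotent.
    """
    if matrix.isna().to_numpy().any():
        raise DataError("quantile_normalize: NaN values present")
    x = matrix.to_numpy(dtype=float)
    n_rows, n_cols = x.shape
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(n_cols):
        # average ranks (1-based); half-ranks interpolate between ref values
        r = stats.rankdata(x[:, j], method="average")
        out[:, j] = np.interp(r, np.arange(1, n_rows + 1), ref)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def collapse_probes(matrix: pd.DataFrame, probe_map: pd.Series) -> pd.DataFrame:
    """Average probes per gene symbol; drop probes mapped to zero or to
    multiple symbols.

    ``probe_map`` maps probe id -> gene symbol; a probe appearing more than
    once (multi-mapping) or absent/empty is dropped.
    """
    if matrix.index.has_duplicates:
        raise DataError("collapse_probes: probe ids must be unique")
    pm = probe_map.dropna()
    pm = pm[pm.astype(str).str.len() > 0]
    multi = pm.index[pm.index.duplicated(keep=False)]
    pm = pm.drop(index=multi)
    keep = matrix.index.intersection(pm.index)
    if len(keep) == 0:
        raise DataError("collapse_probes: no probe maps to a unique gene symbol")
    collapsed = matrix.loc[keep].groupby(pm.loc[keep]).mean()
    collapsed.index.name = matrix.index.name
    return collapsed


def detect_doppelgangers(
    matrix: pd.DataFrame,
    correlation_cutoff: float = 0.99,
    top_n_variable: int | None = 2000,
) -> tuple[list[tuple[str, str, float]], list[str]]:
    """All sample pairs whose Pearson correlation reaches the cutoff,
    sorted by correlation descending.

    Computed on the ``top_n_variable`` most variable genes (duplicate arrays
    stay near-perfectly correlated there while unrelated arrays decorrelate).
    Zero-variance samples are excluded and reported in the warnings list.
    """
    if matrix.shape[1] < 2:
        raise UsageError("detect_doppelgangers: need >= 2 samples")
    warns: list[str] = []
    sd = matrix.std(axis=0, ddof=1)
    bad = sd.index[sd == 0].tolist()
    if bad:
        warns.append(f"excluded zero-variance samples: {bad}")
    m = matrix.drop(columns=bad)
    if top_n_variable is not None and matrix.shape[0] > top_n_variable:
        var = m.var(axis=1)
        m = m.loc[var.nlargest(top_n_variable).index]
    corr = np.corrcoef(m.to_numpy().T)
    cols = m.columns
    pairs = [
        (cols[i], cols[j], float(corr[i, j]))
        for i, j in combinations(range(len(cols)), 2)
        if corr[i, j] >= correlation_cutoff
    ]
    pairs.sort(key=lambda t: -t[2])
    return pairs, warns


def concordance_scores(matrix: pd.DataFrame) -> pd.Series:
    """Spearman correlation of each array's gene ranks with the element-wise
    median rank profile of all other arrays.

    A constant array gets score 0 (with a warning): its ranking carries no
    information.
    """
    if matrix.shape[1] < 3:
        raise UsageError("concordance_scores: need >= 3 samples")
    ranks = matrix.rank(axis=0, method="average")
    scores = {}
    for col in matrix.columns:
        others = ranks.drop(columns=col).median(axis=1)
        own = matrix[col]
        if own.nunique() == 1:
            warnings.warn(f"constant array {col}: concordance set to 0")
            scores[col] = 0.0
            continue
        rho = stats.spearmanr(own, others).statistic
        scores[col] = float(rho)
    return pd.Series(scores, name="concordance")


def ka_distances(matrix: pd.DataFrame) -> tuple[pd.Series, set]:
    """Two-sample KS distance of each array vs the pooled other arrays, with
    Tukey upper-fence flags (Ka > Q3 + 1.5*IQR)."""
    if matrix.isna().to_numpy().any():
        raise DataError("ka_distances: NaN values present")
    if matrix.shape[1] < 3:
        raise UsageError("ka_distances: need >= 3 samples")
    x = matrix.to_numpy(dtype=float)
    ka = {}
    for j, col in enumerate(matrix.columns):
        rest = np.delete(x, j, axis=1).ravel()
        ka[col] = float(stats.ks_2samp(x[:, j], rest).statistic)
    ka_s = pd.Series(ka, name="ka")
    q1, q3 = np.percentile(ka_s, [25, 75])
    fence = q3 + 1.5 * (q3 - q1)
    flags = set(ka_s.index[ka_s > fence])
    return ka_s, flags


def rosner_esd(
    values: pd.Series | np.ndarray,
    max_outliers: int | None = None,
    alpha: float = 0.05,
) -> list:
    """Generalized extreme Studentized deviate (ESD) test.

    Iteratively removes the most extreme value; flags the first ``j`` most
    extreme where the last significant test statistic R_i > lambda_i occurs
    at i = j. Returns flagged labels (or integer positions for arrays).
    Zero-variance input flags nothing.
    """
    s = pd.Series(values)
    n = len(s)
    k = max_outliers if max_outliers is not None else ceil(0.1 * n)
    k = min(k, n - 2)
    if k < 1 or n < k + 2:
        return []
    if s.nunique() == 1:
        return []
    work = s.astype(float).copy()
    removed: list = []
    stats_r: list[float] = []
    lambdas: list[float] = []
    for i in range(1, k + 1):
        mu, sd = work.mean(), work.std(ddof=1)
        if sd == 0:
            break
        dev = (work - mu).abs()
        idx = dev.idxmax()
        stats_r.append(float(dev.loc[idx] / sd))
        n_i = n - i + 1
        p = 1 - alpha / (2 * n_i)
        t = stats.t.ppf(p, n_i - 2)
        lambdas.append((n_i - 1) * t / sqrt((n_i - 2 + t**2) * n_i))
        removed.append(idx)
        work = work.drop(index=idx)
    n_out = 0
    for i in range(len(stats_r), 0, -1):
        if stats_r[i - 1] > lambdas[i - 1]:
            n_out = i
            break
    return removed[:n_out]


# Two-sided Dixon critical values at alpha in {0.10, 0.05, 0.01}
# (r10 for n<=7, r11 for 8<=n<=10, r21 for 11<=n<=13, r22 for n>=14).
_DIXON_CRIT = {
    0.10: {3: 0.885, 4: 0.679, 5: 0.557, 6: 0.482, 7: 0.434,
           8: 0.479, 9: 0.441, 10: 0.409,
           11: 0.517, 12: 0.490, 13: 0.467,
           14: 0.492, 15: 0.472, 16: 0.454, 17: 0.438, 18: 0.424,
           19: 0.412, 20: 0.401, 21: 0.391, 22: 0.382, 23: 0.374,
           24: 0.367, 25: 0.360, 26: 0.354, 27: 0.348, 28: 0.342,
           29: 0.337, 30: 0.332},
    0.05: {3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568,
           8: 0.615, 9: 0.570, 10: 0.534,
           11: 0.625, 12: 0.592, 13: 0.565,
           14: 0.590, 15: 0.568, 16: 0.548, 17: 0.531, 18: 0.516,
           19: 0.503, 20: 0.491, 21: 0.480, 22: 0.470, 23: 0.461,
           24: 0.452, 25: 0.445, 26: 0.438, 27: 0.432, 28: 0.426,
           29: 0.420, 30: 0.414},
    0.01: {3: 0.994, 4: 0.926, 5: 0.821, 6: 0.740, 7: 0.680,
           8: 0.717, 9: 0.672, 10: 0.635,
           11: 0.709, 12: 0.660, 13: 0.638,
           14: 0.670, 15: 0.647, 16: 0.627, 17: 0.610, 18: 0.594,
           19: 0.580, 20: 0.567, 21: 0.555, 22: 0.544, 23: 0.535,
           24: 0.526, 25: 0.517, 26: 0.510, 27: 0.502, 28: 0.495,
           29: 0.489, 30: 0.483},
}


def dixon_q(values: pd.Series | np.ndarray, alpha: float = 0.05):
    """Dixon's outlier test for small samples (3 <= n <= 30).

    Tests the single most extreme value using the ratio variant matched to
    the sample size (r10 up to n=7, r11 to n=10, r21 to n=13, r22 beyond),
    against two-sided tabulated critical values. Returns
    ``(flagged_label_or_None, Q)``; ties for most extreme resolve to the
    lowest index. All-equal input is undefined: Q = 0, no flag.
    """
    s = pd.Series(values).astype(float)
    n = len(s)
    if n < 3 or n > 30:
        raise UsageError(f"dixon_q: n must be in [3, 30], got {n}")
    if alpha not in _DIXON_CRIT:
        raise UsageError(f"dixon_q: alpha must be one of {sorted(_DIXON_CRIT)}")
    order = s.sort_values(kind="stable")
    x = order.to_numpy()
    rng_full = x[-1] - x[0]
    if rng_full == 0:
        return None, 0.0
    if n <= 7:
        j, i = 1, 0  # gap index offset, trimming of opposite tail
    elif n <= 10:
        j, i = 1, 1
    elif n <= 13:
        j, i = 2, 1
    else:
        j, i = 2, 2
    # candidate low extreme: gap to j-th neighbour over range trimmed at top
    q_low = (x[j] - x[0]) / (x[n - 1 - i] - x[0])
    q_high = (x[-1] - x[-1 - j]) / (x[-1] - x[i])
    if q_high > q_low:
        q, pos = q_high, order.index[-1]
    elif q_low > q_high:
        q, pos = q_low, order.index[0]
    else:  # tie: lowest index wins
        cand = [order.index[0], order.index[-1]]
        try:
            pos = min(cand)
        except TypeError:
            pos = sorted(cand, key=str)[0]
        q = q_low
    crit = _DIXON_CRIT[alpha][n]
    return (pos if q > crit else None), float(q)


def assess_dataset(
    ds: ExpressionDataset,
    alpha: float = 0.05,
    max_outliers: int | None = None,
    dopp_cutoff: float = 0.99,
    ka_floor: float = 0.1,
) -> QualityReport:
    """Run the full QC screen on one dataset.

    Concordance scores feed Rosner's ESD when n > 7 and Dixon's Q otherwise
    (small-n practice); Ka adds distribution-shift flags; doppelgaenger pairs
    are reported, not dropped — dropping is an explicit pipeline policy.

    The Tukey fence on Ka is sensitive to the natural spread of clean
    cohorts, so fence exceedances only count as outliers when the distance
    also has practical size (``ka_floor``); a genuinely shifted array sits
    far above it.
    """
    conc = concordance_scores(ds.expr)
    ka, ka_flags = ka_distances(ds.expr)
    ka_flags = {s for s in ka_flags if ka[s] > ka_floor}
    report = QualityReport(ds.dataset_id, conc, ka, ka_boxplot_outliers=ka_flags)
    n = len(conc)
    # the tests are two-sided on scores; an array is only *bad* when its
    # concordance is materially below the cohort (practical significance
    # guard, same rationale as ka_floor)
    floor = conc.median() - 0.1
    if n > 7:
        report.esd_outliers = {
            s for s in rosner_esd(conc, max_outliers, alpha) if conc[s] < floor
        }
    else:
        flagged, _ = dixon_q(conc, alpha)
        if flagged is not None and conc[flagged] < floor:
            report.dixon_outlier = flagged
    pairs, warns = detect_doppelgangers(ds.expr, dopp_cutoff)
    report.doppelganger_pairs = pairs
    report.warnings.extend(warns)
    return report
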