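"""Differential and correlation summaries of the normalized panel.

Fold changes between iron-limited and iron-replete groups with Welch
(unequal-variance) t-tests, a Spearman correlation matrix of log2 counts
with hierarchical clustering order, PCA sample scores, pairwise R-squared
for co-regulated gene pairs, and the flow-cytometry growth-rate formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .core import ACTD_TREATMENTS, CountMatrix, DataError


# ---------------------------------------------------------------------------
# fold changes
# ---------------------------------------------------------------------------

@dataclass
class FoldChangeResult:
    gene: str
    mean_low: float
    mean_high: float
    fold_change: float | None
    log2_fc: float | None
    t_statistic: float
    p_value: float
    p_adjusted: float


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests
    return multipletests(p, method="fdr_bh")[1]


def fold_change_table(
    matrix: CountMatrix,
    group_a: set[str],
    group_b: set[str],
    log_scale_test: bool = False,
) -> pd.DataFrame:
    """Per-gene fold changes group_a / group_b with Welch t-tests.

    By convention group_a is the iron-limited (low) group and group_b the
    iron-replete (high) group, so induced-under-limitation genes have fold
    change > 1.  The Welch test runs on the normalized counts themselves
    (``log_scale_test=True`` switches to log2 counts).  Genes with a zero
    group mean get an undefined (NaN) fold change.  p-values are
    Benjamini-Hochberg adjusted across genes.
    """
    if not group_a or not group_b:
        raise DataError("both groups must be non-empty")
    for sid in list(group_a) + list(group_b):
        if sid not in matrix.values.columns:
            raise DataError(f"sample {sid!r} not in matrix")
    genes = [p.probe_id for p in matrix.probes if p.probe_class == "endogenous"]
    rows = []
    for g in genes:
        a = matrix.values.loc[g, sorted(group_a)].to_numpy(dtype=float)
        b = matrix.values.loc[g, sorted(group_b)].to_numpy(dtype=float)
        mean_a, mean_b = float(a.mean()), float(b.mean())
        if mean_a > 0 and mean_b > 0:
            fc = mean_a / mean_b
            l2fc = float(np.log2(fc))
        else:
            fc, l2fc = np.nan, np.nan
        ta, tb = (np.log2(a + 1), np.log2(b + 1)) if log_scale_test else (a, b)
        if np.allclose(ta, ta[0]) and np.allclose(tb, tb[0]) and np.isclose(
            ta[0], tb[0]
        ):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(ta, tb, equal_var=False)
        rows.append({
            "gene": g, "mean_low": mean_a, "mean_high": mean_b,
            "fold_change": fc, "log2_fc": l2fc,
            "t_statistic": float(t), "p_value": float(p),
        })
    table = pd.DataFrame(rows)
    table["p_adjusted"] = _bh_adjust(table["p_value"].to_numpy())
    return table


def iron_contrast_groups(matrix: CountMatrix) -> tuple[set[str], set[str]]:
    """Sample IDs of the low-iron and high-iron groups (ST and LT combined)."""
    low = {s.sample_id for s in matrix.biological_samples() if s.treatment == "low"}
    high = {s.sample_id for s in matrix.biological_samples() if s.treatment == "high"}
    return low, high


# ---------------------------------------------------------------------------
# correlation matrix
# ---------------------------------------------------------------------------

def spearman_matrix(
    matrix: CountMatrix,
    exclude_treatments: frozenset[str] = ACTD_TREATMENTS,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Gene x gene Spearman correlation of log2 counts.

    Transcription-inhibited samples are excluded by default (their global
    decay correlates everything with everything).  Constant genes get NaN
    for their pairs.  The second return value is the average-linkage
    (1 - rho distance) clustering leaf order used for heatmap layout.
    """
    keep = [
        s.sample_id for s in matrix.biological_samples()
        if s.treatment not in exclude_treatments
    ]
    if len(keep) < 3:
        raise DataError("need >= 3 samples for a correlation matrix")
    genes = [
        p.probe_id for p in matrix.probes
        if p.probe_class in ("endogenous", "housekeeping")
    ]
    data = np.log2(matrix.values.loc[genes, keep] + pseudocount)
    corr = data.T.corr(method="spearman")
    # a gene pinned to a constant (e.g. the housekeeping probe after global
    # normalization) has no defined correlation: report it absent
    const = data.std(axis=1) <= 1e-9 * data.abs().mean(axis=1).clip(lower=1.0)
    for g in data.index[const]:
        corr.loc[g, :] = np.nan
        corr.loc[:, g] = np.nan
    np.fill_diagonal(corr.to_numpy(), 1.0)

    # clustering order on the non-constant genes
    ok = [g for g in genes if not const[g]]
    if len(ok) >= 3:
        d = 1.0 - corr.loc[ok, ok].to_numpy()
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2.0
        order_idx = leaves_list(linkage(squareform(d, checks=False),
                                        method="average"))
        order = [ok[i] for i in order_idx]
    else:
        order = ok
    return corr, order


def pairwise_r2(
    matrix: CountMatrix, gene_a: str, gene_b: str,
    exclude_treatments: frozenset[str] = ACTD_TREATMENTS,
    pseudocount: float = 1.0,
) -> dict[str, float]:
    """Squared Pearson and Spearman correlation of log2 counts for a pair."""
    keep = [
        s.sample_id for s in matrix.biological_samples()
        if s.treatment not in exclude_treatments
    ]
    a = np.log2(matrix.values.loc[gene_a, keep].to_numpy(dtype=float) + pseudocount)
    b = np.log2(matrix.values.loc[gene_b, keep].to_numpy(dtype=float) + pseudocount)
    pear = stats.pearsonr(a, b).statistic
    spear = stats.spearmanr(a, b).statistic
    return {"pearson_r2": float(pear**2), "spearman_r2": float(spear**2)}


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_scores(
    matrix: CountMatrix,
    exclude_treatments: frozenset[str] = ACTD_TREATMENTS,
    pseudocount: float = 1.0,
    n_components: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on gene-centered log2 counts.

    Returns per-sample scores for the leading components and the
    explained-variance ratios (summing to <= 1).
    """
    keep = [
        s.sample_id for s in matrix.biological_samples()
        if s.treatment not in exclude_treatments
    ]
    if len(keep) < 2:
        raise DataError("PCA needs >= 2 samples")
    genes = [
        p.probe_id for p in matrix.probes
        if p.probe_class in ("endogenous", "housekeeping")
    ]
    data = np.log2(matrix.values.loc[genes, keep] + pseudocount).to_numpy().T
    n_comp = n_components or min(data.shape)
    pca = PCA(n_components=min(n_comp, min(data.shape)))
    scores = pca.fit_transform(data)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=keep, columns=cols),
        pca.explained_variance_ratio_,
    )


# ---------------------------------------------------------------------------
# growth rates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthObservation:
    """Paired cell counts for the per-day growth rate mu."""

    n0: float
    nt: float
    t_hours: float

    def __post_init__(self) -> None:
        if self.n0 <= 0 or self.nt <= 0:
            raise DataError("cell counts must be > 0")
        if self.t_hours <= 0:
            raise DataError("t_hours must be > 0")

    @property
    def mu_per_day(self) -> float:
        return growth_rate(self.n0, self.nt, self.t_hours)


def growth_rate(n0: float, nt: float, t_hours: float) -> float:
    """Per-day growth rate mu = ((ln Nt - ln N0) / t) * 24."""
    if n0 <= 0 or nt <= 0 or t_hours <= 0:
        raise DataError("growth rate needs positive counts and time")
    return (np.log(nt) - np.log(n0)) / t_hours * 24.0
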