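"""qPCR relative quantification, differential-expression calls, and clustering.

Relative expression follows the comparative-Ct method: per replicate
``dCT = Ct(target) - Ct(reference)``, per condition
``ddCT = mean dCT(condition) - mean dCT(calibrator)``, and the matrix stores
``-ddCT`` so positive values mean induction; ``fold change = 2^-ddCT``.
A gene is called up-regulated in a condition at fold >= 2 with Welch-test
p < 0.05 on replicate dCT values, down-regulated at fold <= 0.5 with
p < 0.05. Genes are grouped by agglomerative clustering (default
1 - Pearson correlation across conditions, average linkage, cut at k = 4,
labels I-IV by descending cluster size), and expression clusters are
cross-tabulated against intron patterns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .io import CtTable

log = logging.getLogger(__name__)

ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")


@dataclass
class ExpressionMatrix:
    """-ddCT values (genes x conditions) with replicate-level dCT provenance."""

    minus_ddct: pd.DataFrame  # genes x conditions
    replicate_dct: pd.DataFrame  # tidy: gene_id, condition_id, replicate, dct
    reference_gene_id: str
    calibrator_condition_id: str
    condition_meta: pd.DataFrame | None = None  # condition_id, group, tissue

    @property
    def genes(self) -> list[str]:
        return list(self.minus_ddct.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.minus_ddct.columns)


def delta_delta_ct(ct: CtTable, condition_meta: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Build the -ddCT matrix from replicate-level Ct measurements.

    Replicates are matched to the reference gene by (condition, replicate);
    conditions missing a reference measurement are dropped for all genes
    with a log notice. The calibrator column is exactly 0 by construction.
    """
    df = ct.data
    ref = (
        df[df.gene_id == ct.reference_gene_id]
        .set_index(["condition_id", "replicate"])["ct"]
        .rename("ref_ct")
    )
    targets = df[df.gene_id != ct.reference_gene_id].copy()
    targets = targets.join(ref, on=["condition_id", "replicate"])
    missing = targets[targets.ref_ct.isna()]
    if not missing.empty:
        dropped = sorted(missing.condition_id.unique())
        log.info("conditions dropped for missing reference Ct: %s", dropped)
        targets = targets.dropna(subset=["ref_ct"])
    targets["dct"] = targets.ct - targets.ref_ct
    mean_dct = targets.groupby(["gene_id", "condition_id"])["dct"].mean().unstack()
    ddct = mean_dct.sub(mean_dct[ct.calibrator_condition_id], axis=0)
    minus_ddct = -ddct
    # preserve input condition order
    order = [c for c in df.condition_id.unique() if c in minus_ddct.columns]
    gene_order = [g for g in df.gene_id.unique() if g in minus_ddct.index]
    return ExpressionMatrix(
        minus_ddct=minus_ddct.loc[gene_order, order],
        replicate_dct=targets[["gene_id", "condition_id", "replicate", "dct"]],
        reference_gene_id=ct.reference_gene_id,
        calibrator_condition_id=ct.calibrator_condition_id,
        condition_meta=condition_meta,
    )


def fold_changes(matrix: ExpressionMatrix) -> pd.DataFrame:
    """fold change = 2^-ddCT, cell-wise (calibrator column is exactly 1)."""
    return 2.0 ** matrix.minus_ddct


@dataclass(frozen=True)
class DECall:
    gene: str
    condition: str
    fold_change: float
    p_value: float
    call: str  # up | down | ns
    flags: tuple = ()


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch p; degenerate zero-variance samples decided exactly."""
    if len(a) < 2 or len(b) < 2:
        return np.nan
    if np.var(a) == 0 and np.var(b) == 0:
        return 0.0 if not np.isclose(a.mean(), b.mean()) else 1.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def de_calls(
    matrix: ExpressionMatrix,
    up_fold: float = 2.0,
    down_fold: float = 0.5,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-(gene, condition) differential-expression calls.

    p-values come from a two-sided Welch test on replicate dCT (condition
    vs calibrator). No multiple-testing correction by default; set
    ``bh_correct`` for Benjamini-Hochberg across all tests.
    """
    folds = fold_changes(matrix)
    dct = matrix.replicate_dct
    cal = matrix.calibrator_condition_id
    rows = []
    for gene in matrix.genes:
        gd = dct[dct.gene_id == gene]
        base = gd.loc[gd.condition_id == cal, "dct"].to_numpy()
        for cond in matrix.conditions:
            if cond == cal:
                continue
            treat = gd.loc[gd.condition_id == cond, "dct"].to_numpy()
            p = _welch_p(treat, base)
            rows.append(
                {"gene": gene, "condition": cond,
                 "fold_change": folds.at[gene, cond], "p_value": p}
            )
    out = pd.DataFrame(rows)
    if bh_correct and not out.empty:
        out["p_value"] = _benjamini_hochberg(out["p_value"].to_numpy())
    def decide(row):
        if np.isnan(row.p_value):
            return "ns"
        if row.fold_change >= up_fold and row.p_value < alpha:
            return "up"
        if row.fold_change <= down_fold and row.p_value < alpha:
            return "down"
        return "ns"
    out["call"] = out.apply(decide, axis=1) if not out.empty else []
    out["flagged_single_replicate"] = out["p_value"].isna() if not out.empty else []
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def de_summary_by_group(calls: pd.DataFrame, condition_meta: pd.DataFrame) -> pd.DataFrame:
    """Proportion of up/down/ns calls per treatment group."""
    merged = calls.merge(
        condition_meta[["condition_id", "group"]],
        left_on="condition", right_on="condition_id",
    )
    tab = merged.groupby("group")["call"].value_counts(normalize=True).unstack(fill_value=0.0)
    return tab


@dataclass
class ExpressionCluster:
    labels: pd.Series  # gene -> roman label
    linkage: np.ndarray
    k: int
    settings: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)


def cluster_expression(
    matrix: ExpressionMatrix,
    k: int = 4,
    distance: str = "correlation",
    linkage_method: str = "average",
) -> ExpressionCluster:
    """Agglomerative clustering of genes on their -ddCT profiles.

    Default metric is 1 - Pearson correlation across conditions with
    average linkage, cut into ``k`` clusters labelled I, II, ... by
    descending size (ties by first-gene order). Missing cells are imputed
    by gene mean (logged); constant-profile genes (undefined correlation)
    are clustered among themselves by Euclidean fallback and flagged.
    """
    X = matrix.minus_ddct.copy()
    if X.isna().any().any():
        log.info("imputing %d missing cells by gene mean", int(X.isna().sum().sum()))
        X = X.apply(lambda row: row.fillna(row.mean()), axis=1)
    genes = list(X.index)
    values = X.to_numpy(float)
    flags: dict = {}
    constant = np.std(values, axis=1) == 0
    if distance == "correlation" and constant.any():
        flags["euclidean_fallback_genes"] = [g for g, c in zip(genes, constant) if c]
        log.info("constant-profile genes fall back to Euclidean assignment: %s",
                 flags["euclidean_fallback_genes"])
        ok = ~constant
        sub = values[ok]
        Z = hierarchy.linkage(pdist(sub, metric="correlation"), method=linkage_method)
        k_eff = min(k, sub.shape[0])
        sub_labels = hierarchy.fcluster(Z, t=k_eff, criterion="maxclust")
        centroids = np.array([sub[sub_labels == c].mean(axis=0) for c in range(1, k_eff + 1)])
        labels_num = np.empty(len(genes), dtype=int)
        labels_num[ok] = sub_labels
        for idx in np.flatnonzero(constant):
            labels_num[idx] = 1 + int(
                np.argmin(np.linalg.norm(centroids - values[idx], axis=1))
            )
    else:
        metric = "correlation" if distance == "correlation" else distance
        Z = hierarchy.linkage(pdist(values, metric=metric), method=linkage_method)
        k_eff = min(k, len(genes))
        labels_num = hierarchy.fcluster(Z, t=k_eff, criterion="maxclust")
    # relabel by descending cluster size; ties by first occurrence
    sizes = pd.Series(labels_num).value_counts()
    first_seen = {c: int(np.argmax(labels_num == c)) for c in sizes.index}
    ordering = sorted(sizes.index, key=lambda c: (-sizes[c], first_seen[c]))
    roman = {c: ROMAN[rank] for rank, c in enumerate(ordering)}
    labels = pd.Series([roman[c] for c in labels_num], index=genes, name="cluster")
    return ExpressionCluster(
        labels=labels,
        linkage=Z,
        k=int(len(sizes)),
        settings={"k": k, "distance": distance, "linkage": linkage_method},
        flags=flags,
    )


def pattern_enrichment(
    clusters: ExpressionCluster, pattern_by_gene: dict[str, str]
) -> pd.DataFrame:
    """Per-pattern share of genes in each expression cluster.

    Rows are intron patterns, columns clusters; each row sums to 1 over the
    genes carrying both a pattern and a cluster label. Patterns absent from
    the cohort are omitted.
    """
    rows = []
    for gene, label in clusters.labels.items():
        pattern = pattern_by_gene.get(gene)
        if pattern is None:
            continue
        rows.append({"pattern": pattern, "cluster": label})
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows)
    tab = df.groupby("pattern")["cluster"].value_counts(normalize=True).unstack(fill_value=0.0)
    return tab
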