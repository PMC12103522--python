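"""CPM normalization, replicate QC, translational efficiency, and
rank-based pathway prioritization.

The pipeline: raw counts are normalized to counts-per-million (CPM) per
sample; replicates are screened by Pearson correlation and Welch t-tests on
log-scale CPM; a gene's translational efficiency (TE) is its mean Ribo-Seq
CPM over its mean RNA-Seq CPM; and a pathway is translationally prioritized
"up" when its mean TE >= 1 and its genes rank significantly higher in the
Ribo-Seq dataset than in the RNA-Seq dataset by a right-tailed Mann-Whitney
U test (symmetrically "down" with the left tail).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic_data import CountMatrix

__all__ = [
    "CpmMatrix",
    "TETable",
    "PrioritizationTable",
    "ReplicateQC",
    "NormalizationError",
    "GeneUniverseError",
    "cpm_normalize",
    "replicate_qc",
    "gene_te",
    "mwu_one_tailed",
    "pathway_prioritization",
    "DEFAULT_ALPHA",
    "DEFAULT_PCC_FLOOR",
    "DEFAULT_MIN_GENES",
]

DEFAULT_ALPHA = 0.05
DEFAULT_PCC_FLOOR = 0.9
DEFAULT_MIN_GENES = 3

#: scipy switches to the exact MWU null below this combined sample size
#: (ties force the tie-corrected normal approximation regardless).
_MWU_EXACT_MAX_N = 25


class NormalizationError(ValueError):
    """A sample cannot be normalized (zero total counts)."""


class GeneUniverseError(ValueError):
    """RNA and Ribo tables do not share the same gene universe."""


@dataclass
class CpmMatrix:
    """Counts-per-million; every sample column sums to 1e6."""

    values: pd.DataFrame  # index gene, columns samples
    assay_of: dict[str, str]
    replicate_of: dict[str, int]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def replicates(self, assay: str) -> list[str]:
        return [s for s in self.values.columns if self.assay_of[s] == assay]


@dataclass
class TETable:
    """Per-gene mean CPM in each assay and their ratio (TE)."""

    table: pd.DataFrame  # index gene; columns mean_rna, mean_ribo, te, included

    @property
    def included(self) -> pd.DataFrame:
        return self.table[self.table["included"]]


@dataclass
class ReplicateQC:
    pcc: dict[str, pd.DataFrame]  # assay -> replicate x replicate PCC matrix
    ttest_p: dict[str, pd.DataFrame]  # assay -> pairwise two-tailed Welch p
    pass_flag: bool
    untested: bool = False


@dataclass
class PrioritizationTable:
    table: pd.DataFrame
    # columns: pathway, n_genes, mean_te, u_stat, p_right, p_left,
    #          p_right_bh, p_left_bh, classification, low_n


def cpm_normalize(counts: CountMatrix) -> CpmMatrix:
    """Counts-per-million: count / sample total * 1e6, per sample."""
    totals = counts.counts.sum(axis=0)
    bad = totals[totals <= 0]
    if len(bad):
        raise NormalizationError(
            f"samples with zero total counts: {list(bad.index)}"
        )
    values = counts.counts.astype(float) / totals.astype(float) * 1e6
    return CpmMatrix(
        values=values,
        assay_of=dict(counts.assay_of),
        replicate_of=dict(counts.replicate_of),
    )


def _log_cpm(col: pd.Series) -> np.ndarray:
    return np.log10(col.to_numpy(dtype=float) + 1.0)


def replicate_qc(
    cpm: CpmMatrix,
    pcc_floor: float = DEFAULT_PCC_FLOOR,
    alpha: float = DEFAULT_ALPHA,
) -> ReplicateQC:
    """Pairwise Pearson correlation and Welch t-tests on log10(CPM+1)
    between replicates of each assay.

    Passes when every off-diagonal PCC exceeds ``pcc_floor`` and no pairwise
    t-test rejects equality of means at ``alpha``.  With a single replicate
    in every assay the QC is untested and passes with a flag.
    """
    pccs: dict[str, pd.DataFrame] = {}
    tps: dict[str, pd.DataFrame] = {}
    any_pair = False
    ok = True
    for assay in sorted(set(cpm.assay_of.values())):
        reps = cpm.replicates(assay)
        k = len(reps)
        pcc = pd.DataFrame(np.eye(k), index=reps, columns=reps)
        tp = pd.DataFrame(np.ones((k, k)), index=reps, columns=reps)
        for i in range(k):
            for j in range(i + 1, k):
                any_pair = True
                x = _log_cpm(cpm.values[reps[i]])
                y = _log_cpm(cpm.values[reps[j]])
                r = float(stats.pearsonr(x, y).statistic)
                if np.array_equal(x, y):
                    p = 1.0  # identical distributions: no mean difference
                else:
                    p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
                pcc.iloc[i, j] = pcc.iloc[j, i] = r
                tp.iloc[i, j] = tp.iloc[j, i] = p
                if r <= pcc_floor or p < alpha:
                    ok = False
        pccs[assay] = pcc
        tps[assay] = tp
    if not any_pair:
        import warnings

        warnings.warn("single replicate per assay: replicate QC untested")
        return ReplicateQC(pcc=pccs, ttest_p=tps, pass_flag=True, untested=True)
    return ReplicateQC(pcc=pccs, ttest_p=tps, pass_flag=ok)


def gene_te(
    rna: CpmMatrix,
    ribo: CpmMatrix,
    min_cpm: float = 0.0,
) -> TETable:
    """TE(g) = mean Ribo-Seq CPM over replicates / mean RNA-Seq CPM.

    Genes whose mean RNA CPM does not exceed ``min_cpm`` (default: any zero),
    or whose mean Ribo CPM is zero, are excluded (``included = False``) —
    no pseudocounts are applied, so TE is finite and positive wherever it is
    reported.
    """
    if set(rna.genes) != set(ribo.genes):
        diff = sorted(set(rna.genes) ^ set(ribo.genes))
        raise GeneUniverseError(
            f"gene universes differ; symmetric difference: {diff[:10]}"
            + ("..." if len(diff) > 10 else "")
        )
    mean_rna = rna.values.mean(axis=1)
    mean_ribo = ribo.values.reindex(rna.values.index).mean(axis=1)
    included = (mean_rna > min_cpm) & (mean_ribo > 0)
    te = pd.Series(np.nan, index=mean_rna.index)
    te[included] = mean_ribo[included] / mean_rna[included]
    return TETable(
        table=pd.DataFrame(
            {
                "mean_rna": mean_rna,
                "mean_ribo": mean_ribo,
                "te": te,
                "included": included,
            }
        )
    )


def mwu_one_tailed(x: np.ndarray, y: np.ndarray, alternative: str) -> tuple[float, float]:
    """One-tailed Mann-Whitney U of x versus y.

    Exact null for small untied samples (combined n <= 25), otherwise the
    tie-corrected normal approximation with continuity correction.  Returns
    ``(U, p)`` with U the statistic of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    small = len(pooled) <= _MWU_EXACT_MAX_N
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (small and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def pathway_prioritization(
    te: TETable,
    rna: CpmMatrix,
    ribo: CpmMatrix,
    pathways: dict[str, list[str]],
    alpha: float = DEFAULT_ALPHA,
    min_genes: int = DEFAULT_MIN_GENES,
) -> PrioritizationTable:
    """Classify each pathway's translational prioritization.

    All included genes are ranked by mean CPM within the RNA dataset and,
    separately, within the Ribo dataset (average ranks on ties).  For a
    pathway, the right-/left-tailed MWU compares its genes' Ribo ranks
    against their RNA ranks; classification is "up" iff mean TE >= 1 and
    right p < alpha, "down" iff mean TE <= 1 and left p < alpha, else "ns".
    Pathways with fewer than ``min_genes`` included genes are reported as
    "ns" with the ``low_n`` flag, never dropped.
    """
    if min_genes < 2:
        raise ValueError("min_genes must be >= 2")
    inc = te.table[te.table["included"]]
    genes = list(inc.index)
    universe = set(te.table.index)
    rna_rank = pd.Series(stats.rankdata(inc["mean_rna"]), index=genes)
    ribo_rank = pd.Series(stats.rankdata(inc["mean_ribo"]), index=genes)
    rows = []
    for pw in sorted(pathways):
        members = pathways[pw]
        unknown = set(members) - universe
        if unknown:
            raise GeneUniverseError(
                f"pathway {pw!r} references genes outside the tables: "
                f"{sorted(unknown)[:5]}"
            )
        used = [g for g in members if g in rna_rank.index]
        n = len(used)
        low_n = n < min_genes
        mean_te = float(inc.loc[used, "te"].mean()) if n else np.nan
        if low_n:
            rows.append((pw, n, mean_te, np.nan, np.nan, np.nan, "ns", True))
            continue
        x = ribo_rank[used].to_numpy()
        y = rna_rank[used].to_numpy()
        u, p_right = mwu_one_tailed(x, y, "greater")
        _, p_left = mwu_one_tailed(x, y, "less")
        if mean_te >= 1.0 and p_right < alpha:
            cls = "up"
        elif mean_te <= 1.0 and p_left < alpha:
            cls = "down"
        else:
            cls = "ns"
        rows.append((pw, n, mean_te, u, p_right, p_left, cls, False))
    table = pd.DataFrame(
        rows,
        columns=[
            "pathway",
            "n_genes",
            "mean_te",
            "u_stat",
            "p_right",
            "p_left",
            "classification",
            "low_n",
        ],
    )
    # BH-adjusted columns for transparency; classification uses raw p-values
    for col in ("p_right", "p_left"):
        adj = np.full(len(table), np.nan)
        mask = table[col].notna().to_numpy()
        if mask.any():
            adj[mask] = multipletests(table.loc[mask, col], method="fdr_bh")[1]
        table[col + "_bh"] = adj
    return PrioritizationTable(table=table)
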