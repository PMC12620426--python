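"""Drug-signature enrichment scoring for bulk and single-cell expression.

Two scoring schemes are provided, matching the two validation arms of the
trigger-discovery framework:

* :func:`ssgsea` — single-sample GSEA for bulk samples: per sample the genes
  are ranked by expression and the enrichment score is the summed difference
  between the rank-weighted empirical CDF of in-set genes (weight
  ``rank**alpha``) and the unweighted CDF of out-of-set genes, followed by
  min-max normalisation across the run's samples. Group differences are
  assessed by one-way ANOVA.
* :func:`add_module_score` — binned-control module scoring for single cells:
  genes are binned by dataset-average expression, each signature gene draws
  expression-matched control genes from its bin, and a cell's score is the
  mean signature expression minus the mean control expression. Cell-type
  differences are assessed by one-vs-rest Wilcoxon rank-sum tests with
  Benjamini-Hochberg correction.

Single-cell quality control (:func:`qc_filter_cells`) applies the standard
mitochondrial / ribosomal / hemoglobin content rules plus minimum
gene-per-cell and cell-per-gene prevalence filters; :func:`batch_adjust`
removes additive per-gene batch offsets while preserving the overall gene
mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionBundle",
    "GeneSet",
    "EnrichmentResult",
    "qc_filter_cells",
    "batch_adjust",
    "ssgsea",
    "compare_groups",
    "add_module_score",
    "compare_celltypes",
]


@dataclass
class ExpressionBundle:
    """A genes x columns expression matrix with per-column annotations.

    ``annotation`` is indexed by the matrix columns and carries ``group`` (bulk
    subtype) or ``cell_type`` plus ``batch``. ``mode`` is 'bulk' or
    'single_cell'.
    """

    matrix: pd.DataFrame
    annotation: pd.DataFrame
    mode: str = "bulk"

    def __post_init__(self) -> None:
        if self.matrix.index.duplicated().any():
            raise ValueError("duplicate gene names in expression matrix")
        if not self.matrix.columns.equals(self.annotation.index):
            self.annotation = self.annotation.reindex(self.matrix.columns)
            if self.annotation.isna().all(axis=1).any():
                raise ValueError("annotation does not cover all columns")


@dataclass
class GeneSet:
    name: str
    genes: list[str] = field(default_factory=list)


@dataclass
class EnrichmentResult:
    """Per-column enrichment scores and the comparison performed on them."""

    scores: pd.Series
    raw_scores: pd.Series | None = None
    statistic: float | None = None
    pvalue: float | None = None
    per_group: pd.DataFrame | None = None


_MT_PREFIX = ("MT-",)
_RIBO_PREFIX = ("RPS", "RPL")
_HB_PREFIX = ("HBA", "HBB")


def _family_fractions(matrix: pd.DataFrame) -> pd.DataFrame:
    names = matrix.index.str.upper()
    total = matrix.sum(axis=0).to_numpy(dtype=float)
    total = np.where(total == 0, 1.0, total)
    out = {}
    for key, prefixes in (("mt", _MT_PREFIX), ("ribo", _RIBO_PREFIX),
                          ("hb", _HB_PREFIX)):
        mask = names.str.startswith(prefixes)
        out[key] = matrix.loc[mask].sum(axis=0).to_numpy(dtype=float) / total
    return pd.DataFrame(out, index=matrix.columns)


def qc_filter_cells(bundle: ExpressionBundle, *, max_mt: float = 0.16,
                    min_ribo: float = 0.03, max_hb: float = 0.0,
                    min_genes: int = 200, min_cells: int = 3) -> ExpressionBundle:
    """Remove low-quality cells, then low-prevalence genes.

    A cell is excluded when its mitochondrial content exceeds ``max_mt``, its
    ribosomal content falls below ``min_ribo``, its hemoglobin content exceeds
    ``max_hb`` (any hemoglobin counts, by default), or it expresses fewer than
    ``min_genes`` genes. Genes expressed in fewer than ``min_cells`` remaining
    cells are then dropped.
    """
    if bundle.mode != "single_cell":
        raise ValueError("qc_filter_cells requires a single-cell bundle")
    mat = bundle.matrix
    frac = _family_fractions(mat)
    n_expressed = (mat > 0).sum(axis=0)
    keep = ((frac["mt"] <= max_mt) & (frac["ribo"] >= min_ribo)
            & (frac["hb"] <= max_hb) & (n_expressed >= min_genes))
    if not keep.any():
        raise ValueError("QC filter removed every cell")
    mat = mat.loc[:, keep.to_numpy()]
    gene_prev = (mat > 0).sum(axis=1)
    mat = mat.loc[gene_prev >= min_cells]
    return ExpressionBundle(matrix=mat,
                            annotation=bundle.annotation.loc[mat.columns],
                            mode="single_cell")


def batch_adjust(bundle: ExpressionBundle) -> ExpressionBundle:
    """Center each gene per batch, restoring the overall gene mean.

    A linear batch-covariate removal: with a single batch the data are
    returned unchanged.
    """
    if "batch" not in bundle.annotation.columns:
        return bundle
    batches = bundle.annotation["batch"]
    if batches.nunique() < 2:
        return bundle
    x = bundle.matrix.to_numpy(dtype=float)
    overall = x.mean(axis=1, keepdims=True)
    adj = x.copy()
    for b in batches.unique():
        cols = (batches == b).to_numpy()
        adj[:, cols] += overall[:, 0:1] - x[:, cols].mean(axis=1, keepdims=True)
    return ExpressionBundle(matrix=pd.DataFrame(adj, index=bundle.matrix.index,
                                                columns=bundle.matrix.columns),
                            annotation=bundle.annotation, mode=bundle.mode)


def _ssgsea_sample(expr: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Raw enrichment score of one sample (vectorised running-sum form)."""
    n = expr.size
    ranks = stats.rankdata(expr)              # average ties; highest gene ~ n
    order = np.argsort(-expr, kind="stable")  # walk from highest expression
    in_ord = in_set[order]
    w = ranks[order] ** alpha
    w_in = np.where(in_ord, w, 0.0)
    denom_in = w_in.sum()
    n_out = n - int(in_set.sum())
    cdf_in = np.cumsum(w_in) / denom_in
    cdf_out = np.cumsum(np.where(in_ord, 0.0, 1.0)) / max(n_out, 1)
    return float(np.sum(cdf_in - cdf_out))


def ssgsea(bundle: ExpressionBundle, gene_set: GeneSet | list[str],
           alpha: float = 0.25, normalize: bool = True) -> EnrichmentResult:
    """Single-sample GSEA scores for every column of the bundle.

    Raw scores are min-max normalised across the run's samples when
    ``normalize`` is set (the returned ``raw_scores`` keep the unnormalised
    values). Raises if the gene set does not intersect the matrix genes.
    """
    genes = list(gene_set.genes if isinstance(gene_set, GeneSet) else gene_set)
    in_set = bundle.matrix.index.isin(genes)
    if not in_set.any():
        raise ValueError("gene set does not intersect matrix genes")
    if in_set.all():
        raise ValueError("gene set covers every matrix gene")
    x = bundle.matrix.to_numpy(dtype=float)
    raw = np.array([_ssgsea_sample(x[:, j], in_set, alpha)
                    for j in range(x.shape[1])])
    scores = raw
    if normalize:
        span = raw.max() - raw.min()
        scores = (raw - raw.min()) / span if span > 0 else np.zeros_like(raw)
    return EnrichmentResult(
        scores=pd.Series(scores, index=bundle.matrix.columns),
        raw_scores=pd.Series(raw, index=bundle.matrix.columns))


def compare_groups(scores: pd.Series, groups: pd.Series) -> tuple[float, float]:
    """One-way ANOVA of enrichment scores across sample groups."""
    groups = groups.reindex(scores.index)
    samples = [scores[groups == g].to_numpy() for g in groups.unique()]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 samples each")
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)


def add_module_score(bundle: ExpressionBundle, gene_set: GeneSet | list[str],
                     n_bins: int = 24, n_ctrl: int = 100, seed: int = 0,
                     log_normalize: bool = True) -> EnrichmentResult:
    """Module score per cell: mean set expression minus matched-control mean.

    All genes are binned into ``n_bins`` by dataset-average expression; each
    signature gene contributes ``n_ctrl`` control genes drawn (seeded, with
    replacement) from its own bin, so the control pool is expression-matched.

    ``log_normalize`` applies per-cell library-size normalisation (to the
    median total) followed by log1p first — the scale on which module scores
    are conventionally defined; disable it when the matrix is already
    normalised log-expression.
    """
    genes = list(gene_set.genes if isinstance(gene_set, GeneSet) else gene_set)
    present = [g for g in genes if g in bundle.matrix.index]
    if not present:
        raise ValueError("gene set does not intersect matrix genes")
    rng = np.random.default_rng(seed)
    mat = bundle.matrix
    if log_normalize:
        totals = mat.sum(axis=0).to_numpy(dtype=float)
        totals = np.where(totals == 0, 1.0, totals)
        scaled = mat.to_numpy(dtype=float) * (np.median(totals) / totals)
        mat = pd.DataFrame(np.log1p(scaled), index=mat.index,
                           columns=mat.columns)
    avg = mat.mean(axis=1)
    bins = pd.qcut(avg.rank(method="first"), q=min(n_bins, len(avg)),
                   labels=False)
    by_bin = {b: np.flatnonzero(bins.to_numpy() == b) for b in np.unique(bins)}
    gene_pos = {g: i for i, g in enumerate(mat.index)}

    ctrl_rows: list[np.ndarray] = []
    n_small_bins = 0
    for g in present:
        pool = by_bin[int(bins.iloc[gene_pos[g]])]
        n_small_bins += len(pool) < n_ctrl
        ctrl_rows.append(rng.choice(pool, size=n_ctrl, replace=True))
    if n_small_bins:
        logger.warning("%d/%d signature genes sit in bins smaller than "
                       "n_ctrl=%d; controls drawn with replacement",
                       n_small_bins, len(present), n_ctrl)
    ctrl_idx = np.concatenate(ctrl_rows)
    x = mat.to_numpy(dtype=float)
    set_idx = np.array([gene_pos[g] for g in present])
    score = x[set_idx].mean(axis=0) - x[ctrl_idx].mean(axis=0)
    return EnrichmentResult(scores=pd.Series(score, index=mat.columns))


def compare_celltypes(scores: pd.Series, cell_types: pd.Series,
                      alternative: str = "greater",
                      min_cells: int = 3) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum test per cell type, BH-corrected.

    Returns a DataFrame indexed by cell type with columns statistic, pvalue,
    padj and median_score, sorted by adjusted p-value. Types with fewer than
    ``min_cells`` cells are skipped with a warning.
    """
    cell_types = cell_types.reindex(scores.index)
    rows = []
    for ct in cell_types.unique():
        mask = (cell_types == ct).to_numpy()
        if mask.sum() < min_cells or (~mask).sum() < min_cells:
            logger.warning("cell type %s has < %d cells; skipped", ct, min_cells)
            continue
        u, p = stats.mannwhitneyu(scores[mask], scores[~mask],
                                  alternative=alternative)
        rows.append((ct, float(u), float(p), float(scores[mask].median())))
    if not rows:
        raise ValueError("no cell type had enough cells to test")
    out = pd.DataFrame(rows, columns=["cell_type", "statistic", "pvalue",
                                      "median_score"]).set_index("cell_type")
    out["padj"] = multipletests(out["pvalue"].to_numpy(), method="fdr_bh")[1]
    return out.sort_values("padj")
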