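"""Drug-target / disease-gene intersection analysis.

Disease gene lists arrive with a relevance score; genes at or above the
threshold (default 10) are retained, intersected with drug-target lists
(case-normalized), and the overlap size is assessed with a hypergeometric
upper-tail test against an explicit gene universe.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom

__all__ = ["filter_disease_genes", "intersect", "overlap_significance",
           "overlap_analysis"]


def filter_disease_genes(scored: pd.DataFrame, min_score: float = 10.0
                         ) -> set[str]:
    """Symbols with relevance score >= ``min_score`` (inclusive), uppercased.

    Expects columns (gene, score); duplicate symbols keep their maximum
    score before thresholding.
    """
    df = scored.copy()
    df["gene"] = df["gene"].astype(str).str.upper().str.strip()
    df["score"] = pd.to_numeric(df["score"])
    best = df.groupby("gene")["score"].max()
    return set(best[best >= min_score].index)


def intersect(drug_targets: set[str], disease_genes: set[str]) -> list[str]:
    """Exact case-normalized intersection, sorted."""
    a = {str(g).upper().strip() for g in drug_targets}
    b = {str(g).upper().strip() for g in disease_genes}
    return sorted(a & b)


def overlap_significance(k: int, n1: int, n2: int, universe: int) -> float:
    """Hypergeometric upper tail P(X >= k) for an overlap of k between gene
    sets of sizes n1 and n2 drawn from an explicit universe."""
    if not (0 <= k <= min(n1, n2) <= universe) or max(n1, n2) > universe:
        raise ValueError("inconsistent overlap counts")
    return float(hypergeom.sf(k - 1, universe, n1, n2))


def overlap_analysis(drug_targets: set[str], disease_scored: pd.DataFrame,
                     universe: int, min_score: float = 10.0) -> dict:
    """Full pipeline step: filter, intersect, test. Returns a JSON-ready dict."""
    disease = filter_disease_genes(disease_scored, min_score=min_score)
    genes = intersect(drug_targets, disease)
    p = overlap_significance(len(genes), len(drug_targets), len(disease),
                             universe)
    return {"overlap": len(genes), "p": p, "genes": genes,
            "n_drug_targets": len(drug_targets),
            "n_disease_genes": len(disease), "universe": universe}
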