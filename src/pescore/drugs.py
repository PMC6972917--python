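"""Drug-target over-representation and top-drug selection per pathway.

For a candidate pathway of size n inside a gene universe of size N, a
drug with K target genes in the universe and k of them inside the
pathway gets the hypergeometric upper-tail P value P(X >= k).  P values
are Benjamini-Hochberg adjusted across the drugs tested for that pathway
(per-pathway correction); enriched drugs must reach q < 0.05 with an
overlap of at least three target genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class DrugEnrichmentResult:
    pathway: str
    drug_name: str
    overlap_genes: set
    overlap_k: int
    universe_n: int
    drug_targets_k: int
    pathway_size_n: int
    pvalue: float
    fdr_q: float
    atc_code: str
    significant: bool  # q < alpha and overlap >= min_overlap


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q values, order-preserving with input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("P values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def hypergeom_upper_tail(k, universe_n, drug_targets_k, pathway_n) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, universe_n, drug_targets_k, pathway_n))


def drug_ora(pathway, interactions, universe, min_overlap=3, fdr_alpha=0.05,
             keep_all=False) -> list:
    """Over-representation of each drug's targets in one pathway.

    Parameters
    ----------
    pathway : :class:`~pescore.io.GeneSet`
    interactions : DataFrame
        Drug-gene interaction table (``drug_name, gene_id, atc_code`` used).
    universe : iterable of gene ids
        Background gene universe; must contain the pathway's genes.
        Target genes outside the universe are ignored.
    keep_all : bool
        Return every tested drug rather than only the enriched ones.

    Returns results sorted by (q, -overlap, drug name); ``significant``
    marks ``q < fdr_alpha and overlap >= min_overlap``.  Drugs with no
    target in the pathway are not tested.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    if not pathway.genes <= universe:
        logger.warning("drug_ora: %d pathway genes outside the universe are ignored",
                       len(pathway.genes - universe))
    path_genes = pathway.genes & universe
    n = len(path_genes)
    big_n = len(universe)

    results = []
    for drug, block in interactions.groupby("drug_name", sort=True):
        targets = set(block["gene_id"]) & universe
        overlap = targets & path_genes
        if not overlap:
            continue
        p = hypergeom_upper_tail(len(overlap), big_n, len(targets), n)
        atc = next((a for a in block.get("atc_code", []) if a), "")
        results.append(DrugEnrichmentResult(
            pathway=pathway.name, drug_name=drug, overlap_genes=overlap,
            overlap_k=len(overlap), universe_n=big_n, drug_targets_k=len(targets),
            pathway_size_n=n, pvalue=max(p, np.finfo(float).tiny), fdr_q=np.nan,
            atc_code=atc, significant=False,
        ))
    if not results:
        return []
    q = bh_adjust([r.pvalue for r in results])
    for r, qi in zip(results, q):
        r.fdr_q = float(qi)
        r.significant = bool(qi < fdr_alpha and r.overlap_k >= min_overlap)
    results.sort(key=lambda r: (r.fdr_q, -r.overlap_k, r.drug_name))
    if not keep_all:
        results = [r for r in results if r.significant]
    return results


def select_top_drug(pathway, interactions, mode="interaction_score", universe=None,
                    ora_results=None):
    """Pick the single best drug for a pathway.

    ``interaction_score`` mode (default): among approved drugs, the
    interaction with the highest confidence score between a druggable
    pathway gene and the drug (ties by drug name).  ``ora`` mode: the
    over-representation result with the smallest q; ties prefer the
    larger target overlap, then the lexicographically first drug name.

    Returns the winning interaction row (as a Series) or
    :class:`DrugEnrichmentResult`, or ``None`` with a warning when the
    pathway has no eligible drug.
    """
    if mode == "interaction_score":
        genes = pathway.druggable_genes or pathway.genes
        block = interactions.loc[
            interactions["approved"] & interactions["gene_id"].isin(genes)
        ]
        if block.empty:
            logger.warning("select_top_drug: no approved interaction for %r", pathway.name)
            return None
        block = block.sort_values(["interaction_score", "drug_name"],
                                  ascending=[False, True], kind="mergesort")
        return block.iloc[0]
    if mode == "ora":
        if ora_results is None:
            if universe is None:
                raise ValueError("ora mode needs ora_results or a universe")
            ora_results = drug_ora(pathway, interactions, universe, keep_all=True)
        if not ora_results:
            logger.warning("select_top_drug: no tested drug for %r", pathway.name)
            return None
        return min(ora_results, key=lambda r: (r.fdr_q, -r.overlap_k, r.drug_name))
    raise ValueError(f"unknown mode {mode!r}")
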