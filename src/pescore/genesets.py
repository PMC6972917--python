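"""Competitive gene-set association and candidate pathway selection.

The competitive test regresses gene-level Z scores on a set-membership
indicator with gene-size covariates,

    gene_z ~ 1 + in_set + M + log M,

asking whether genes inside the pathway are more strongly associated
than genes outside it (one-sided P on the membership coefficient).
Pathways reaching P < 0.001 at any P_T become PES candidates; when a
pathway is associated at several thresholds the most significant one is
kept (ties broken toward the more stringent threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class DegenerateDesignError(ValueError):
    """The set covers all or none of the tested genes."""


@dataclass
class GeneSetResult:
    set_name: str
    p_threshold: float
    beta: float
    se: float
    pvalue: float      # one-sided, enrichment alternative
    n_genes_in_set: int


@dataclass
class CandidatePathway:
    """A pathway selected for PES construction, with its chosen P_T."""

    set_name: str
    p_threshold: float
    pvalue: float
    genes: set
    druggable_genes: set = field(default_factory=set)


def competitive_set_test(gene_results: pd.DataFrame, gene_set,
                         p_threshold=None) -> GeneSetResult:
    """Competitive association of one gene set at one P_T.

    Parameters
    ----------
    gene_results : DataFrame
        Rows for a single ``p_threshold`` with columns
        ``gene, n_snps, gene_z``.
    gene_set : :class:`~pescore.io.GeneSet`
    """
    if p_threshold is None:
        levels = gene_results["p_threshold"].unique() if "p_threshold" in gene_results else [np.nan]
        if len(levels) > 1:
            raise ValueError("gene_results mixes several P_T; pass p_threshold")
        p_threshold = float(levels[0])
    member = gene_results["gene"].isin(gene_set.genes).to_numpy(dtype=float)
    n_in = int(member.sum())
    n = len(gene_results)
    if n_in < 2 or n - n_in < 2:
        raise DegenerateDesignError(
            f"set {gene_set.name!r}: {n_in} genes inside / {n - n_in} outside at P_T={p_threshold}"
        )
    z = gene_results["gene_z"].to_numpy(dtype=float)
    m = gene_results["n_snps"].to_numpy(dtype=float)
    x = np.column_stack([np.ones(n), member, m, np.log(m)])
    coef, _, rank, _ = np.linalg.lstsq(x, z, rcond=None)
    resid = z - x @ coef
    dof = n - rank
    if dof <= 0:
        raise DegenerateDesignError(f"set {gene_set.name!r}: no residual degrees of freedom")
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(x.T @ x)
    se = float(np.sqrt(max(sigma2 * xtx_inv[1, 1], 0.0)))
    beta = float(coef[1])
    eps = 1e-10 * max(1.0, float(np.abs(z).max()))
    if se <= eps:
        # exact fit: a constant response carries no evidence either way
        if abs(beta) <= eps:
            beta, pvalue = 0.0, 0.5
        else:
            pvalue = np.finfo(float).tiny if beta > 0 else 1.0
    else:
        pvalue = float(stats.t.sf(beta / se, dof))
    return GeneSetResult(set_name=gene_set.name, p_threshold=float(p_threshold),
                         beta=beta, se=se, pvalue=pvalue, n_genes_in_set=n_in)


def run_set_analysis(gene_results: pd.DataFrame, gene_sets) -> pd.DataFrame:
    """Competitive test of every set at every P_T present in ``gene_results``.

    Degenerate designs (a set covering none or all tested genes at a
    threshold) are skipped with a log entry.  Returns columns
    ``set_name, p_threshold, beta, se, pvalue, n_genes_in_set``.
    """
    rows = []
    for p_t, block in gene_results.groupby("p_threshold", sort=False):
        for gs in gene_sets:
            try:
                r = competitive_set_test(block, gs, p_threshold=p_t)
            except DegenerateDesignError as exc:
                logger.info("run_set_analysis: skipping %s", exc)
                continue
            rows.append((r.set_name, r.p_threshold, r.beta, r.se, r.pvalue, r.n_genes_in_set))
    return pd.DataFrame(rows, columns=["set_name", "p_threshold", "beta", "se",
                                       "pvalue", "n_genes_in_set"])


def select_candidates(set_results: pd.DataFrame, gene_sets, alpha=0.001) -> list:
    """Select PES candidate pathways: competitive P < ``alpha`` at any P_T.

    For a pathway associated at several thresholds the most significant is
    chosen; exact P ties prefer the more stringent (smaller) threshold.
    """
    by_name = {gs.name: gs for gs in gene_sets}
    candidates = []
    for name, block in set_results.groupby("set_name", sort=False):
        hits = block.loc[block["pvalue"] < alpha]
        if hits.empty:
            continue
        best = hits.sort_values(["pvalue", "p_threshold"],
                                ascending=[True, True], kind="mergesort").iloc[0]
        gs = by_name.get(name)
        if gs is None:
            logger.warning("select_candidates: %r missing from gene_sets; skipped", name)
            continue
        candidates.append(CandidatePathway(
            set_name=name, p_threshold=float(best["p_threshold"]),
            pvalue=float(best["pvalue"]), genes=set(gs.genes),
            druggable_genes=set(gs.druggable_genes),
        ))
    candidates.sort(key=lambda c: (c.pvalue, c.set_name))
    return candidates
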