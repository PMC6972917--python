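"""PES effects on the expression of each pathway's own genes.

For every (pathway, gene) pair with expression available, the model

    expression_g ~ PES_pathway + age + sex + PRS_Total

is fitted by OLS; the standardised coefficient t = beta / SE gives a
two-sided P on the residual degrees of freedom, adjusted per pathway by
Benjamini-Hochberg with an exploratory FDR < 0.1 cut-off.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .drugs import bh_adjust

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["pathway", "gene", "beta", "se", "t", "pvalue", "qvalue",
                  "n", "significant"]


def pes_expression_scan(scores: pd.DataFrame, expression: pd.DataFrame,
                        phenotypes: pd.DataFrame, pathways,
                        covariates=("age", "sex"), prs_column="PRS_TOTAL",
                        fdr_alpha=0.1, standardise_expression=False) -> pd.DataFrame:
    """Association of each PES with expression of its pathway's genes.

    Parameters
    ----------
    scores : individuals x score columns (PES columns named ``PES_<set>``
        plus the genome-wide PRS column).
    expression : genes x individuals matrix, pre-normalised.
    pathways : iterable of :class:`~pescore.genesets.CandidatePathway`
        (anything with ``set_name`` and ``genes``).

    Returns one row per (pathway, gene) with expression available, BH
    adjusted within pathway; genes in several pathways are tested once
    per pathway.  Pathways whose design is degenerate (constant PES or
    n <= parameters) are skipped with a warning.
    """
    samples = [s for s in scores.index if s in expression.columns
               and s in phenotypes.index]
    if not samples:
        raise ValueError("no samples shared between scores, expression and phenotypes")
    pheno = phenotypes.loc[samples]
    covs = [c for c in covariates if c in pheno.columns]
    base = [np.ones(len(samples))] + [pheno[c].to_numpy(dtype=float) for c in covs]
    if prs_column in scores.columns:
        base.append(scores.loc[samples, prs_column].to_numpy(dtype=float))

    rows = []
    for pathway in pathways:
        col = f"PES_{pathway.set_name}"
        if col not in scores.columns:
            logger.warning("pes_expression_scan: no score column for %r", pathway.set_name)
            continue
        pes = scores.loc[samples, col].to_numpy(dtype=float)
        if np.ptp(pes) == 0:
            logger.warning("pes_expression_scan: %r PES constant; skipped", pathway.set_name)
            continue
        xmat = np.column_stack([base[0], pes, *base[1:]])
        n, p = xmat.shape
        if n <= p:
            logger.warning("pes_expression_scan: %r skipped (n=%d <= %d parameters)",
                           pathway.set_name, n, p)
            continue
        genes = sorted(g for g in pathway.genes if g in expression.index)
        if not genes:
            continue
        xtx_inv = np.linalg.pinv(xmat.T @ xmat)
        hat = xtx_inv @ xmat.T
        pvals, partial = [], []
        for gene in genes:
            e = expression.loc[gene, samples].to_numpy(dtype=float)
            if standardise_expression:
                sd = e.std()
                e = (e - e.mean()) / (sd if sd > 0 else 1.0)
            coef = hat @ e
            resid = e - xmat @ coef
            sigma2 = float(resid @ resid) / (n - p)
            se = float(np.sqrt(max(sigma2 * xtx_inv[1, 1], 0.0)))
            beta = float(coef[1])
            t = beta / se if se > 0 else 0.0
            pv = float(2 * stats.t.sf(abs(t), n - p)) if se > 0 else 1.0
            pvals.append(max(pv, np.finfo(float).tiny))
            partial.append((beta, se, t))
        qvals = bh_adjust(pvals)
        for gene, (beta, se, t), pv, qv in zip(genes, partial, pvals, qvals):
            rows.append((pathway.set_name, gene, beta, se, t, pv, float(qv), n,
                         bool(qv < fdr_alpha)))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def count_tested_genes(pathways, expression: pd.DataFrame):
    """Genes with expression available per pathway, and their total.

    A gene that belongs to several pathways is counted once per pathway.
    Returns ``(per_pathway: dict, total: int)``.
    """
    available = set(expression.index)
    per = {p.set_name: len(set(p.genes) & available) for p in pathways}
    return per, int(sum(per.values()))
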