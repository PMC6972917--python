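"""LD clumping, pathway-restricted scores (PES) and genome-wide PRS.

A score is the additive model

    score_i = sum_j beta_j * G_ij,

the GWAS effect size of each retained variant multiplied by the
individual's dosage of its counted allele, summed over the variants of a
score definition (a raw sum, no per-SNP averaging).  A PES restricts the
variants to those mapped to one candidate pathway's genes at the
pathway's own P_T; PRS_Total uses all clumped variants at the P_T that
maximises the Nagelkerke R-squared increment over covariates in a
case-control logistic model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genes import subset_by_threshold

logger = logging.getLogger(__name__)

#: default P_T grid for genome-wide PRS optimisation
DEFAULT_PRS_GRID = (5e-8, 1e-5, 1e-3, 0.01, 0.05, 0.1, 0.2, 0.5, 1.0)


@dataclass
class ScoreDefinition:
    """The variants and aligned effect sizes behind one score column."""

    name: str
    snp_ids: list
    betas: np.ndarray
    p_threshold: float
    pathway: str = "TOTAL"

    def __post_init__(self):
        self.betas = np.asarray(self.betas, dtype=float)
        if len(self.snp_ids) == 0:
            raise ValueError(f"score {self.name!r} has no SNPs")
        if len(self.snp_ids) != self.betas.size or not np.isfinite(self.betas).all():
            raise ValueError(f"score {self.name!r}: effects misaligned or non-finite")


@dataclass
class PRSOptimizationResult:
    grid: list
    r2: list                    # Nagelkerke R^2 increment per P_T
    chosen_p_threshold: float
    n_snps: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"p_threshold": self.grid, "nagelkerke_r2": self.r2})


def ld_clump(sumstats: pd.DataFrame, reference, r2=0.1, window_kb=250,
             p_max=1.0) -> list:
    """Greedy LD clumping; returns the retained SNP ids.

    SNPs are visited by ascending P (ties broken by snp_id); each index
    SNP removes not-yet-retained SNPs within ``window_kb`` whose squared
    dosage correlation with it exceeds ``r2``.  SNPs absent from the
    reference are treated as unlinked (retained if reached).
    """
    if r2 <= 0 or window_kb <= 0:
        raise ValueError("clump parameters must be positive")
    ss = sumstats.loc[sumstats["pvalue"] <= p_max] if p_max < 1.0 else sumstats
    ss = ss.sort_values(["pvalue", "snp_id"], kind="mergesort")

    ref_idx = reference.variants.set_index("snp_id").index
    dos = reference.mean_imputed()
    dos = dos - dos.mean(axis=0)
    norms = np.sqrt((dos ** 2).sum(axis=0))
    norms[norms == 0] = np.inf

    retained = []
    window = window_kb * 1000
    for chrom, block in ss.groupby("chrom", sort=False):
        alive = np.ones(len(block), dtype=bool)
        pos = block["pos"].to_numpy()
        ids = block["snp_id"].to_numpy()
        cols = ref_idx.get_indexer(ids)
        n_unref = int((cols < 0).sum())
        if n_unref:
            logger.info("ld_clump: %d SNPs on chrom %s absent from reference (unlinked)",
                        n_unref, chrom)
        for i in range(len(block)):
            if not alive[i]:
                continue
            retained.append(ids[i])
            if cols[i] < 0:
                continue
            near = np.nonzero(np.abs(pos - pos[i]) <= window)[0]
            near = near[(near != i) & alive[near] & (cols[near] >= 0)]
            if near.size == 0:
                continue
            gi = dos[:, cols[i]]
            gn = dos[:, cols[near]]
            with np.errstate(invalid="ignore"):
                corr = (gi @ gn) / (norms[cols[i]] * norms[cols[near]])
            alive[near[np.nan_to_num(corr) ** 2 > r2]] = False
    return retained


def compute_score(defn: ScoreDefinition, gm, standardise_by_snp_count=False) -> np.ndarray:
    """Evaluate a score on a genotype matrix (alleles must be harmonised).

    SNPs in the definition but absent from ``gm`` are dropped with a log
    entry; missing dosages are mean-imputed per variant.  Returns one
    value per individual in ``gm``.
    """
    idx = gm.variants.set_index("snp_id").index.get_indexer(defn.snp_ids)
    present = idx >= 0
    if not present.any():
        raise ValueError(f"score {defn.name!r}: no overlapping SNPs in genotype matrix")
    if not present.all():
        logger.info("compute_score(%s): %d/%d SNPs absent from genotypes",
                    defn.name, int((~present).sum()), present.size)
    d = gm.mean_imputed()[:, idx[present]]
    score = d @ defn.betas[present]
    if standardise_by_snp_count:
        score = score / int(present.sum())
    return score


def build_pes_definitions(candidates, sumstats: pd.DataFrame, gene_map: dict,
                          reference, r2=0.1, window_kb=250) -> list:
    """One :class:`ScoreDefinition` per candidate pathway.

    For each pathway: take the SNPs mapped to its genes, keep those below
    the pathway's chosen P_T, LD-clump them, and pair the survivors with
    their (harmonised) effect sizes.  Pathways with no surviving SNP are
    skipped with a warning.
    """
    defs = []
    for cand in candidates:
        snps = sorted({s for g in cand.genes for s in gene_map.get(g, [])})
        ss = sumstats.loc[sumstats["snp_id"].isin(snps)]
        ss = subset_by_threshold(ss, cand.p_threshold)
        if ss.empty:
            logger.warning("build_pes_definitions: %r has no SNPs at P_T=%g; skipped",
                           cand.set_name, cand.p_threshold)
            continue
        kept = ld_clump(ss, reference, r2=r2, window_kb=window_kb)
        if not kept:
            logger.warning("build_pes_definitions: %r empty after clumping; skipped",
                           cand.set_name)
            continue
        betas = ss.set_index("snp_id")["beta"].loc[kept].to_numpy()
        defs.append(ScoreDefinition(name=f"PES_{cand.set_name}", snp_ids=list(kept),
                                    betas=betas, p_threshold=cand.p_threshold,
                                    pathway=cand.set_name))
    return defs


def nagelkerke_r2(loglik_null: float, loglik_full: float, n: int) -> float:
    """Nagelkerke pseudo R-squared from two log-likelihoods.

    ``R2 = [1 - exp((2/n)(L0 - L1))] / [1 - exp((2/n) L0)]``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if loglik_full < loglik_null - 1e-9:
        raise ValueError("full-model log-likelihood below null log-likelihood")
    denom = 1.0 - np.exp(2.0 * loglik_null / n)
    if denom == 0.0:
        raise ValueError("saturated null (L0 = 0): Nagelkerke R^2 undefined")
    r2 = (1.0 - np.exp(2.0 * (loglik_null - loglik_full) / n)) / denom
    return float(min(max(r2, 0.0), 1.0))


def _logit_loglik(y, x) -> float:
    model = sm.Logit(y, x)
    return float(model.fit(disp=0, maxiter=200).llf)


def optimise_total_prs(sumstats: pd.DataFrame, gm, phenotypes: pd.DataFrame,
                       grid=DEFAULT_PRS_GRID, covariates=("sex", "PC1", "PC2", "PC3"),
                       r2=0.1, window_kb=250, name="PRS_TOTAL"):
    """Genome-wide PRS with P_T chosen by Nagelkerke R-squared increment.

    Clumping is applied once at ``p_max = 1``; each grid P_T then
    thresholds the clumped SNPs, scores the cohort and fits
    ``case_status ~ covariates + score`` against the covariate-only
    logistic model.  The reported R-squared is the Nagelkerke increment;
    the chosen P_T maximises it (ties toward the smaller P_T).

    Returns ``(PRSOptimizationResult, ScoreDefinition)``.
    """
    grid = sorted(grid)
    if not grid:
        raise ValueError("empty P_T grid")
    pheno = phenotypes.loc[[str(s) for s in gm.samples]]
    y = pheno["case_status"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("phenotype has a single class")
    covs = [c for c in covariates if c in pheno.columns]
    x0 = np.column_stack([np.ones(len(y))] + [pheno[c].to_numpy(dtype=float) for c in covs])
    ll0 = _logit_loglik(y, x0)

    clumped = ld_clump(sumstats, gm, r2=r2, window_kb=window_kb, p_max=1.0)
    ss = sumstats.set_index("snp_id").loc[clumped]

    r2_values, defs = [], []
    for p_t in grid:
        sel = ss.loc[ss["pvalue"] < p_t] if p_t < 1.0 else ss
        if sel.empty:
            r2_values.append(0.0)
            defs.append(None)
            continue
        defn = ScoreDefinition(name=name, snp_ids=list(sel.index),
                               betas=sel["beta"].to_numpy(), p_threshold=p_t)
        score = compute_score(defn, gm)
        x1 = np.column_stack([x0, score])
        ll1 = _logit_loglik(y, x1)
        r2_values.append(nagelkerke_r2(ll0, max(ll1, ll0), len(y)))
        defs.append(defn)
    best = int(np.argmax(r2_values))  # argmax takes the first (smallest P_T) on ties
    if defs[best] is None:
        raise ValueError("no SNPs at any grid threshold")
    result = PRSOptimizationResult(grid=list(grid), r2=r2_values,
                                   chosen_p_threshold=float(grid[best]),
                                   n_snps=len(defs[best].snp_ids))
    return result, defs[best]


def score_matrix(definitions, gm, standardise_by_snp_count=False) -> pd.DataFrame:
    """Evaluate several score definitions into an individuals x scores frame."""
    data = {d.name: compute_score(d, gm, standardise_by_snp_count) for d in definitions}
    df = pd.DataFrame(data, index=[str(s) for s in gm.samples])
    df.index.name = "sample_id"
    return df
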