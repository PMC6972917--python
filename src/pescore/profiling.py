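"""Individual PES profiles: percentile carriers, case-control association,
Gaussian-mixture clustering and cluster enrichment.

Elevated-score carriers are defined by nearest-rank percentiles of the
study population (75th, 90th, 99th by default; boundary ties are all
flagged).  Score / carrier-count association with case status is a
binomial logistic regression adjusted for sex and principal components,
with and without PRS_Total as an extra covariate, P values by Wald test.

The joint structure of (PRS_Total, elevated-PES count) is clustered with
finite Gaussian mixtures fitted by EM over six covariance families
(spherical / diagonal / full, each with equal or per-component
parameters), the number of clusters chosen by the highest
``BIC = 2 loglik - k_params ln(n)`` (mixture-modelling convention:
higher is better).  Cluster over-representation of top-percentile
carriers is tested by multinomial logistic regression against the
largest cluster.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_LEVELS = (0.75, 0.90, 0.99)

GMM_FAMILIES = (
    ("spherical", "equal"), ("spherical", "variable"),
    ("diagonal", "equal"), ("diagonal", "variable"),
    ("full", "equal"), ("full", "variable"),
)


class DegenerateDesignError(ValueError):
    pass


# ---------------------------------------------------------------------------
# percentile profiling
# ---------------------------------------------------------------------------

@dataclass
class PercentileFlags:
    """Per-individual elevated-score flags and counts.

    ``flags[level]`` is a boolean individuals x scores frame; ``counts``
    has one ``n<level>`` column per level (row sums of the flags).
    """

    flags: dict
    counts: pd.DataFrame


def flag_percentiles(scores: pd.DataFrame, levels=DEFAULT_LEVELS) -> PercentileFlags:
    """Flag individuals in the top (1 - level) fraction of each score.

    Nearest-rank rule: with N individuals, the top ``ceil((1 - level) N)``
    ranks are flagged; individuals tied exactly at the boundary value are
    all flagged.
    """
    n = len(scores)
    if n < 2:
        raise ValueError("need at least two individuals to rank")
    flags = {}
    for level in sorted(levels):
        if not 0 < level < 1:
            raise ValueError(f"percentile level {level} outside (0, 1)")
        # round before ceil: (1 - 0.99) * 100 is 1.0000000000000009 in binary
        k = math.ceil(round((1.0 - level) * n, 9))
        frame = pd.DataFrame(index=scores.index)
        for col in scores.columns:
            v = scores[col].to_numpy(dtype=float)
            if np.ptp(v) == 0:
                logger.warning("flag_percentiles: score %r is constant; all flagged", col)
            boundary = np.sort(v)[n - k]
            frame[col] = v >= boundary
        flags[level] = frame
    counts = pd.DataFrame(
        {f"n{round(level * 100)}": flags[level].sum(axis=1) for level in sorted(levels)},
        index=scores.index,
    )
    return PercentileFlags(flags=flags, counts=counts)


# ---------------------------------------------------------------------------
# case-control association
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    term: str
    beta: float
    se: float
    z: float
    wald_p: float
    odds_ratio: float
    ci95_low: float
    ci95_high: float
    covariates: tuple
    prs_adjusted: bool


def associate_with_case(predictor, phenotypes: pd.DataFrame, term="score",
                        covariates=("sex", "PC1", "PC2", "PC3"),
                        adjust_prs=False, prs=None) -> AssociationResult:
    """Logistic association of a score or carrier count with case status.

    Fits ``case_status ~ predictor + covariates (+ PRS_Total)`` by maximum
    likelihood and reports the Wald test on the predictor with OR and 95%
    CI.  Raises :class:`DegenerateDesignError` for a constant predictor or
    separation.
    """
    x = np.asarray(predictor, dtype=float)
    y = phenotypes["case_status"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise DegenerateDesignError("phenotype has a single class")
    if np.ptp(x) == 0:
        raise DegenerateDesignError(f"predictor {term!r} is constant")
    covs = [c for c in covariates if c in phenotypes.columns]
    design = [np.ones(len(y))] + [phenotypes[c].to_numpy(dtype=float) for c in covs]
    if adjust_prs:
        if prs is None:
            raise ValueError("adjust_prs=True requires the PRS_Total vector")
        design.append(np.asarray(prs, dtype=float))
    design.append(x)
    xmat = np.column_stack(design)
    try:
        fit = sm.Logit(y, xmat).fit(disp=0, maxiter=200)
    except Exception as exc:  # PerfectSeparationError and friends
        raise DegenerateDesignError(f"logistic fit failed for {term!r}: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise DegenerateDesignError(f"logistic fit did not converge for {term!r}")
    beta, se = float(fit.params[-1]), float(fit.bse[-1])
    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    return AssociationResult(
        term=term, beta=beta, se=se, z=z, wald_p=max(p, np.finfo(float).tiny),
        odds_ratio=float(np.exp(beta)),
        ci95_low=float(np.exp(beta - 1.96 * se)), ci95_high=float(np.exp(beta + 1.96 * se)),
        covariates=tuple(covs), prs_adjusted=bool(adjust_prs),
    )


# ---------------------------------------------------------------------------
# Gaussian mixture model
# ---------------------------------------------------------------------------

@dataclass
class GMMFit:
    """A fitted Gaussian mixture: parameters, likelihood, BIC, assignments."""

    model_name: str
    k: int
    weights: np.ndarray
    means: np.ndarray          # (k, d)
    covariances: np.ndarray    # (k, d, d)
    loglik: float
    n_params: int
    bic: float                 # 2 loglik - n_params ln(n); higher is better
    assignments: np.ndarray
    n: int
    loglik_history: list


class _EMDegenerate(RuntimeError):
    pass


def _n_cov_params(family: str, shared: str, k: int, d: int) -> int:
    per = {"spherical": 1, "diagonal": d, "full": d * (d + 1) // 2}[family]
    return per if shared == "equal" else k * per


def _log_gaussian_all(x, means, covs):
    """(n, k) log-density of every point under every component."""
    d = x.shape[1]
    sign, logdet = np.linalg.slogdet(covs)
    if (sign <= 0).any():
        raise _EMDegenerate("non-PD covariance")
    covinv = np.linalg.inv(covs)
    diff = x[:, None, :] - means[None, :, :]
    maha = np.einsum("nkd,kde,nke->nk", diff, covinv, diff)
    return -0.5 * (d * np.log(2 * np.pi) + logdet[None, :] + maha)


def _m_step_cov(x, resp, means, nk, family, shared, floor):
    n, d = x.shape
    k = means.shape[0]
    diff = x[:, None, :] - means[None, :, :]
    scat = np.einsum("nk,nkd,nke->kde", resp, diff, diff) / nk[:, None, None]
    if shared == "equal":
        pooled = np.einsum("k,kij->ij", nk / n, scat)
        scat = np.broadcast_to(pooled, (k, d, d)).copy()
    if family == "diagonal":
        out = np.zeros_like(scat)
        idx = np.arange(d)
        out[:, idx, idx] = np.maximum(scat[:, idx, idx], floor)
        return out
    if family == "spherical":
        out = np.zeros_like(scat)
        idx = np.arange(d)
        var = np.maximum(scat[:, idx, idx].mean(axis=1), floor)
        out[:, idx, idx] = var[:, None]
        return out
    # full: floor the eigenvalues
    for j in range(k):
        scat[j] = (scat[j] + scat[j].T) / 2
        w = np.linalg.eigvalsh(scat[j])
        if w.min() < floor:
            scat[j] += (floor - w.min()) * np.eye(d)
    return scat


def _em_once(x, k, family, shared, rng, tol, max_iter):
    n, d = x.shape
    floor = 1e-6 * np.trace(np.cov(x, rowvar=False).reshape(d, d)) / d + 1e-12
    # k-means initialisation
    if k == 1:
        resp = np.ones((n, 1))
    else:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, n_init=1,
                    random_state=int(rng.integers(2 ** 31 - 1))).fit(x)
        resp = np.zeros((n, k))
        resp[np.arange(n), km.labels_] = 1.0

    loglik, history = -np.inf, []
    weights = means = covs = None
    for _ in range(max_iter):
        nk = resp.sum(axis=0)
        if (nk < 1e-8).any():
            raise _EMDegenerate("empty component")
        weights = nk / n
        means = (resp.T @ x) / nk[:, None]
        covs = _m_step_cov(x, resp, means, nk, family, shared, floor)
        log_resp = np.log(weights)[None, :] + _log_gaussian_all(x, means, covs)
        peak = log_resp.max(axis=1)
        norm = peak + np.log(np.exp(log_resp - peak[:, None]).sum(axis=1))
        new_loglik = float(norm.sum())
        if not np.isfinite(new_loglik):
            raise _EMDegenerate("non-finite log-likelihood")
        if new_loglik < loglik - 1e-6 * (1 + abs(loglik)):
            raise _EMDegenerate("log-likelihood decreased")  # guards the EM invariant
        history.append(new_loglik)
        resp = np.exp(log_resp - norm[:, None])
        if loglik > -np.inf and new_loglik - loglik < tol * (1 + abs(new_loglik)):
            loglik = new_loglik
            break
        loglik = new_loglik
    assignments = np.argmax(resp, axis=1)
    return weights, means, covs, loglik, assignments, history


def fit_gmm(points, k_range=range(1, 10), families=GMM_FAMILIES, n_init=10,
            seed=0, tol=1e-6, max_iter=500):
    """Fit Gaussian mixtures over a (family, K) grid and select by BIC.

    Parameters
    ----------
    points : (n, d) array
        Typically ``(PRS_Total, elevated-PES count)`` pairs.
    k_range : iterable of int
    families : iterable of (family, sharing) pairs
        ``family in {spherical, diagonal, full}``, sharing in
        ``{equal, variable}`` across components.
    n_init : int
        Seeded k-means restarts per candidate; best log-likelihood kept.

    Returns
    -------
    (best : GMMFit, bic_table : DataFrame)
        ``bic_table`` has one row per fitted (model, K) candidate;
        degenerate candidates are dropped with a log entry.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    rows, fits = [], []
    for family, shared in families:
        for k in k_range:
            if n <= k:
                continue
            best = None
            for _ in range(n_init if k > 1 else 1):
                try:
                    cand = _em_once(x, k, family, shared, rng, tol, max_iter)
                except (_EMDegenerate, np.linalg.LinAlgError) as exc:
                    logger.info("fit_gmm: %s-%s K=%d restart discarded (%s)",
                                family, shared, k, exc)
                    continue
                if best is None or cand[3] > best[3]:
                    best = cand
            if best is None:
                continue
            weights, means, covs, loglik, assignments, history = best
            n_params = (k - 1) + k * x.shape[1] + _n_cov_params(family, shared, k, x.shape[1])
            bic = 2.0 * loglik - n_params * np.log(n)
            fit = GMMFit(model_name=f"{family}-{shared}", k=k, weights=weights,
                         means=means, covariances=covs, loglik=loglik,
                         n_params=n_params, bic=bic, assignments=assignments,
                         n=n, loglik_history=history)
            fits.append(fit)
            rows.append((fit.model_name, k, loglik, n_params, bic))
    if not fits:
        raise ValueError("no GMM candidate could be fitted")
    table = pd.DataFrame(rows, columns=["model", "k", "loglik", "n_params", "bic"])
    best = max(fits, key=lambda f: f.bic)
    return best, table


# ---------------------------------------------------------------------------
# cluster enrichment
# ---------------------------------------------------------------------------

def cluster_enrichment(assignments, carrier_flag, phenotypes: pd.DataFrame,
                       covariates=("sex", "PC1", "PC2", "PC3"),
                       min_cluster_size=5) -> list:
    """Multinomial test of carrier over-representation per cluster.

    Cluster membership is regressed on the top-percentile carrier flag
    plus covariates; the largest cluster is the reference outcome.
    Clusters smaller than ``min_cluster_size`` are dropped.  Returns one
    :class:`AssociationResult` per non-reference cluster (the ``beta`` is
    the carrier coefficient of that cluster's contrast; odds-ratio fields
    are relative-risk ratios vs the reference cluster).
    """
    assignments = np.asarray(assignments)
    labels, counts = np.unique(assignments, return_counts=True)
    keep_labels = labels[counts >= min_cluster_size]
    dropped = set(labels) - set(keep_labels)
    if dropped:
        logger.info("cluster_enrichment: dropping small clusters %s", sorted(dropped))
    mask = np.isin(assignments, keep_labels)
    if len(keep_labels) < 2:
        raise DegenerateDesignError("fewer than two clusters of usable size")
    sub = assignments[mask]
    labels, counts = np.unique(sub, return_counts=True)
    reference = labels[np.argmax(counts)]
    # recode so the reference cluster is outcome 0
    others = [c for c in labels if c != reference]
    code = {reference: 0, **{c: i + 1 for i, c in enumerate(others)}}
    y = np.array([code[c] for c in sub])

    pheno = phenotypes.loc[mask] if len(phenotypes) == len(assignments) else phenotypes
    covs = [c for c in covariates if c in pheno.columns]
    xmat = np.column_stack(
        [np.ones(mask.sum()), np.asarray(carrier_flag, dtype=float)[mask]]
        + [pheno[c].to_numpy(dtype=float) for c in covs]
    )
    fit = sm.MNLogit(y, xmat).fit(disp=0, maxiter=500, method="newton")
    params, bse = np.asarray(fit.params), np.asarray(fit.bse)  # (n_vars, k-1)
    results = []
    for i, cluster in enumerate(others):
        beta, se = float(params[1, i]), float(bse[1, i])
        z = beta / se
        p = float(2 * stats.norm.sf(abs(z)))
        results.append(AssociationResult(
            term=f"cluster_{cluster}_vs_{reference}", beta=beta, se=se, z=z,
            wald_p=max(p, np.finfo(float).tiny), odds_ratio=float(np.exp(beta)),
            ci95_low=float(np.exp(beta - 1.96 * se)),
            ci95_high=float(np.exp(beta + 1.96 * se)),
            covariates=tuple(covs), prs_adjusted=False,
        ))
    return results
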