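"""Synthetic GWAS studies with pathway-concentrated polygenic signal.

The generator emulates the statistical structure the pipeline assumes,
at desk scale:

* **Genotypes** — LD blocks of biallelic SNPs.  Within a block a latent
  AR(1) Gaussian vector is drawn per haplotype and thresholded at the
  allele-frequency quantile; the dosage is the sum of the two haplotype
  alleles, giving controllable LD without coalescent machinery.
* **Phenotype** — an additive liability threshold model: causal effects
  are Gaussian, with the effect variance of SNPs inside the enriched
  pathways' genes inflated by a multiplier; liability is scaled to the
  target heritability and dichotomised at the prevalence quantile.
  Cases and controls are sampled from a population pool.
* **Summary statistics** — a per-SNP logistic GWAS (intercept + dosage,
  full Newton fit, vectorised across SNPs) on the emitted cohort.
* **Expression** — pathway genes' expression responds linearly to the
  pathway score with Gaussian noise and a small age effect.

Every draw flows from a single seed; fixtures are reproducible bitwise.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSet, GenotypeMatrix, flag_druggable, write_gene_annotation, \
    write_gene_sets_gmt, write_summary_stats, write_vcf

logger = logging.getLogger(__name__)

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
_SNP_SPACING = 4000  # bp between adjacent simulated SNPs


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults are the desk-scale conditions used throughout the test
    suite; :func:`preset` provides the named variants.
    """

    n_individuals: int = 500          # cohort size when not case-control sampled
    n_cases: int | None = None        # sample this many cases from a pool
    n_controls: int | None = None
    n_gwas: int | None = None         # separate discovery-GWAS cohort size
    n_snps: int = 1000
    n_genes: int = 100
    n_sets: int = 20
    genes_per_set: int = 10
    ld_block_size: int = 20
    ld_rho: float = 0.8
    maf_range: tuple = (0.05, 0.5)
    enriched_sets: tuple = (0,)       # indices of planted pathways
    enrichment_multiplier: float = 15.0
    causal_fraction: float = 0.2
    h2: float = 0.7                   # liability-scale heritability
    prevalence: float = 0.2           # desk-scale override of a rare-trait prevalence
    druggable_fraction: float = 0.5
    n_drugs: int = 60
    n_expression_samples: int = 75
    expression_effect: float = 0.5    # slope per SD of pathway score
    expression_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must lie in [0, 1)")
        if not 0 < self.h2 < 1:
            raise ValueError("h2 must lie in (0, 1)")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")


def preset(name, seed=0, **overrides) -> SimulationConfig:
    """Named study conditions.

    ``mini``: small and fast for unit tests.  ``paper-shaped``: a
    425-case / 251-control cohort with 50 druggable pathways of 10 genes,
    eight of them enriched.  ``null``: no pathway enrichment and no
    genetic effect at all.
    """
    base = {
        "mini": dict(n_individuals=300, n_snps=400, n_genes=40, n_sets=10,
                     genes_per_set=5, n_drugs=30),
        "paper-shaped": dict(n_cases=425, n_controls=251, n_gwas=4000, n_snps=2500,
                             n_genes=250, n_sets=50, genes_per_set=10,
                             enriched_sets=tuple(range(8))),
        "null": dict(n_individuals=500, n_gwas=800, n_snps=1000, n_genes=100,
                     n_sets=20, genes_per_set=10, enriched_sets=(), h2=1e-6,
                     causal_fraction=0.0, prevalence=0.5),
    }
    if name not in base:
        raise ValueError(f"unknown preset {name!r}")
    return SimulationConfig(**{**base[name], "seed": seed, **overrides})


@dataclass
class GroundTruth:
    """What the generator planted, serialised alongside every fixture."""

    causal_betas: dict                  # snp_id -> liability-scale beta
    enriched_sets: list
    expression_slopes: dict             # gene_id -> slope on its pathway score
    case_labels: dict                   # sample_id -> 0/1

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class StudyData:
    """A complete synthetic study, ready for the pipeline."""

    config: SimulationConfig
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    sumstats: pd.DataFrame
    annotation: pd.DataFrame
    gene_sets: list
    druggable_genes: list
    interactions: pd.DataFrame
    gene_map: dict = field(default_factory=dict)   # gene -> SNP ids (by construction)
    truth: GroundTruth | None = None


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _draw_variants(config: SimulationConfig, rng):
    """Variant metadata plus the latent thresholds encoding each MAF."""
    m = config.n_snps
    maf = rng.uniform(*config.maf_range, size=m)
    thresholds = stats.norm.isf(maf)
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(len(_ALLELE_PAIRS), size=m)]
    variants = pd.DataFrame({
        "snp_id": [f"rs{j:06d}" for j in range(m)],
        "chrom": "1",
        "pos": np.arange(1, m + 1) * _SNP_SPACING,
        "counted_allele": [p[0] for p in pairs],
        "other_allele": [p[1] for p in pairs],
        "impute_score": np.round(rng.uniform(0.85, 1.0, size=m), 4),
    })
    return variants, thresholds


def _draw_dosages(n, thresholds, config: SimulationConfig, rng) -> np.ndarray:
    m, block, rho = config.n_snps, config.ld_block_size, config.ld_rho

    def haplotypes():
        h = np.empty((n, m))
        for start in range(0, m, block):
            b = min(block, m - start)
            eps = rng.standard_normal((n, b))
            x = np.empty((n, b))
            x[:, 0] = eps[:, 0]
            for t in range(1, b):
                x[:, t] = rho * x[:, t - 1] + np.sqrt(1 - rho ** 2) * eps[:, t]
            h[:, start:start + b] = x
        return h > thresholds

    return haplotypes().astype(float) + haplotypes().astype(float)


def simulate_genotypes(config: SimulationConfig, n=None, rng=None,
                       variants=None, thresholds=None) -> GenotypeMatrix:
    """LD-block genotypes: thresholded AR(1) Gaussian haplotype pairs.

    Pass ``variants``/``thresholds`` from :func:`_draw_variants` to draw
    several cohorts over the same variant panel.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_individuals if n is None else n
    if variants is None:
        variants, thresholds = _draw_variants(config, rng)
    dosages = _draw_dosages(n, thresholds, config, rng)
    samples = [f"ind{i:05d}" for i in range(n)]
    return GenotypeMatrix(samples=samples, variants=variants.copy(), dosages=dosages)


# ---------------------------------------------------------------------------
# annotation, gene sets, drugs
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimulationConfig, variants: pd.DataFrame) -> tuple:
    """Tile genes over consecutive SNP windows; returns (annotation, gene_map)."""
    per_gene = config.n_snps // config.n_genes
    rows, gene_map = [], {}
    for g in range(config.n_genes):
        lo, hi = g * per_gene, min((g + 1) * per_gene, config.n_snps) - 1
        sub = variants.iloc[lo:hi + 1]
        gene_id = f"G{g:04d}"
        rows.append((gene_id, "1", int(sub["pos"].iloc[0]), int(sub["pos"].iloc[-1]),
                     "+" if g % 2 == 0 else "-"))
        gene_map[gene_id] = list(sub["snp_id"])
    annot = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return annot, gene_map


def simulate_gene_sets(config: SimulationConfig, rng) -> tuple:
    """Random pathways plus a druggable-gene list; every set keeps >= 1
    druggable member so the full collection survives druggability
    filtering (mirroring a pathway collection pre-filtered for drug
    targets)."""
    genes = [f"G{g:04d}" for g in range(config.n_genes)]
    sets = []
    for s in range(config.n_sets):
        member = rng.choice(config.n_genes, size=min(config.genes_per_set, config.n_genes),
                            replace=False)
        name = f"SET{s:03d}"
        sets.append(GeneSet(name=name, description=f"synthetic pathway {s}",
                            genes={genes[i] for i in sorted(member)}))
    n_drug = max(1, int(config.druggable_fraction * config.n_genes))
    druggable = {genes[i] for i in rng.choice(config.n_genes, size=n_drug, replace=False)}
    for s in sets:
        if not (s.genes & druggable):
            druggable.add(min(s.genes))
    retained, _ = flag_druggable(sets, druggable)
    return retained, sorted(druggable)


def simulate_drug_interactions(config: SimulationConfig, rng, druggable,
                               gene_sets=()) -> pd.DataFrame:
    """Synthetic drug-gene interaction table (DGidb-like).

    Besides drugs with scattered random targets, each pathway gets one
    focused drug hitting several of its members — mirroring how real
    target databases concentrate a drug's targets within functional
    families, which is what pathway-level drug over-representation
    detects.
    """
    genes = list(druggable)
    rows = []
    atc_letters = list("ABCDGHJLMNPRSV")

    def atc():
        return atc_letters[int(rng.integers(len(atc_letters)))] + \
            f"{int(rng.integers(100)):02d}"

    for d in range(config.n_drugs):
        k = int(rng.integers(2, max(3, len(genes) // 4)))
        targets = rng.choice(len(genes), size=min(k, len(genes)), replace=False)
        approved = bool(rng.random() < 0.7)
        code = atc()
        for t in targets:
            rows.append((f"drug{d:03d}", genes[t], float(np.round(rng.uniform(0.1, 10), 3)),
                         approved, code))
    for s in gene_sets:
        members = sorted(s.genes)
        k = min(len(members), int(rng.integers(4, 7)))
        targets = [members[i] for i in rng.choice(len(members), size=k, replace=False)]
        code = atc()
        for g in targets:
            rows.append((f"drug_{s.name}", g, float(np.round(rng.uniform(1, 10), 3)),
                         True, code))
    df = pd.DataFrame(rows, columns=["drug_name", "gene_id", "interaction_score",
                                     "approved", "atc_code"])
    return df.drop_duplicates(["drug_name", "gene_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# phenotype + GWAS
# ---------------------------------------------------------------------------

def logistic_gwas(dosages, y, max_iter=30, tol=1e-8):
    """Per-SNP logistic regression (intercept + dosage), Newton iterations
    vectorised across SNPs.  Returns (beta, se, pvalue) arrays; monomorphic
    SNPs get beta 0, se inf, P 1."""
    x = np.asarray(dosages, dtype=float)
    y = np.asarray(y, dtype=float)[:, None]
    n, m = x.shape
    poly = np.ptp(x, axis=0) > 0
    a = np.full(m, np.log(y.mean() / (1 - y.mean())))
    b = np.zeros(m)
    for _ in range(max_iter):
        eta = a[None, :] + x * b[None, :]
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        r = y - p
        g0, g1 = r.sum(axis=0), (r * x).sum(axis=0)
        h00, h01, h11 = w.sum(axis=0), (w * x).sum(axis=0), (w * x * x).sum(axis=0)
        det = h00 * h11 - h01 ** 2
        det = np.where(det <= 0, np.inf, det)
        da = (h11 * g0 - h01 * g1) / det
        db = (h00 * g1 - h01 * g0) / det
        step = np.clip(np.column_stack([da, db]), -5, 5)
        a += np.where(poly, step[:, 0], 0.0)
        b += np.where(poly, step[:, 1], 0.0)
        if not poly.any() or np.max(np.abs(step[poly])) < tol:
            break
    eta = a[None, :] + x * b[None, :]
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1 - p)
    h00, h01, h11 = w.sum(axis=0), (w * x).sum(axis=0), (w * x * x).sum(axis=0)
    det = h00 * h11 - h01 ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.where(det > 0, h00 / det, np.inf))
    se = np.where(poly, se, np.inf)
    beta = np.where(poly, b, 0.0)
    z = np.where(np.isfinite(se), beta / se, 0.0)
    pval = np.clip(2 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    return beta, se, pval


def _draw_effects(config, rng, variants, enriched_snps):
    """Causal mask and raw liability effects, enriched-pathway variance inflated."""
    m = len(variants)
    causal = rng.random(m) < config.causal_fraction
    beta = np.zeros(m)
    beta[causal] = rng.standard_normal(int(causal.sum()))
    enriched = variants["snp_id"].isin(set(enriched_snps)).to_numpy()
    beta[causal & enriched] *= np.sqrt(config.enrichment_multiplier)
    return beta, causal


def _scale_effects(dosages, beta, h2):
    """Scale effects so the genetic liability variance equals h2 (empirically)."""
    g = (dosages - dosages.mean(axis=0)) @ beta
    sd = g.std()
    return beta * np.sqrt(h2) / sd if sd > 0 else beta


def _case_labels(dosages, beta_scaled, config, rng):
    g = (dosages - dosages.mean(axis=0)) @ beta_scaled
    liability = g + rng.standard_normal(dosages.shape[0]) * np.sqrt(1 - config.h2)
    return (liability > stats.norm.isf(config.prevalence)).astype(int)


def _liability(gm, config, rng, enriched_snps):
    beta, causal = _draw_effects(config, rng, gm.variants, enriched_snps)
    beta_scaled = _scale_effects(gm.dosages, beta, config.h2)
    case = _case_labels(gm.dosages, beta_scaled, config, rng)
    return case, beta_scaled, causal


def _gwas_sumstats(gm: GenotypeMatrix, y) -> pd.DataFrame:
    beta_hat, se, pval = logistic_gwas(gm.dosages, y)
    return pd.DataFrame({
        "snp_id": gm.variants["snp_id"],
        "chrom": gm.variants["chrom"],
        "pos": gm.variants["pos"],
        "effect_allele": gm.variants["counted_allele"],
        "other_allele": gm.variants["other_allele"],
        "beta": beta_hat,
        "pvalue": pval,
    })


def _phenotype_table(cohort: GenotypeMatrix, y, rng) -> pd.DataFrame:
    from sklearn.decomposition import PCA

    pcs = PCA(n_components=3, svd_solver="randomized",
              random_state=int(rng.integers(2 ** 31 - 1))).fit_transform(
        cohort.dosages - cohort.dosages.mean(axis=0))
    return pd.DataFrame({
        "sample_id": cohort.samples,
        "case_status": y,
        "sex": rng.integers(0, 2, size=cohort.n_samples),
        "age": np.round(rng.normal(42.2, 10.5, size=cohort.n_samples), 1),
        "PC1": pcs[:, 0], "PC2": pcs[:, 1], "PC3": pcs[:, 2],
    }).set_index("sample_id")


def simulate_phenotype_and_gwas(gm: GenotypeMatrix, config: SimulationConfig, rng,
                                enriched_snps=()):
    """Liability-threshold phenotype plus per-SNP logistic GWAS.

    When ``config.n_cases`` is set, cases and controls are sampled from
    ``gm`` (treated as the population pool) and the returned genotype
    matrix is the sampled cohort; otherwise the whole of ``gm`` is the
    cohort.  Returns ``(cohort_gm, phenotypes, sumstats, truth_parts)``.
    """
    case, beta_true, causal = _liability(gm, config, rng, set(enriched_snps))
    if config.n_cases is not None:
        case_idx = np.nonzero(case == 1)[0]
        ctrl_idx = np.nonzero(case == 0)[0]
        if len(case_idx) < config.n_cases or len(ctrl_idx) < (config.n_controls or 0):
            raise ValueError(
                f"pool yielded {len(case_idx)} cases / {len(ctrl_idx)} controls; "
                f"increase the pool or the prevalence"
            )
        pick = np.concatenate([
            rng.choice(case_idx, size=config.n_cases, replace=False),
            rng.choice(ctrl_idx, size=config.n_controls, replace=False),
        ])
        pick.sort()
        cohort = gm.subset_samples(pick)
        y = case[pick]
    else:
        cohort, y = gm, case
    if y.sum() < 10:
        raise ValueError("fewer than 10 cases simulated; increase n or prevalence")

    sumstats = _gwas_sumstats(cohort, y)
    pheno = _phenotype_table(cohort, y, rng)

    causal_betas = {
        sid: float(b) for sid, b, c in zip(gm.variants["snp_id"], beta_true, causal) if c
    }
    return cohort, pheno, sumstats, (causal_betas, {s: int(v) for s, v in
                                                    zip(cohort.samples, y)})


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(scores: pd.DataFrame, pathway_genes: dict,
                        config: SimulationConfig, rng, age=None):
    """Expression of pathway genes responding to their pathway's score.

    ``scores`` columns must be named ``PES_<set_name>``; for each pathway
    in ``pathway_genes`` half of its genes (at least one) get a slope of
    ``config.expression_effect`` per score SD, the rest zero.  Returns
    ``(expression genes x samples, slopes dict)``.
    """
    samples = list(scores.index)
    n = len(samples)
    age = np.zeros(n) if age is None else np.asarray(age, dtype=float)
    rows, slopes = {}, {}
    for set_name, genes in pathway_genes.items():
        col = f"PES_{set_name}"
        if col not in scores.columns:
            continue
        s = scores[col].to_numpy(dtype=float)
        sd = s.std()
        s = (s - s.mean()) / (sd if sd > 0 else 1.0)
        genes = sorted(genes)
        n_hit = max(1, len(genes) // 2)
        for i, gene in enumerate(genes):
            if gene in rows:   # gene already emitted for another pathway
                continue
            gamma = config.expression_effect if i < n_hit else 0.0
            slopes[gene] = gamma
            rows[gene] = (rng.normal(8.0, 0.5) + gamma * s + 0.01 * age
                          + rng.standard_normal(n) * config.expression_noise_sd)
    expr = pd.DataFrame(rows, index=samples).T
    expr.index.name = "gene_id"
    return expr, slopes


# ---------------------------------------------------------------------------
# whole studies and fixture suites
# ---------------------------------------------------------------------------

def _pool_size(config: SimulationConfig) -> int:
    if config.n_cases is None:
        return config.n_individuals
    need_cases = config.n_cases / config.prevalence
    need_ctrls = (config.n_controls or 0) / (1 - config.prevalence)
    return int(max(need_cases, need_ctrls) * 1.35) + 50


def simulate_study(config: SimulationConfig) -> StudyData:
    """Generate a complete study under one seed.

    With ``config.n_gwas`` set, summary statistics come from a separate
    discovery cohort of that size (the two-cohort mode, mirroring a
    large external GWAS scored in a smaller target cohort, and avoiding
    winner's-curse coupling); otherwise the GWAS runs on the emitted
    cohort itself.
    """
    rng = np.random.default_rng(config.seed)
    variants, thresholds = _draw_variants(config, rng)
    annot, gene_map = simulate_annotation(config, variants)
    sets, druggable = simulate_gene_sets(config, rng)
    interactions = simulate_drug_interactions(config, rng, druggable, gene_sets=sets)
    enriched_names = [sets[i].name for i in config.enriched_sets if i < len(sets)]
    enriched_snps = {s for name in enriched_names
                     for g in next(x.genes for x in sets if x.name == name)
                     for s in gene_map[g]}

    if config.n_gwas is None:
        pool = simulate_genotypes(config, n=_pool_size(config), rng=rng,
                                  variants=variants, thresholds=thresholds)
        cohort, pheno, sumstats, (causal_betas, labels) = simulate_phenotype_and_gwas(
            pool, config, rng, enriched_snps)
    else:
        beta_raw, causal = _draw_effects(config, rng, variants, enriched_snps)
        disc = _draw_dosages(config.n_gwas, thresholds, config, rng)
        beta_scaled = _scale_effects(disc, beta_raw, config.h2)
        y_disc = _case_labels(disc, beta_scaled, config, rng)
        if y_disc.sum() < 10:
            raise ValueError("fewer than 10 cases in the discovery cohort")
        gwas_gm = GenotypeMatrix(
            samples=[f"disc{i:05d}" for i in range(config.n_gwas)],
            variants=variants.copy(), dosages=disc)
        sumstats = _gwas_sumstats(gwas_gm, y_disc)

        pool = simulate_genotypes(config, n=_pool_size(config), rng=rng,
                                  variants=variants, thresholds=thresholds)
        y_pool = _case_labels(pool.dosages, beta_scaled, config, rng)
        if config.n_cases is not None:
            case_idx = np.nonzero(y_pool == 1)[0]
            ctrl_idx = np.nonzero(y_pool == 0)[0]
            if len(case_idx) < config.n_cases or len(ctrl_idx) < (config.n_controls or 0):
                raise ValueError("target pool too small for the requested cohort")
            pick = np.concatenate([
                rng.choice(case_idx, size=config.n_cases, replace=False),
                rng.choice(ctrl_idx, size=config.n_controls, replace=False),
            ])
            pick.sort()
            cohort, y = pool.subset_samples(pick), y_pool[pick]
        else:
            cohort, y = pool, y_pool
        pheno = _phenotype_table(cohort, y, rng)
        causal_betas = {sid: float(b) for sid, b, c in
                        zip(variants["snp_id"], beta_scaled, causal) if c}
        labels = {s: int(v) for s, v in zip(cohort.samples, y)}

    truth = GroundTruth(causal_betas=causal_betas, enriched_sets=enriched_names,
                        expression_slopes={}, case_labels=labels)
    return StudyData(config=config, genotypes=cohort, phenotypes=pheno,
                     sumstats=sumstats, annotation=annot, gene_sets=sets,
                     druggable_genes=druggable, interactions=interactions,
                     gene_map=gene_map, truth=truth)


def write_fixture_suite(config: SimulationConfig, outdir, force=False) -> dict:
    """Emit every pipeline input as plain-text files under ``outdir``.

    Writes summary stats, gene annotation, GMT, druggable list, drug
    interactions, genotypes (VCF and PLINK), phenotypes, an expression
    matrix driven by oracle pathway scores (true causal effects summed
    over each enriched pathway's SNPs), and the ground-truth JSON.
    Returns the path map.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} is not empty (pass force=True)")
    outdir.mkdir(parents=True, exist_ok=True)
    study = simulate_study(config)
    rng = np.random.default_rng(config.seed + 1)

    paths = {
        "sumstats": outdir / "sumstats.tsv",
        "annotation": outdir / "genes.tsv",
        "gmt": outdir / "pathways.gmt",
        "druggable": outdir / "druggable_genes.txt",
        "interactions": outdir / "drug_interactions.tsv",
        "vcf": outdir / "genotypes.vcf",
        "plink": outdir / "genotypes",
        "phenotypes": outdir / "phenotypes.tsv",
        "expression": outdir / "expression.tsv",
        "truth": outdir / "ground_truth.json",
    }
    write_summary_stats(study.sumstats, paths["sumstats"])
    write_gene_annotation(study.annotation, paths["annotation"])
    write_gene_sets_gmt(study.gene_sets, paths["gmt"])
    Path(paths["druggable"]).write_text("\n".join(study.druggable_genes) + "\n")
    study.interactions.to_csv(paths["interactions"], sep="\t", index=False)
    write_vcf(study.genotypes, paths["vcf"])
    from .plink import write_plink

    write_plink(study.genotypes, paths["plink"])
    study.phenotypes.reset_index().to_csv(paths["phenotypes"], sep="\t", index=False)

    # oracle pathway scores: true causal effects summed over pathway SNPs
    enriched = {name: next(s.genes for s in study.gene_sets if s.name == name)
                for name in study.truth.enriched_sets}
    if enriched:
        snp_index = study.genotypes.variants.set_index("snp_id")
        oracle = {}
        for name, genes in enriched.items():
            snps = [s for g in sorted(genes) for s in study.gene_map[g]
                    if s in study.truth.causal_betas]
            if not snps:
                continue
            cols = snp_index.index.get_indexer(snps)
            betas = np.array([study.truth.causal_betas[s] for s in snps])
            oracle[f"PES_{name}"] = study.genotypes.dosages[:, cols] @ betas
        scores = pd.DataFrame(oracle, index=[str(s) for s in study.genotypes.samples])
        cases = study.phenotypes.loc[study.phenotypes["case_status"] == 1]
        n_expr = min(config.n_expression_samples, len(cases))
        sub = list(cases.index[:n_expr])
        expr, slopes = simulate_expression(
            scores.loc[sub], enriched, config, rng,
            age=study.phenotypes.loc[sub, "age"].to_numpy())
        expr.to_csv(paths["expression"], sep="\t")
        study.truth.expression_slopes = slopes
    study.truth.to_json(paths["truth"])
    return paths
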