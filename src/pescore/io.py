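"""Readers, writers, allele harmonisation and variant QC.

Conventions
-----------
* Coordinates are 1-based inclusive everywhere (summary-stat / bim style);
  half-open inputs must be converted at the boundary by the caller.
* Summary statistics are held in a :class:`pandas.DataFrame` with the
  canonical columns :data:`SUMSTAT_COLUMNS`; effect sizes are always betas
  (odds ratios are log-transformed at read time).
* Genotypes are held in :class:`GenotypeMatrix`: individuals x variants
  dosages in [0, 2] with NaN for missing calls, plus per-variant metadata
  including the counted (dosage) allele.  For VCF the counted allele is
  ALT; for PLINK it is the bim column-5 allele (A1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical summary-statistic columns, in order
SUMSTAT_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "pvalue",
]

#: strand-ambiguous allele pairs
PALINDROMIC_PAIRS = {frozenset({"A", "T"}), frozenset({"C", "G"})}


class ConfigurationError(ValueError):
    """A mandatory column or option is missing or inconsistent."""


class InputError(ValueError):
    """An input file is readable but contains no usable data."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    """A named pathway: a set of gene ids, optionally flagged druggable."""

    name: str
    description: str
    genes: set
    druggable_genes: set = field(default_factory=set)

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if not self.druggable_genes <= self.genes:
            raise ValueError(f"druggable genes of {self.name!r} not a subset")


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix with variant metadata.

    ``dosages`` is float with NaN for missing calls; ``variants`` carries
    ``snp_id, chrom, pos, counted_allele, other_allele`` and optionally
    ``impute_score``.
    """

    samples: list
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        self.variants = self.variants.reset_index(drop=True)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0) < 0 or np.nanmax(self.dosages, initial=0) > 2:
                raise ValueError("dosages outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def missingness(self) -> np.ndarray:
        """Per-variant fraction of missing calls."""
        return np.isnan(self.dosages).mean(axis=0)

    def mean_imputed(self) -> np.ndarray:
        """Dosages with missing calls replaced by the per-variant mean.

        All-missing variants impute to 0 (monomorphic placeholder).
        """
        d = self.dosages.copy()
        mask = np.isnan(d)
        if mask.any():
            with np.errstate(invalid="ignore"):
                col_mean = np.nanmean(np.where(mask, np.nan, d), axis=0)
            col_mean = np.nan_to_num(col_mean)
            d[mask] = np.take(col_mean, np.nonzero(mask)[1])
        return d

    def subset_variants(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[index],
            dosages=self.dosages[:, index],
        )

    def subset_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in index],
            variants=self.variants,
            dosages=self.dosages[index, :],
        )


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def read_summary_stats(path, column_map=None, sep=None) -> pd.DataFrame:
    """Read GWAS summary statistics from delimited text.

    Parameters
    ----------
    path : str
        Whitespace- or tab-delimited file with a header row.
    column_map : dict, optional
        Maps canonical names (``snp_id, chrom, pos, effect_allele,
        other_allele, beta | or, pvalue``) to the file's column names.
        Identity map by default.  If an ``or`` entry is given, the column
        is read as an odds ratio and converted to ``beta = ln(OR)``.
    sep : str, optional
        Field separator; any whitespace by default.

    Returns
    -------
    pandas.DataFrame with :data:`SUMSTAT_COLUMNS`.  Rows with P outside
    (0, 1] or missing alleles are dropped (count logged).
    """
    df = pd.read_csv(path, sep=sep if sep is not None else r"\s+", dtype={"chrom": str})
    column_map = dict(column_map or {})
    effect_key = "or" if "or" in column_map else "beta"
    wanted = ["snp_id", "chrom", "pos", "effect_allele", "other_allele", effect_key, "pvalue"]
    rename = {}
    for key in wanted:
        src = column_map.get(key, key)
        if src not in df.columns:
            raise ConfigurationError(f"summary-statistic column {src!r} (for {key!r}) not found")
        rename[src] = key
    df = df[list(rename)].rename(columns=rename)
    if effect_key == "or":
        with np.errstate(divide="ignore", invalid="ignore"):
            df["beta"] = np.log(pd.to_numeric(df.pop("or"), errors="coerce"))
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    df["beta"] = pd.to_numeric(df["beta"], errors="coerce")
    df["pvalue"] = pd.to_numeric(df["pvalue"], errors="coerce")
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    n0 = len(df)
    ok = (
        df["pvalue"].gt(0) & df["pvalue"].le(1)
        & df["beta"].notna() & df["pos"].notna()
        & df["effect_allele"].ne("NAN") & df["other_allele"].ne("NAN")
        & df["effect_allele"].ne(df["other_allele"])
    )
    dropped = int(n0 - ok.sum())
    if dropped:
        logger.warning("read_summary_stats: dropped %d/%d invalid rows", dropped, n0)
    df = df.loc[ok].reset_index(drop=True)
    if df.empty:
        raise InputError(f"no valid summary-statistic rows in {path}")
    df["pos"] = df["pos"].astype(int)
    df.attrs["n_dropped"] = dropped
    return df[SUMSTAT_COLUMNS]


def write_summary_stats(sumstats: pd.DataFrame, path) -> None:
    sumstats[SUMSTAT_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets / annotation / druggability
# ---------------------------------------------------------------------------

def read_gene_sets_gmt(path) -> list:
    """Parse a GMT file: each line is ``name<TAB>description<TAB>gene...``."""
    sets, seen = [], set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}:{lineno}: GMT line has {len(fields)} fields (need >= 3)")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if name in seen:
                raise InputError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            seen.add(name)
            sets.append(GeneSet(name=name, description=desc, genes=set(genes)))
    return sets


def write_gene_sets_gmt(sets, path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.genes)]) + "\n")


def flag_druggable(sets, druggable_gene_list):
    """Split gene sets into those with and without a druggable member.

    Returns ``(retained, discarded)``; every retained set has its
    ``druggable_genes`` populated with the intersection.
    """
    druggable = set(druggable_gene_list)
    if not druggable:
        raise ValueError("druggable gene list is empty")
    retained, discarded = [], []
    for s in sets:
        hits = s.genes & druggable
        if hits:
            retained.append(replace(s, druggable_genes=hits))
        else:
            discarded.append(s)
    return retained, discarded


def read_gene_annotation(path) -> pd.DataFrame:
    """Read BED-like gene coordinates (1-based inclusive) from TSV.

    Columns: ``gene_id, chrom, start, end, strand``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("gene_id", "chrom", "start", "end", "strand"):
        if col not in df.columns:
            raise ConfigurationError(f"annotation column {col!r} missing")
    if df["gene_id"].duplicated().any():
        raise InputError("duplicate gene_id in annotation")
    if (df["start"] > df["end"]).any():
        raise InputError("annotation with start > end")
    df["strand"] = df["strand"].where(df["strand"].isin(["+", "-"]), "+")
    return df.reset_index(drop=True)


def write_gene_annotation(annot: pd.DataFrame, path) -> None:
    annot[["gene_id", "chrom", "start", "end", "strand"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phenotypes / drug interactions / expression
# ---------------------------------------------------------------------------

def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype/covariate TSV indexed by ``sample_id`` with binary ``case_status``."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns or "case_status" not in df.columns:
        raise ConfigurationError("phenotype table needs sample_id and case_status columns")
    if df["sample_id"].duplicated().any():
        raise InputError("duplicate sample ids in phenotype table")
    if not df["case_status"].isin([0, 1]).all():
        raise InputError("case_status must be 0/1")
    return df.set_index("sample_id")


def read_drug_interactions(path) -> pd.DataFrame:
    """Drug-gene interaction TSV: drug_name, gene_id, interaction_score, approved, atc_code."""
    df = pd.read_csv(path, sep="\t", dtype={"atc_code": str}, keep_default_na=False,
                     na_values=[""])
    for col in ("drug_name", "gene_id", "interaction_score", "approved"):
        if col not in df.columns:
            raise ConfigurationError(f"drug-interaction column {col!r} missing")
    if df.duplicated(["drug_name", "gene_id"]).any():
        raise InputError("duplicate (drug, gene) pairs in interaction table")
    df["approved"] = df["approved"].astype(bool)
    if "atc_code" not in df.columns:
        df["atc_code"] = ""
    df["atc_code"] = df["atc_code"].fillna("")
    return df.reset_index(drop=True)


def read_expression(path) -> pd.DataFrame:
    """Expression matrix TSV: rows = genes (index column ``gene_id``), columns = samples."""
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path, fmt="vcf") -> GenotypeMatrix:
    """Read genotype dosages from VCF (``fmt='vcf'``) or PLINK (``fmt='plink'``).

    VCF: the FORMAT DS field is used when present, otherwise dosage is the
    ALT-allele count from GT; the counted allele is ALT.  ``R2`` in INFO is
    carried through as ``impute_score``.  PLINK: ``path`` is the prefix of a
    bed/bim/fam triple; the counted allele is bim A1.
    """
    if fmt == "plink":
        from . import plink

        return plink.read_plink(path)
    if fmt != "vcf":
        raise ConfigurationError(f"unknown genotype format {fmt!r}")

    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, cols = [], []
    for var in vcf:
        if var.ALT:
            alt = var.ALT[0]
        else:
            alt = "."
        if var.FORMAT and "DS" in var.FORMAT:
            ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)[: len(samples)]
            ds = np.where((ds < 0) | (ds > 2), np.nan, ds)
        else:
            gt = np.asarray(var.genotype.array())  # (n, ploidy+1)
            alleles = gt[:, :2].astype(float)
            alleles[alleles < 0] = np.nan
            ds = np.clip(alleles, 0, 1).sum(axis=1)
        r2 = var.INFO.get("R2")
        rows.append(
            (var.ID or f"{var.CHROM}:{var.POS}", str(var.CHROM), int(var.POS),
             alt, var.REF, float(r2) if r2 is not None else np.nan)
        )
        cols.append(ds)
    if not cols:
        raise InputError(f"no variants in {path}")
    variants = pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos", "counted_allele", "other_allele", "impute_score"]
    )
    dosages = np.column_stack(cols).astype(float)
    if dosages.shape[0] != len(samples):
        raise InputError(f"sample count mismatch across variants in {path}")
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with DS (and GT for integral dosages).

    REF is the other allele, ALT the counted allele, matching how
    :func:`read_genotypes` interprets a VCF.
    """
    variants = gm.variants
    has_r2 = "impute_score" in variants.columns
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in variants["chrom"].astype(str).unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, gm.samples)) + "\n")
        for j, var in variants.iterrows():
            r2 = var.get("impute_score") if has_r2 else None
            info = f"R2={r2:.6g}" if r2 is not None and not (isinstance(r2, float) and math.isnan(r2)) else "."
            entries = []
            for d in gm.dosages[:, j]:
                if math.isnan(d):
                    entries.append("./.:.")
                    continue
                if float(d).is_integer():
                    k = int(d)
                    gt = ["0/0", "0/1", "1/1"][k]
                else:
                    gt = "./."
                entries.append(f"{gt}:{d:.6g}")
            fh.write(
                f"{var.chrom}\t{var.pos}\t{var.snp_id}\t{var.other_allele}\t"
                f"{var.counted_allele}\t.\t.\t{info}\tGT:DS\t" + "\t".join(entries) + "\n"
            )


def qc_filter_variants(gm: GenotypeMatrix, max_missing=0.02, min_impute=0.8) -> GenotypeMatrix:
    """Drop variants failing the missingness / imputation-quality filters.

    Retention is strict: missingness strictly below ``max_missing`` and
    imputation score strictly above ``min_impute``.  Variants without an
    imputation score are not filtered on it.
    """
    if not (0 <= max_missing <= 1 and 0 <= min_impute <= 1):
        raise ConfigurationError("QC thresholds must lie in [0, 1]")
    miss = gm.missingness()
    keep = miss < max_missing
    if "impute_score" in gm.variants.columns:
        score = gm.variants["impute_score"].to_numpy(dtype=float)
        keep &= np.isnan(score) | (score > min_impute)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("qc_filter_variants: removed %d/%d variants", n_removed, gm.n_variants)
    if not keep.any():
        logger.warning("qc_filter_variants: all variants removed")
    return gm.subset_variants(np.nonzero(keep)[0])


def harmonise_alleles(sumstats: pd.DataFrame, gm: GenotypeMatrix, join="position",
                      drop_palindromic=True) -> pd.DataFrame:
    """Align summary-statistic effect alleles with genotype counted alleles.

    Joins on ``(chrom, pos)`` (default) or ``snp_id``, then reconciles
    alleles: when the genotype's counted allele equals the effect allele
    the beta passes through; when it equals the other allele the beta is
    sign-flipped; pairs whose alleles do not match, strand-ambiguous
    palindromic pairs (A/T, C/G; default policy) and duplicated join keys
    with conflicting alleles are dropped, with counts logged.

    Returns a DataFrame with columns ``snp_id, chrom, pos, beta, pvalue,
    col`` where ``col`` indexes the matching dosage column of ``gm`` and
    ``beta`` is aligned to the counted allele.
    """
    if join not in ("position", "snp_id"):
        raise ConfigurationError(f"unknown join mode {join!r}")
    key = ["chrom", "pos"] if join == "position" else ["snp_id"]
    gvar = gm.variants.copy()
    gvar["col"] = np.arange(len(gvar))
    merged = sumstats.merge(
        gvar[key + ["counted_allele", "other_allele", "col"]].rename(
            columns={"other_allele": "g_other"}),
        on=key, how="inner", suffixes=("", "_g"),
    )
    n_unmatched = len(sumstats) - merged[key].drop_duplicates().shape[0]

    dup = merged.duplicated(key, keep=False)
    if dup.any():
        logger.info("harmonise_alleles: dropping %d rows on duplicated join keys", int(dup.sum()))
        merged = merged.loc[~dup]

    ea, oa = merged["effect_allele"], merged["other_allele"]
    ca, ga = merged["counted_allele"], merged["g_other"]
    same = (ca == ea) & (ga == oa)
    flipped = (ca == oa) & (ga == ea)
    palindromic = [frozenset((a, b)) in PALINDROMIC_PAIRS for a, b in zip(ea, oa)]
    palindromic = pd.Series(palindromic, index=merged.index)
    keep = (same | flipped)
    if drop_palindromic:
        keep &= ~palindromic
    n_mismatch = int((~(same | flipped)).sum())
    n_palin = int((palindromic & (same | flipped)).sum()) if drop_palindromic else 0
    if n_unmatched or n_mismatch or n_palin:
        logger.info(
            "harmonise_alleles: %d unmatched, %d allele-mismatch, %d palindromic dropped",
            n_unmatched, n_mismatch, n_palin,
        )
    merged = merged.loc[keep].copy()
    flip = (merged["counted_allele"] == merged["other_allele"])
    merged["beta"] = np.where(flip, -merged["beta"], merged["beta"])
    out = merged[["snp_id", "chrom", "pos", "beta", "pvalue", "col"]].reset_index(drop=True)
    return out
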