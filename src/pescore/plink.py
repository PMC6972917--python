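"""Minimal PLINK 1 bed/bim/fam reader and writer.

Only hard-called genotypes are representable: dosages must be 0, 1, 2 or
missing.  The bed file is SNP-major (magic ``6c 1b 01``), two bits per
sample: ``00`` homozygous A1, ``10`` heterozygous, ``11`` homozygous A2,
``01`` missing.  The bim column-5 allele (A1) is treated as the counted
allele, so the stored code maps to an A1 count of 2/1/0 respectively.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, InputError

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit code -> A1 dosage (NaN = missing)
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink(prefix) -> GenotypeMatrix:
    """Read a ``prefix.bed/.bim/.fam`` triple into a :class:`GenotypeMatrix`."""
    prefix = str(prefix)
    fam = pd.read_csv(
        f"{prefix}.fam", sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"], dtype={"iid": str},
    )
    bim = pd.read_csv(
        f"{prefix}.bim", sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"], dtype={"chrom": str},
    )
    n, m = len(fam), len(bim)
    with open(f"{prefix}.bed", "rb") as fh:
        header = fh.read(3)
        if header != _MAGIC:
            raise InputError(f"{prefix}.bed: bad magic (not SNP-major PLINK bed)")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    bytes_per_snp = (n + 3) // 4
    if raw.size != bytes_per_snp * m:
        raise InputError(
            f"{prefix}.bed: {raw.size} data bytes, expected {bytes_per_snp * m} "
            f"for {n} samples x {m} variants"
        )
    raw = raw.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, sample-fastest within byte (LSB first)
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (raw >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T  # (n, m)
    variants = pd.DataFrame({
        "snp_id": bim["snp_id"].astype(str),
        "chrom": bim["chrom"],
        "pos": bim["pos"].astype(int),
        "counted_allele": bim["a1"].astype(str),
        "other_allele": bim["a2"].astype(str),
    })
    return GenotypeMatrix(samples=list(fam["iid"]), variants=variants, dosages=dosages)


def write_plink(gm: GenotypeMatrix, prefix) -> None:
    """Write a :class:`GenotypeMatrix` of hard calls as ``prefix.bed/.bim/.fam``."""
    prefix = str(prefix)
    d = gm.dosages
    finite = d[~np.isnan(d)]
    if not np.isin(finite, [0.0, 1.0, 2.0]).all():
        raise ValueError("PLINK bed stores hard calls only (dosages 0/1/2 or missing)")

    pd.DataFrame({
        "fid": gm.samples, "iid": gm.samples,
        "father": 0, "mother": 0, "sex": 0, "pheno": -9,
    }).to_csv(f"{prefix}.fam", sep="\t", header=False, index=False)

    bim = gm.variants
    pd.DataFrame({
        "chrom": bim["chrom"], "snp_id": bim["snp_id"], "cm": 0, "pos": bim["pos"],
        "a1": bim["counted_allele"], "a2": bim["other_allele"],
    }).to_csv(f"{prefix}.bim", sep="\t", header=False, index=False)

    n, m = gm.n_samples, gm.n_variants
    # dosage -> 2-bit code: 2 -> 00, 1 -> 10, 0 -> 11, missing -> 01
    code = np.where(np.isnan(d), 1, np.select([d == 2, d == 1, d == 0], [0, 2, 3])).astype(np.uint8)
    bytes_per_snp = (n + 3) // 4
    padded = np.ones((m, bytes_per_snp * 4), dtype=np.uint8) * 0  # pad with code 00
    padded[:, :n] = code.T
    packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << (2 * k)
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.tobytes())
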