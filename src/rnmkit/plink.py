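"""Readers and writers for the standard genotype/GRM file formats.

PLINK 1 binary (bed/bim/fam, SNP-major) and the GCTA-style GRM triplet
(grm.bin float32 lower triangle, grm.N.bin, grm.id), plus simple TSV helpers
for phenotype/covariate/status tables keyed by IID.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .qc import GRM, GenotypeMatrix

__all__ = [
    "read_plink",
    "write_plink",
    "read_grm",
    "write_grm",
    "read_value_tsv",
    "write_value_tsv",
]

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# 2-bit PLINK codes (counting the A1 allele): 00 -> 2, 10 -> 1, 11 -> 0,
# 01 -> missing
_CODE_TO_DOSAGE = {0b00: 2.0, 0b01: np.nan, 0b10: 1.0, 0b11: 0.0}
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


def write_plink(prefix: str, g: GenotypeMatrix) -> None:
    """Write bed/bim/fam.  Chromosome/positions in the bim are placeholders
    (1 / index) since the toolkit never uses genomic coordinates."""
    n, m = g.dosages.shape
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        for j in range(m):
            col = g.dosages[:, j]
            byte = 0
            shift = 0
            out = bytearray()
            for i in range(n):
                v = col[i]
                code = 0b01 if np.isnan(v) else _DOSAGE_TO_CODE[float(v)]
                byte |= code << shift
                shift += 2
                if shift == 8:
                    out.append(byte)
                    byte, shift = 0, 0
            if shift:
                out.append(byte)
            fh.write(bytes(out))
    with open(prefix + ".bim", "w") as fh:
        for j, sid in enumerate(g.snp_ids):
            fh.write(f"1\t{sid}\t0\t{j + 1}\tA\tG\n")
    with open(prefix + ".fam", "w") as fh:
        for iid in g.sample_ids:
            fh.write(f"{iid}\t{iid}\t0\t0\t0\t-9\n")


def read_plink(prefix: str) -> GenotypeMatrix:
    """Read a bed/bim/fam triplet into a GenotypeMatrix.

    Validates the bed magic bytes, the SNP-major mode byte and the file size
    (3 + ceil(n/4) * m bytes); duplicate IIDs in the fam are rejected.
    """
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None,
                      names=["FID", "IID", "PID", "MID", "sex", "pheno"],
                      dtype={"IID": str})
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos", "a1", "a2"],
                      dtype={"snp": str})
    sample_ids = list(fam["IID"])
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate IID in fam file")
    snp_ids = list(bim["snp"])
    n, m = len(sample_ids), len(snp_ids)

    with open(prefix + ".bed", "rb") as fh:
        header = fh.read(3)
        if header[:2] != _BED_MAGIC:
            raise ValueError("not a PLINK bed file (magic bytes mismatch)")
        if header[2] != _SNP_MAJOR:
            raise ValueError("only SNP-major bed files are supported")
        data = fh.read()
    bytes_per_snp = (n + 3) // 4
    if len(data) != bytes_per_snp * m:
        raise ValueError(
            f"truncated bed file: expected {3 + bytes_per_snp * m} bytes, "
            f"got {3 + len(data)}"
        )
    raw = np.frombuffer(data, dtype=np.uint8).reshape(m, bytes_per_snp)
    # unpack 2-bit codes: sample i of a SNP sits in byte i//4, bits (i%4)*2
    codes = np.zeros((m, n), dtype=np.uint8)
    for k in range(4):
        cols = np.arange(k, n, 4)
        codes[:, cols] = (raw[:, cols // 4] >> (2 * k)) & 0b11
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    dosages = lut[codes].T.copy()
    return GenotypeMatrix(dosages=dosages, sample_ids=sample_ids, snp_ids=snp_ids)


def write_grm(prefix: str, grm: GRM) -> None:
    """GCTA binary triplet: float32 lower triangle (row by row, diagonal
    included), per-pair SNP counts, and a two-column id file."""
    n = grm.n
    iu = [(i, j) for i in range(n) for j in range(i + 1)]
    vals = np.array([grm.values[i, j] for i, j in iu], dtype="<f4")
    vals.tofile(prefix + ".grm.bin")
    np.full(len(iu), grm.n_snps_used, dtype="<f4").tofile(prefix + ".grm.N.bin")
    with open(prefix + ".grm.id", "w") as fh:
        for iid in grm.sample_ids:
            fh.write(f"{iid}\t{iid}\n")


def read_grm(prefix: str) -> GRM:
    ids = pd.read_csv(prefix + ".grm.id", sep="\t", header=None,
                      names=["FID", "IID"], dtype=str)
    sample_ids = list(ids["IID"])
    n = len(sample_ids)
    n_pairs = n * (n + 1) // 2
    vals = np.fromfile(prefix + ".grm.bin", dtype="<f4")
    if vals.size != n_pairs:
        raise ValueError("grm.bin size does not match grm.id")
    counts = np.fromfile(prefix + ".grm.N.bin", dtype="<f4")
    K = np.zeros((n, n))
    pos = 0
    for i in range(n):
        K[i, : i + 1] = vals[pos: pos + i + 1]
        pos += i + 1
    K = K + K.T - np.diag(np.diag(K))
    n_snps = int(round(float(counts[0]))) if counts.size else 0
    return GRM(values=K, sample_ids=sample_ids, n_snps_used=n_snps)


def write_value_tsv(path: str, sample_ids, values, column: str = "value") -> None:
    pd.DataFrame({"IID": sample_ids, column: values}).to_csv(
        path, sep="\t", index=False
    )


def read_value_tsv(path: str, column: str | None = None):
    """Read an `IID<tab>value` table; returns (sample_ids, values)."""
    df = pd.read_csv(path, sep="\t", dtype={"IID": str})
    if "IID" not in df.columns:
        raise ValueError(f"{path}: missing IID column")
    if column is None:
        column = [c for c in df.columns if c != "IID"][0]
    return list(df["IID"]), df[column].to_numpy()
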