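"""Minimal PLINK 1 binary genotype (BED/BIM/FAM) codec.

Implements the SNP-major 2-bit encoding: magic bytes 0x6c 0x1b, mode byte
0x01, then ceil(n/4) bytes per variant.  Two-bit codes (low bits first
within a byte): 00 = homozygous A1 (dosage 2 of the counted allele A1),
10 = heterozygous (1), 11 = homozygous A2 (0), 01 = missing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import io as _io
from .pgs import GenotypeMatrix

__all__ = ["read_plink", "write_plink"]

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# code -> dosage of A1; 1 (=missing) maps to NaN
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSAGE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11}


def write_plink(genos: GenotypeMatrix, prefix: str | Path) -> None:
    """Write BED/BIM/FAM files at ``prefix``.bed/.bim/.fam.

    Dosages must be integral in {0, 1, 2} or NaN.
    """
    prefix = Path(prefix)
    _io.write_bim(genos.snps, prefix.with_suffix(".bim"))
    _io.write_fam(list(genos.individuals), prefix.with_suffix(".fam"))

    n = len(genos.individuals)
    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        for j in range(genos.dosages.shape[1]):
            col = genos.dosages[:, j]
            codes = np.empty(n, dtype=np.uint8)
            nan = np.isnan(col)
            codes[nan] = 0b01
            for dosage, code in _DOSAGE_TO_CODE.items():
                codes[~nan & (np.round(col) == dosage)] = code
            packed = np.zeros(n_bytes, dtype=np.uint8)
            for k in range(n):
                packed[k // 4] |= codes[k] << (2 * (k % 4))
            fh.write(packed.tobytes())


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read BED/BIM/FAM files at ``prefix`` into a GenotypeMatrix."""
    prefix = Path(prefix)
    snps = _io.read_bim(prefix.with_suffix(".bim"))
    fam = _io.read_fam(prefix.with_suffix(".fam"))
    individuals = fam["iid"].tolist()
    n = len(individuals)
    n_bytes = (n + 3) // 4

    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _MAGIC:
        raise ValueError("not a SNP-major PLINK 1 BED file")
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    m = len(snps)
    if len(body) != m * n_bytes:
        raise ValueError(
            f"BED payload has {len(body)} bytes, expected {m * n_bytes} "
            f"for {m} variants x {n} samples"
        )
    body = body.reshape(m, n_bytes)
    # unpack 2-bit codes, low bits first
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, n_bytes * 4)[:, :n]
    dosages = _CODE_TO_DOSAGE[codes].T.copy()
    return GenotypeMatrix(individuals=individuals, snps=snps, dosages=dosages)
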