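"""VanRaden Method I genomic relationship matrix.

G = Z Z' / (2 sum_i p_i (1 - p_i)), where Z is the dosage matrix with
column means 2 p_i subtracted and p_i the allele-b frequency of SNP i.
Missing dosages are mean-imputed (replaced by 2 p_i) before centering, so
they contribute nothing to Z.  Under Hardy-Weinberg equilibrium the
diagonal of G averages 1, which is what makes G comparable to a pedigree
numerator relationship matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_formats import MISSING, GenotypeMatrix

__all__ = ["GRM", "build_grm_method1", "write_grm_text"]


@dataclass
class GRM:
    samples: list[str]
    G: np.ndarray
    freqs_used: np.ndarray
    n_snps_used: int


def build_grm_method1(g: GenotypeMatrix, freqs: np.ndarray | None = None) -> GRM:
    """Build the Method I GRM from a genotype matrix.

    ``freqs`` optionally supplies external allele-b frequencies (one per
    SNP); by default they are computed from the non-missing calls of the
    cohort itself.
    """
    dos = g.dosage.astype(float)
    miss = g.dosage == MISSING
    if freqs is None:
        with np.errstate(invalid="ignore"):
            called = (~miss).sum(axis=0)
            if np.any(called == 0):
                raise ValueError("SNP with no called genotypes; filter first")
            p = np.where(miss, 0, dos).sum(axis=0) / (2.0 * called)
    else:
        p = np.asarray(freqs, dtype=float)
        if p.shape != (g.n_snps,):
            raise ValueError("freqs length must equal the number of SNPs")
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic: Method I denominator is zero")
    if miss.any():
        rr, cc = np.where(miss)
        dos[rr, cc] = 2.0 * p[cc]
    Z = dos - 2.0 * p
    G = (Z @ Z.T) / denom
    return GRM(samples=list(g.samples), G=G, freqs_used=p, n_snps_used=g.n_snps)


def write_grm_text(grm: GRM, path: str | Path) -> None:
    """Plain-text lower-triangle dump: i, j (1-based), n_snps, value."""
    with open(path, "w") as fh:
        for i in range(len(grm.samples)):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{grm.n_snps_used}\t{grm.G[i, j]:.10g}\n")
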