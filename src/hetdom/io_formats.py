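"""Genotype, pedigree and phenotype I/O plus cohort-level filters.

Genotypes travel as a :class:`GenotypeMatrix`: an animals x SNPs dosage
matrix coded 0/1/2 (copies of ``allele_b``) with ``-1`` marking missing
calls, paired with an ordered SNP map.  The on-disk format is the PLINK v1
binary triplet (``.bed``/``.bim``/``.fam``, SNP-major layout).

Allele mapping: ``allele_b`` is the .bim A1 allele, so dosage counts A1
copies (PLINK's two-bit code 00 = A1/A1 maps to dosage 2).  The mapping is
fixed and logged once per read so downstream effect signs are interpretable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("hetdom")

MISSING = -1

PLINK_MAGIC = bytes([0x6C, 0x1B])
SNP_MAJOR = bytes([0x01])

# two-bit PLINK code -> dosage of A1 (= allele_b): 00 hom A1, 01 missing,
# 10 het, 11 hom A2
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0, MISSING: 1, 1: 2, 0: 3}


class PlinkFormatError(ValueError):
    """Raised when a .bed payload does not match the v1 SNP-major layout."""


class PlinkDimensionError(ValueError):
    """Raised when .bed size disagrees with the .bim/.fam row counts."""


@dataclass(frozen=True)
class SNPInfo:
    """One SNP of the panel; positions are 1-based base pairs."""

    snp_id: str
    chrom: str
    pos_bp: int
    allele_a: str = "A"
    allele_b: str = "B"

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"pos_bp must be >= 1, got {self.pos_bp} for {self.snp_id}")


@dataclass
class GenotypeMatrix:
    """Animals x SNPs dosage matrix with its SNP map.

    ``dosage[i, j]`` counts copies of ``snps[j].allele_b`` carried by
    ``samples[i]``; ``-1`` is a missing call.  SNPs are kept sorted by
    (chrom, pos_bp).  ``haplotypes`` is an optional (n, 2, m) phased array
    used by the population simulator; it is dropped by I/O round trips.
    """

    samples: list[str]
    snps: list[SNPInfo]
    dosage: np.ndarray
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, m = self.dosage.shape
        if n != len(self.samples) or m != len(self.snps):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosage entries must be 0, 1, 2 or missing (-1)")
        order = sorted(range(m), key=lambda j: (self.snps[j].chrom, self.snps[j].pos_bp))
        if order != list(range(m)):
            self.snps = [self.snps[j] for j in order]
            self.dosage = self.dosage[:, order]
            if self.haplotypes is not None:
                self.haplotypes = self.haplotypes[:, :, order]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_frame(self) -> pd.DataFrame:
        """SNP map as a DataFrame (snp_id, chrom, pos_bp, alleles)."""
        return pd.DataFrame(
            {
                "snp_id": [s.snp_id for s in self.snps],
                "chrom": [s.chrom for s in self.snps],
                "pos_bp": [s.pos_bp for s in self.snps],
                "allele_a": [s.allele_a for s in self.snps],
                "allele_b": [s.allele_b for s in self.snps],
            }
        )

    def subset_snps(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=[self.snps[j] for j in idx],
            dosage=self.dosage[:, idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, :, idx],
        )

    def subset_samples(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            snps=list(self.snps),
            dosage=self.dosage[idx, :],
            haplotypes=None if self.haplotypes is None else self.haplotypes[idx],
        )


@dataclass
class PhenotypeRecord:
    """One slaughter record with the nuisance factors of the trait model."""

    animal_id: str
    trait_value: float
    dam_parity: str = "1"
    birth_herd: str = "beef"
    twin: str = "0"
    rec_loss_class: int = 0
    contemporary_group: str = "cg0"

    def __post_init__(self) -> None:
        if not np.isfinite(self.trait_value):
            raise ValueError(f"trait_value must be finite for {self.animal_id}")
        if self.birth_herd not in ("beef", "dairy"):
            raise ValueError(f"birth_herd must be beef or dairy, got {self.birth_herd!r}")
        if str(self.twin) not in ("0", "1"):
            raise ValueError(f"twin must be 0 or 1, got {self.twin!r}")
        if not 0 <= int(self.rec_loss_class) <= 6:
            raise ValueError(f"rec_loss_class must be 0..6, got {self.rec_loss_class}")


# ---------------------------------------------------------------------------
# PLINK binary triplet
# ---------------------------------------------------------------------------

def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK ``.bed/.bim/.fam`` triplet into a :class:`GenotypeMatrix`.

    Only the v1 SNP-major layout is supported.  Dosage counts the .bim A1
    allele (stored as ``allele_b``); missing calls become ``-1``.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos_bp", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype=str,
    )
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:2] != PLINK_MAGIC:
        raise PlinkFormatError(f"{prefix}.bed: bad magic number {raw[:2]!r}")
    if raw[2:3] != SNP_MAJOR:
        raise PlinkFormatError(f"{prefix}.bed: not SNP-major v1 layout")
    n, m = len(fam), len(bim)
    bytes_per_snp = (n + 3) // 4
    payload = np.frombuffer(raw[3:], dtype=np.uint8)
    if payload.size != m * bytes_per_snp:
        raise PlinkDimensionError(
            f"{prefix}.bed payload has {payload.size} bytes; expected "
            f"{m} SNPs x {bytes_per_snp} bytes for {n} samples"
        )
    blocks = payload.reshape(m, bytes_per_snp)
    # unpack the four 2-bit codes of each byte, sample-index order
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (blocks >> (2 * k)) & 0b11
    dosage = _CODE_TO_DOSAGE[codes[:, :n]].T  # -> samples x snps

    snps = [
        SNPInfo(r.snp_id, str(r.chrom), int(r.pos_bp), allele_a=r.a2, allele_b=r.a1)
        for r in bim.itertuples()
    ]
    logger.info(
        "read %d samples x %d SNPs from %s (dosage counts the .bim A1 allele)",
        n, m, prefix,
    )
    return GenotypeMatrix(samples=list(fam["iid"]), snps=snps, dosage=dosage)


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``g`` as a PLINK v1 SNP-major triplet (inverse of read_plink)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = g.n_samples, g.n_snps
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for s in g.snps:
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.pos_bp}\t{s.allele_b}\t{s.allele_a}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in g.samples:
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\n")
    bytes_per_snp = (n + 3) // 4
    code = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    code[:] = 1  # pad slots read back as missing but are sliced off anyway
    lut = np.zeros(4, dtype=np.uint8)
    for dos, c in _DOSAGE_TO_CODE.items():
        lut[dos % 4] = c  # -1 % 4 == 3 slot holds the missing code
    code[:, :n] = lut[g.dosage.T % 4]
    packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= code[:, k::4] << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(PLINK_MAGIC + SNP_MAJOR + packed.tobytes())


# ---------------------------------------------------------------------------
# Delimited tables
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> list[PhenotypeRecord]:
    """Read a tab-delimited phenotype table (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        PhenotypeRecord(
            animal_id=r["animal_id"],
            trait_value=float(r["trait_value"]),
            dam_parity=str(r.get("dam_parity", "1")),
            birth_herd=str(r.get("birth_herd", "beef")),
            twin=str(r.get("twin", "0")),
            rec_loss_class=int(r.get("rec_loss_class", 0)),
            contemporary_group=str(r.get("contemporary_group", "cg0")),
        )
        for _, r in df.iterrows()
    ]


def write_phenotypes(records: Iterable[PhenotypeRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "animal_id": r.animal_id,
                "trait_value": r.trait_value,
                "dam_parity": r.dam_parity,
                "birth_herd": r.birth_herd,
                "twin": r.twin,
                "rec_loss_class": r.rec_loss_class,
                "contemporary_group": r.contemporary_group,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path) -> pd.DataFrame:
    """Pedigree table: animal_id, sire_id, dam_id ('0' = unknown/founder) and
    optional breed composition columns prefixed ``breed_``."""
    return pd.read_csv(path, sep="\t", dtype={"animal_id": str, "sire_id": str, "dam_id": str})


# ---------------------------------------------------------------------------
# Cohort filters
# ---------------------------------------------------------------------------

def minor_allele_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """Per-SNP MAF from non-missing calls; NaN where every call is missing."""
    dos = np.ma.masked_equal(g.dosage, MISSING)
    p = dos.mean(axis=0).filled(np.nan) / 2.0
    return np.minimum(p, 1.0 - p)


def apply_maf_filter(g: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Drop SNPs with minor allele frequency <= ``threshold``.

    The rule is inclusive (MAF exactly at the threshold is removed), and
    frequencies come from non-missing calls only.  All-missing SNPs are
    excluded and logged.
    """
    if not 0 <= threshold < 0.5:
        raise ValueError(f"threshold must be in [0, 0.5), got {threshold}")
    maf = minor_allele_frequencies(g)
    all_missing = np.isnan(maf)
    if all_missing.any():
        for j in np.flatnonzero(all_missing):
            logger.warning("SNP %s has no called genotypes; excluded", g.snps[j].snp_id)
    keep = np.flatnonzero(~all_missing & (maf > threshold))
    return g.subset_snps(keep)


def filter_small_groups(
    records: Sequence[PhenotypeRecord], min_size: int = 5
) -> list[PhenotypeRecord]:
    """Drop records whose contemporary group has fewer than ``min_size`` members."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    counts: dict[str, int] = {}
    for r in records:
        counts[r.contemporary_group] = counts.get(r.contemporary_group, 0) + 1
    return [r for r in records if counts[r.contemporary_group] >= min_size]
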