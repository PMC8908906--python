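"""Genomic heterozygosity measures: OH, HL and runs of heterozygosity.

Three per-animal summaries of SNP-chip heterozygosity:

* **OH** — observed heterozygosity, the fraction of an animal's called
  genotypes that are heterozygous.
* **HL** — homozygosity by locus, sum(E_hom) / (sum(E_hom) + sum(E_het)),
  each called locus weighted by its population expected heterozygosity
  E = 1 - sum(allele freq^2); 0 means fully heterozygous, 1 fully
  homozygous.
* **ROHet** — runs of heterozygosity: maximal stretches of consecutive
  heterozygous genotypes found by a 50-SNP sliding window that tolerates a
  small number of homozygous and missing calls.

Missing genotypes never count as heterozygous or homozygous; they shrink
the OH denominator and are excluded from the HL sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .io_formats import MISSING, GenotypeMatrix

__all__ = [
    "LocusStats",
    "RohetParams",
    "RunOfHeterozygosity",
    "HetProfile",
    "locus_stats",
    "observed_heterozygosity",
    "homozygosity_by_locus",
    "detect_rohet",
    "detect_rohet_all",
    "het_profiles",
    "subset_measures",
    "rank_correlation",
    "classify_run_lengths",
]

# length classes for runs, in bp: short <= 150 kb < intermediate <= 300 kb < long
LENGTH_CLASS_EDGES = (150_000, 300_000)
LENGTH_CLASS_LABELS = ("le150kb", "151_300kb", "gt300kb")


@dataclass(frozen=True)
class LocusStats:
    """Per-SNP allele-b frequency and expected heterozygosity."""

    freq_b: np.ndarray
    expected_het: np.ndarray


@dataclass(frozen=True)
class RohetParams:
    """Sliding-window detector settings.

    ``min_density`` defaults to one SNP per 50 kb; the window statistic
    flags a SNP when the fraction of windows covering it that are
    "heterozygous" exceeds ``snp_in_run_threshold`` (set
    ``require_all_windows`` to demand every covering window pass instead).
    """

    window: int = 50
    max_missing_per_window: int = 2
    max_hom_per_window: int = 1
    min_length_bp: int = 1_000
    min_density: float = 1.0 / 50_000
    snp_in_run_threshold: float = 0.05
    max_gap_bp: int = 1_000_000
    require_all_windows: bool = False
    short_chrom_policy: str = "skip"  # or "shrink": single reduced-size window


@dataclass(frozen=True)
class RunOfHeterozygosity:
    animal_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class HetProfile:
    """Per-animal heterozygosity summary."""

    animal_id: str
    oh: float
    hl: float
    rohet_count: int = 0
    rohet_total_bp: int = 0
    rohet_by_class: dict[str, int] = field(
        default_factory=lambda: {k: 0 for k in LENGTH_CLASS_LABELS}
    )


def locus_stats(g: GenotypeMatrix) -> LocusStats:
    """Allele frequencies and expected heterozygosity from the cohort.

    E = 1 - p^2 - q^2 per biallelic locus, frequencies from non-missing
    calls.  A SNP with no called genotype is an error (it cannot carry a
    frequency).
    """
    dos = np.ma.masked_equal(g.dosage, MISSING)
    n_called = (~dos.mask).sum(axis=0) if dos.mask is not np.ma.nomask else np.full(g.n_snps, g.n_samples)
    if np.any(n_called == 0):
        j = int(np.argmin(n_called))
        raise ValueError(f"SNP {g.snps[j].snp_id} has no called genotypes")
    q = np.asarray(dos.mean(axis=0)) / 2.0
    e = 1.0 - q**2 - (1.0 - q) ** 2
    return LocusStats(freq_b=q, expected_het=e)


def observed_heterozygosity(g: GenotypeMatrix, animal: str) -> float:
    """Fraction of the animal's called SNPs that are heterozygous."""
    row = g.dosage[g.samples.index(animal)]
    called = row != MISSING
    if not called.any():
        raise ValueError(f"animal {animal} has no called genotypes")
    return float((row[called] == 1).sum() / called.sum())


def homozygosity_by_locus(g: GenotypeMatrix, stats: LocusStats, animal: str) -> float:
    """HL index: expected-het weight on homozygous loci over all called loci."""
    row = g.dosage[g.samples.index(animal)]
    called = row != MISSING
    if not called.any():
        raise ValueError(f"animal {animal} has no called genotypes")
    e = stats.expected_het
    e_hom = e[called & (row != 1)].sum()
    e_het = e[called & (row == 1)].sum()
    denom = e_hom + e_het
    if denom == 0:
        raise ValueError(f"animal {animal}: all called loci have zero expected heterozygosity")
    return float(e_hom / denom)


# ---------------------------------------------------------------------------
# ROHet sliding-window detector
# ---------------------------------------------------------------------------

def _runs_one_chrom(
    row: np.ndarray, pos: np.ndarray, params: RohetParams
) -> list[tuple[int, int, int, int]]:
    """Candidate runs on one chromosome: (start_bp, end_bp, n_snps, start_idx)."""
    m = row.size
    w = params.window
    if m < w:
        if params.short_chrom_policy == "skip":
            return []
        w = m
    is_missing = row == MISSING
    is_hom = (row == 0) | (row == 2)
    # rolling counts over windows [j, j+w)
    cmiss = np.concatenate([[0], np.cumsum(is_missing)])
    chom = np.concatenate([[0], np.cumsum(is_hom)])
    n_win = m - w + 1
    starts = np.arange(n_win)
    win_ok = (
        (cmiss[starts + w] - cmiss[starts] <= params.max_missing_per_window)
        & (chom[starts + w] - chom[starts] <= params.max_hom_per_window)
    )
    # per-SNP: fraction of covering windows that are heterozygous
    cover_lo = np.maximum(0, np.arange(m) - w + 1)
    cover_hi = np.minimum(n_win - 1, np.arange(m))
    cok = np.concatenate([[0], np.cumsum(win_ok.astype(int))])
    n_ok = cok[cover_hi + 1] - cok[cover_lo]
    n_cov = cover_hi - cover_lo + 1
    if params.require_all_windows:
        flagged = n_ok == n_cov
    else:
        flagged = n_ok / n_cov > params.snp_in_run_threshold
    # a flagged homozygous/missing call can sit inside a run, but runs must
    # start and end on a called heterozygous SNP
    out: list[tuple[int, int, int, int]] = []
    j = 0
    while j < m:
        if not flagged[j]:
            j += 1
            continue
        k = j
        while (
            k + 1 < m
            and flagged[k + 1]
            and pos[k + 1] - pos[k] <= params.max_gap_bp
        ):
            k += 1
        idx = np.arange(j, k + 1)
        het_idx = idx[row[idx] == 1]
        if het_idx.size:
            lo, hi = int(het_idx[0]), int(het_idx[-1])
            n_snps = hi - lo + 1
            length = int(pos[hi] - pos[lo]) + 1
            if length >= params.min_length_bp and n_snps / length >= params.min_density:
                out.append((int(pos[lo]), int(pos[hi]), n_snps, lo))
        j = k + 1
    return out


def detect_rohet(
    g: GenotypeMatrix, animal: str, params: RohetParams | None = None
) -> list[RunOfHeterozygosity]:
    """Detect heterozygous runs for one animal, per chromosome.

    The 50-SNP window slides in 1-SNP steps; a window is heterozygous when
    it holds at most ``max_missing_per_window`` missing and
    ``max_hom_per_window`` homozygous calls.  Consecutive flagged SNPs
    (inter-SNP gap <= ``max_gap_bp``) form candidates, trimmed to start and
    end on heterozygous calls, then screened on minimum length and SNP
    density.
    """
    params = params or RohetParams()
    row = g.dosage[g.samples.index(animal)]
    chroms = np.array([s.chrom for s in g.snps])
    pos = np.array([s.pos_bp for s in g.snps])
    runs: list[RunOfHeterozygosity] = []
    for ch in pd.unique(chroms):
        sel = chroms == ch
        for start_bp, end_bp, n_snps, _ in _runs_one_chrom(row[sel], pos[sel], params):
            runs.append(RunOfHeterozygosity(animal, str(ch), start_bp, end_bp, n_snps))
    return runs


def detect_rohet_all(
    g: GenotypeMatrix, params: RohetParams | None = None
) -> dict[str, list[RunOfHeterozygosity]]:
    return {a: detect_rohet(g, a, params) for a in g.samples}


def classify_run_lengths(runs: list[RunOfHeterozygosity]) -> dict[str, int]:
    """Count runs in the short / intermediate / long bp-length classes."""
    counts = {k: 0 for k in LENGTH_CLASS_LABELS}
    for r in runs:
        if r.length_bp <= LENGTH_CLASS_EDGES[0]:
            counts[LENGTH_CLASS_LABELS[0]] += 1
        elif r.length_bp <= LENGTH_CLASS_EDGES[1]:
            counts[LENGTH_CLASS_LABELS[1]] += 1
        else:
            counts[LENGTH_CLASS_LABELS[2]] += 1
    return counts


# ---------------------------------------------------------------------------
# Profiles and subsets
# ---------------------------------------------------------------------------

def het_profiles(
    g: GenotypeMatrix,
    stats: LocusStats | None = None,
    rohet_params: RohetParams | None = None,
    with_runs: bool = True,
) -> pd.DataFrame:
    """OH, HL and ROHet summaries for every animal, as a DataFrame."""
    stats = stats or locus_stats(g)
    rows = []
    for a in g.samples:
        prof = HetProfile(
            animal_id=a,
            oh=observed_heterozygosity(g, a),
            hl=homozygosity_by_locus(g, stats, a),
        )
        if with_runs:
            runs = detect_rohet(g, a, rohet_params)
            prof.rohet_count = len(runs)
            prof.rohet_total_bp = sum(r.length_bp for r in runs)
            prof.rohet_by_class = classify_run_lengths(runs)
        rows.append(
            {
                "animal_id": prof.animal_id,
                "oh": prof.oh,
                "hl": prof.hl,
                "rohet_count": prof.rohet_count,
                "rohet_total_bp": prof.rohet_total_bp,
                **{f"rohet_{k}": v for k, v in prof.rohet_by_class.items()},
            }
        )
    return pd.DataFrame(rows)


def subset_measures(
    g: GenotypeMatrix,
    stats: LocusStats,
    snp_subset: np.ndarray | dict[str, np.ndarray],
) -> pd.DataFrame:
    """OH and HL restricted to a SNP subset.

    ``snp_subset`` is either one boolean/index array applied to every
    animal (e.g. the SNPs of chromosomes carrying dominance hits, for a
    trait-specific measure) or a per-animal mapping (e.g. the complement of
    each animal's own ROHet SNPs).
    """
    def _one(animal: str, idx: np.ndarray) -> dict:
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        if idx.size == 0:
            raise ValueError(f"empty SNP subset for animal {animal}")
        sub = g.subset_snps(idx)
        sub_stats = LocusStats(stats.freq_b[idx], stats.expected_het[idx])
        return {
            "animal_id": animal,
            "oh": observed_heterozygosity(sub, animal),
            "hl": homozygosity_by_locus(sub, sub_stats, animal),
        }

    if isinstance(snp_subset, dict):
        return pd.DataFrame([_one(a, snp_subset[a]) for a in g.samples if a in snp_subset])
    return pd.DataFrame([_one(a, snp_subset) for a in g.samples])


def rank_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    return float(_sps.spearmanr(x, y).statistic)
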