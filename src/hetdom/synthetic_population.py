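"""Synthetic crossbred populations with the structure the analysis assumes.

The generator emulates a multi-breed beef/dairy cattle cohort: breeds are
founder allele-frequency vectors diverged from a common ancestral
frequency (an F_ST-style Balding-Nichols draw); founders are sampled in
Hardy-Weinberg proportions within breed; offspring gametes are produced by
per-chromosome gamete dropping with Poisson recombination (no
interference), so crossbreds show both elevated global heterozygosity and
local heterozygous runs.  Phenotypes add fixed effects, sparse additive
and dominance QTL effects, a pedigree-dropped polygenic term and Gaussian
noise, with every generative component kept in a truth table for recovery
tests.

All stochastic operations are pure functions of their inputs and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, PhenotypeRecord, SNPInfo
from .pedigree_coefficients import (
    BreedComposition,
    bin_recombination_class,
    recombination_loss,
)

__all__ = [
    "BreedModel",
    "SimPedigree",
    "TraitArchitecture",
    "default_breed_model",
    "simulate_founders",
    "mate",
    "simulate_phenotypes",
    "simulate_crossbred_cohort",
    "analytic_trait_variance",
]


@dataclass
class BreedModel:
    """Breed labels, per-breed allele-b frequencies and the SNP map.

    ``chrom_lengths_morgans`` gives each chromosome's genetic length; one
    Morgan means one expected crossover per transmitted gamete.
    """

    breeds: list[str]
    founder_freqs: np.ndarray  # K x m, entries in (0, 1)
    snps: list[SNPInfo]
    chrom_lengths_morgans: dict[str, float]

    def __post_init__(self) -> None:
        self.founder_freqs = np.asarray(self.founder_freqs, dtype=float)
        if len(self.breeds) < 2:
            raise ValueError("crossbred scenarios need at least 2 breeds")
        if self.founder_freqs.shape != (len(self.breeds), len(self.snps)):
            raise ValueError("founder_freqs must be K breeds x m SNPs")
        if np.any((self.founder_freqs <= 0) | (self.founder_freqs >= 1)):
            raise ValueError("founder frequencies must lie strictly in (0, 1)")
        # keep the same (chrom, pos) order GenotypeMatrix enforces
        order = sorted(range(len(self.snps)),
                       key=lambda j: (self.snps[j].chrom, self.snps[j].pos_bp))
        if order != list(range(len(self.snps))):
            self.snps = [self.snps[j] for j in order]
            self.founder_freqs = self.founder_freqs[:, order]


@dataclass
class SimPedigree:
    """Pedigree records plus per-animal breed composition.

    ``table`` columns: animal_id, sire_id, dam_id ('0' marks a founder
    side); parents always precede offspring.
    """

    table: pd.DataFrame
    compositions: dict[str, BreedComposition] = field(default_factory=dict)

    def add(self, animal: str, sire: str, dam: str, comp: BreedComposition) -> None:
        self.table = pd.concat(
            [
                self.table,
                pd.DataFrame([{"animal_id": animal, "sire_id": sire, "dam_id": dam}]),
            ],
            ignore_index=True,
        )
        self.compositions[animal] = comp

    @staticmethod
    def empty() -> "SimPedigree":
        return SimPedigree(
            table=pd.DataFrame(columns=["animal_id", "sire_id", "dam_id"])
        )


@dataclass
class TraitArchitecture:
    """Generative trait model.

    * ``qtl_add``: SNP index -> additive effect (trait units per allele-b copy)
    * ``qtl_dom``: SNP index -> dominance effect (trait units for the
      heterozygote, on top of the homozygote midpoint)
    * ``h2_poly``: fraction of trait variance from the polygenic term
    * ``fixed_effect_levels``: factor -> {level: effect}; levels are
      assigned uniformly at random per animal
    * ``sigma_e``: residual SD
    """

    qtl_add: dict[int, float] = field(default_factory=dict)
    qtl_dom: dict[int, float] = field(default_factory=dict)
    h2_poly: float = 0.0
    fixed_effect_levels: dict[str, dict[str, float]] = field(default_factory=dict)
    sigma_e: float = 1.0
    intercept: float = 0.0

    def polygenic_variance(self, freqs: np.ndarray) -> float:
        """sigma_a^2 implied by h2_poly given the QTL and residual variances."""
        if self.h2_poly == 0.0:
            return 0.0
        v_qtl = _qtl_variance(self, freqs)
        return self.h2_poly * (v_qtl + self.sigma_e**2) / (1.0 - self.h2_poly)


def _qtl_variance(arch: TraitArchitecture, freqs: np.ndarray) -> float:
    """HWE variance of the QTL sum at the given allele-b frequencies."""
    v = 0.0
    for j, a in arch.qtl_add.items():
        p = freqs[j]
        v += a * a * 2.0 * p * (1.0 - p)
    for j, d in arch.qtl_dom.items():
        p = freqs[j]
        h = 2.0 * p * (1.0 - p)
        v += d * d * h * (1.0 - h)
    return v


def analytic_trait_variance(arch: TraitArchitecture, freqs: np.ndarray) -> float:
    """Target trait variance: fixed effects (uniform level assignment) +
    QTL (HWE) + polygenic + residual.  Covariances between the independent
    components are zero by construction."""
    v = _qtl_variance(arch, freqs) + arch.polygenic_variance(freqs) + arch.sigma_e**2
    for levels in arch.fixed_effect_levels.values():
        eff = np.array(list(levels.values()), dtype=float)
        v += float(eff.var())
    return v


def default_breed_model(
    n_breeds: int = 3,
    n_chrom: int = 2,
    snps_per_chrom: int = 500,
    spacing_bp: int = 2_000,
    fst: float = 0.25,
    frac_divergent_blocks: float = 0.2,
    block_snps: int = 100,
    block_fixation: float = 0.97,
    chrom_length_morgans: float = 1.0,
    seed: int = 0,
) -> BreedModel:
    """A compact multi-breed model with Balding-Nichols diverged frequencies.

    Ancestral frequencies are Uniform(0.1, 0.9); each breed draws its own
    frequency from Beta(p (1-F)/F, (1-p)(1-F)/F), so ``fst`` controls how
    divergent (and hence how heterotic) crosses are.

    A fraction of ``block_snps``-SNP segments are made strongly
    breed-differentiated: within such a block each breed sits near
    fixation for one allele (frequency ``block_fixation`` or its
    complement, chosen per breed, never identical across all breeds).
    Crosses between breeds favouring opposite alleles are then mostly
    heterozygous along the block — the local structure
    runs-of-heterozygosity detection needs, which independent per-SNP
    draws cannot produce.  Fixation is deliberately partial so that run
    detection stays sporadic at the individual level: per-animal run
    counts are then a weak, noisy correlate of ancestry, while genome-wide
    heterozygosity remains a strong one, matching how the two measures
    behave in real multi-breed cattle data.
    """
    rng = np.random.default_rng(seed)
    m = n_chrom * snps_per_chrom
    anc = rng.uniform(0.1, 0.9, size=m)
    a = anc * (1.0 - fst) / fst
    b = (1.0 - anc) * (1.0 - fst) / fst
    freqs = np.clip(rng.beta(a, b, size=(n_breeds, m)), 1e-3, 1.0 - 1e-3)
    block_starts = np.arange(0, m, block_snps)
    n_div = max(1, round(frac_divergent_blocks * block_starts.size))
    for start in rng.choice(block_starts, size=min(n_div, block_starts.size), replace=False):
        states = rng.integers(2, size=n_breeds)  # which allele each breed fixes
        while states.min() == states.max():  # differentiated by definition
            states = rng.integers(2, size=n_breeds)
        block = slice(int(start), min(int(start) + block_snps, m))
        width = block.stop - block.start
        jitter = rng.uniform(0.0, 0.01, size=(n_breeds, width))
        freqs[:, block] = np.where(
            states[:, None] == 1, block_fixation - jitter, 1.0 - block_fixation + jitter
        )
    breeds = [f"breed{k}" for k in range(n_breeds)]
    snps = [
        SNPInfo(
            snp_id=f"snp_{c}_{i}",
            chrom=f"chr{c + 1}",
            pos_bp=(i + 1) * spacing_bp,
        )
        for c in range(n_chrom)
        for i in range(snps_per_chrom)
    ]
    lengths = {f"chr{c + 1}": chrom_length_morgans for c in range(n_chrom)}
    return BreedModel(breeds=breeds, founder_freqs=freqs, snps=snps,
                      chrom_lengths_morgans=lengths)


def simulate_founders(
    bm: BreedModel, n_per_breed: int, seed: int
) -> tuple[GenotypeMatrix, SimPedigree]:
    """Purebred founders in HWE within breed, with phased haplotypes."""
    if n_per_breed < 1:
        raise ValueError("n_per_breed must be >= 1")
    rng = np.random.default_rng(seed)
    m = len(bm.snps)
    ped = SimPedigree.empty()
    ids, haps = [], []
    for k, breed in enumerate(bm.breeds):
        p = bm.founder_freqs[k]
        h = (rng.random((n_per_breed, 2, m)) < p).astype(np.int8)
        for i in range(n_per_breed):
            aid = f"{breed}_f{i}"
            ids.append(aid)
            ped.add(aid, "0", "0", BreedComposition.purebred(breed))
        haps.append(h)
    hap = np.concatenate(haps, axis=0)
    g = GenotypeMatrix(
        samples=ids, snps=list(bm.snps), dosage=hap.sum(axis=1).astype(np.int8),
        haplotypes=hap,
    )
    return g, ped


def _chrom_slices(snps: list[SNPInfo]) -> list[tuple[str, slice]]:
    out, start = [], 0
    for j in range(1, len(snps) + 1):
        if j == len(snps) or snps[j].chrom != snps[start].chrom:
            out.append((snps[start].chrom, slice(start, j)))
            start = j
    return out


def _gamete(hap: np.ndarray, bm: BreedModel, pos: np.ndarray, rng) -> np.ndarray:
    """One recombined gamete from a (2, m) phased parent."""
    m = hap.shape[1]
    gam = np.empty(m, dtype=np.int8)
    for chrom, sl in _chrom_slices(bm.snps):
        L = bm.chrom_lengths_morgans[chrom]
        p = pos[sl]
        n_x = rng.poisson(L)
        cur = int(rng.integers(2))
        if n_x == 0:
            gam[sl] = hap[cur, sl]
            continue
        breaks = np.sort(rng.uniform(p[0], p[-1] + 1, size=n_x))
        seg = np.searchsorted(breaks, p, side="right")
        choice = (cur + seg) % 2
        idx = np.arange(sl.start, sl.stop)
        gam[sl] = hap[choice, idx]
    return gam


def mate(
    g: GenotypeMatrix,
    ped: SimPedigree,
    pairs: list[tuple[str, str]],
    seed: int,
    id_prefix: str = "off",
) -> tuple[GenotypeMatrix, SimPedigree]:
    """Extend the population with one offspring per (sire, dam) pair.

    Each gamete recombines per chromosome (Poisson crossover count at the
    chromosome's Morgan length, uniform breakpoints); offspring breed
    composition is the parental mean.  Requires phased haplotypes on ``g``.
    """
    if g.haplotypes is None:
        raise ValueError("mate() needs phased haplotypes (simulated genotypes)")
    rng = np.random.default_rng(seed)
    bm = getattr(g, "_breed_model", None)
    if bm is None:
        raise ValueError("attach the BreedModel as g._breed_model before mating")
    pos = np.array([s.pos_bp for s in g.snps], dtype=float)
    index = {a: i for i, a in enumerate(g.samples)}
    existing = int(sum(1 for a in g.samples if a.startswith(id_prefix)))
    new_ids, new_haps = [], []
    hap_all = g.haplotypes
    for k, (sire, dam) in enumerate(pairs):
        for par in (sire, dam):
            if par not in index:
                raise ValueError(f"unknown parent {par}")
        if sire == dam:
            import logging

            logging.getLogger("hetdom").warning("self-mating of %s", sire)
        child = f"{id_prefix}{existing + k}"
        h = np.stack(
            [
                _gamete(hap_all[index[sire]], bm, pos, rng),
                _gamete(hap_all[index[dam]], bm, pos, rng),
            ]
        )
        new_ids.append(child)
        new_haps.append(h)
        ped.add(
            child, sire, dam,
            BreedComposition.mean(ped.compositions[sire], ped.compositions[dam]),
        )
        index[child] = len(g.samples) + k
        hap_all = np.concatenate([hap_all, h[None]], axis=0)
    hap = np.concatenate([g.haplotypes] + [h[None] for h in new_haps], axis=0)
    out = GenotypeMatrix(
        samples=list(g.samples) + new_ids,
        snps=list(g.snps),
        dosage=hap.sum(axis=1).astype(np.int8),
        haplotypes=hap,
    )
    out._breed_model = bm  # type: ignore[attr-defined]
    return out, ped


def simulate_phenotypes(
    g: GenotypeMatrix,
    ped: SimPedigree,
    arch: TraitArchitecture,
    seed: int,
    group_size: int = 10,
) -> tuple[list[PhenotypeRecord], pd.DataFrame]:
    """Phenotypes for every genotyped animal, plus a truth table.

    trait = intercept + fixed effects + sum(additive QTL * dosage)
          + sum(dominance QTL * 1[dosage == 1]) + polygenic + N(0, sigma_e^2)

    The polygenic value is gene-dropped along the pedigree (founders
    N(0, sigma_a^2); offspring = parent average + Mendelian sampling with
    variance sigma_a^2 / 2), independent of the markers, so marker QTL and
    polygenic signals stay separable.  Contemporary groups are blocks of
    ``group_size`` randomized animals; recombination-loss classes come
    from the pedigree compositions.
    """
    rng = np.random.default_rng(seed)
    n = g.n_samples
    freqs = np.clip(g.dosage.astype(float).mean(axis=0) / 2.0, 1e-6, 1 - 1e-6)
    sigma_a = float(np.sqrt(arch.polygenic_variance(freqs)))

    # polygenic gene dropping down the (sorted parents-first) pedigree
    poly: dict[str, float] = {}
    for _, r in ped.table.iterrows():
        aid, sire, dam = r["animal_id"], r["sire_id"], r["dam_id"]
        if sire == "0" and dam == "0":
            poly[aid] = rng.normal(0.0, sigma_a) if sigma_a else 0.0
        else:
            pa = 0.5 * (poly[sire] + poly[dam])
            ms = rng.normal(0.0, sigma_a / np.sqrt(2.0)) if sigma_a else 0.0
            poly[aid] = pa + ms

    # fixed-effect level assignment
    fe_levels: dict[str, list[str]] = {}
    fe_value = np.zeros(n)
    assigned: dict[str, list[str]] = {}
    for factor, levels in arch.fixed_effect_levels.items():
        labs = list(levels)
        pick = rng.integers(len(labs), size=n)
        assigned[factor] = [labs[i] for i in pick]
        fe_value += np.array([levels[labs[i]] for i in pick])

    # QTL contributions
    qtl = np.zeros(n)
    for j, a in arch.qtl_add.items():
        dos = g.dosage[:, j].astype(float)
        qtl += a * np.where(dos < 0, 2 * freqs[j], dos)
    for j, d in arch.qtl_dom.items():
        qtl += d * (g.dosage[:, j] == 1)

    poly_vec = np.array([poly.get(a, 0.0) for a in g.samples])
    noise = rng.normal(0.0, arch.sigma_e, size=n) if arch.sigma_e else np.zeros(n)
    trait = arch.intercept + fe_value + qtl + poly_vec + noise

    # contemporary groups: block randomization
    order = rng.permutation(n)
    cg = np.empty(n, dtype=object)
    for b, start in enumerate(range(0, n, group_size)):
        cg[order[start:start + group_size]] = f"cg{b}"

    records, truth_rows = [], []
    for i, aid in enumerate(g.samples):
        comp = ped.compositions.get(aid)
        row = ped.table.loc[ped.table["animal_id"] == aid]
        if comp is not None and not row.empty and row.iloc[0]["sire_id"] != "0":
            rl = recombination_loss(
                ped.compositions[row.iloc[0]["sire_id"]],
                ped.compositions[row.iloc[0]["dam_id"]],
            )
        else:
            rl = 0.0
        rec = PhenotypeRecord(
            animal_id=aid,
            trait_value=float(trait[i]),
            dam_parity=assigned.get("dam_parity", ["1"] * n)[i],
            birth_herd=assigned.get("birth_herd", ["beef"] * n)[i],
            twin=assigned.get("twin", ["0"] * n)[i],
            rec_loss_class=bin_recombination_class(min(max(rl, 0.0), 1.0)),
            contemporary_group=str(cg[i]),
        )
        records.append(rec)
        truth_rows.append(
            {
                "animal_id": aid,
                "trait": float(trait[i]),
                "fixed": float(fe_value[i]),
                "qtl": float(qtl[i]),
                "polygenic": float(poly_vec[i]),
                "noise": float(noise[i]),
            }
        )
    return records, pd.DataFrame(truth_rows)


def simulate_crossbred_cohort(
    bm: BreedModel,
    n_founders_per_breed: int = 20,
    n_f1: int = 40,
    n_f2: int = 40,
    seed: int = 0,
) -> tuple[GenotypeMatrix, SimPedigree]:
    """Founders + between-breed F1s + random-mated second generation.

    The mating design yields a spread of pedigree heterosis coefficients
    (0 for purebreds, 1 for F1s, intermediate for later crosses), which is
    what the heterosis-vs-heterozygosity correlation analyses need.
    """
    rng = np.random.default_rng(seed)
    g, ped = simulate_founders(bm, n_founders_per_breed, seed=int(rng.integers(2**31)))
    g._breed_model = bm  # type: ignore[attr-defined]
    K = len(bm.breeds)
    founders_by_breed = [
        [f"{b}_f{i}" for i in range(n_founders_per_breed)] for b in bm.breeds
    ]
    pairs = []
    for _ in range(n_f1):
        ka, kb = rng.choice(K, size=2, replace=False)
        pairs.append(
            (
                founders_by_breed[ka][rng.integers(n_founders_per_breed)],
                founders_by_breed[kb][rng.integers(n_founders_per_breed)],
            )
        )
    g, ped = mate(g, ped, pairs, seed=int(rng.integers(2**31)), id_prefix="f1_")
    pool = list(g.samples)
    pairs2 = []
    for _ in range(n_f2):
        a, b = rng.choice(len(pool), size=2, replace=False)
        pairs2.append((pool[a], pool[b]))
    g, ped = mate(g, ped, pairs2, seed=int(rng.integers(2**31)), id_prefix="g2_")
    return g, ped
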