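"""Pedigree-based coefficients for crossbred populations.

Breed composition propagates down the pedigree as the parental mean.  From
the sire and dam compositions two classical crossbreeding coefficients are
derived: the heterosis coefficient (the expected fraction of loci with
alleles from different breeds, a pedigree proxy for heterozygosity) and the
Dickerson recombination-loss coefficient.  The module also builds the
numerator relationship matrix A with phantom-parent genetic groups, i.e.
the (A, Q) pair of the animal model a ~ N(Qg, A sigma_a^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BreedComposition",
    "PedigreeModel",
    "breed_composition",
    "heterosis_coefficient",
    "recombination_loss",
    "bin_recombination_class",
    "build_nrm_with_groups",
]


@dataclass(frozen=True)
class BreedComposition:
    """Per-animal breed fractions; values sum to 1."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.fractions.values()), dtype=float)
        if (vals < -1e-12).any():
            raise ValueError("breed fractions must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"breed fractions must sum to 1, got {vals.sum()}")

    def __getitem__(self, breed: str) -> float:
        return self.fractions.get(breed, 0.0)

    def majority_breed(self) -> str:
        # ties broken lexicographically
        return min(self.fractions, key=lambda b: (-self.fractions[b], b))

    @staticmethod
    def purebred(breed: str) -> "BreedComposition":
        return BreedComposition({breed: 1.0})

    @staticmethod
    def mean(a: "BreedComposition", b: "BreedComposition") -> "BreedComposition":
        breeds = set(a.fractions) | set(b.fractions)
        return BreedComposition({br: (a[br] + b[br]) / 2.0 for br in breeds})


@dataclass
class PedigreeModel:
    """Numerator relationship matrix with genetic-group incidence.

    ``A`` is twice the kinship matrix over the pedigree animals (order given
    by ``animals``); ``Q[i, g]`` is animal i's expected fraction of genes
    from phantom-parent group g, each row summing to 1.
    """

    animals: list[str]
    A: np.ndarray
    Q: np.ndarray
    group_labels: list[str]


def _as_records(ped: pd.DataFrame) -> list[tuple[str, str, str]]:
    return [
        (str(r["animal_id"]), str(r["sire_id"]), str(r["dam_id"]))
        for _, r in ped.iterrows()
    ]


def breed_composition(
    ped: pd.DataFrame,
    founder_comps: dict[str, BreedComposition],
    animal: str | None = None,
) -> dict[str, BreedComposition] | BreedComposition:
    """Breed composition of every pedigree animal (or one ``animal``).

    Founders (parent id '0') take their composition from ``founder_comps``;
    non-founders get the mean of the parental compositions, recursively.
    An animal with exactly one known parent is refused: the pedigree proxy
    is undefined without a composition for the unknown side.
    """
    comps: dict[str, BreedComposition] = dict(founder_comps)
    for aid, sire, dam in _as_records(ped):
        if aid in comps:
            continue
        if sire == "0" and dam == "0":
            raise ValueError(f"founder {aid} has no breed composition supplied")
        if sire == "0" or dam == "0":
            raise ValueError(
                f"animal {aid} has one unknown parent; supply a phantom "
                "purebred composition for it in founder_comps"
            )
        if sire not in comps or dam not in comps:
            raise ValueError(f"pedigree not sorted parents-first at animal {aid}")
        comps[aid] = BreedComposition.mean(comps[sire], comps[dam])
    if animal is not None:
        return comps[animal]
    return comps


def heterosis_coefficient(sire: BreedComposition, dam: BreedComposition) -> float:
    """Expected-heterozygosity proxy: 1 - sum_i B_S_i * B_D_i.

    0 for a purebred mating within one breed, 1 for a fully outcrossed
    mating between non-overlapping compositions.
    """
    breeds = set(sire.fractions) | set(dam.fractions)
    return 1.0 - sum(sire[b] * dam[b] for b in breeds)


def recombination_loss(sire: BreedComposition, dam: BreedComposition) -> float:
    """Dickerson recombination loss: 1 - sum_i (B_S_i^2 + B_D_i^2) / 2."""
    breeds = set(sire.fractions) | set(dam.fractions)
    return 1.0 - sum((sire[b] ** 2 + dam[b] ** 2) / 2.0 for b in breeds)


_REC_EDGES = (0.0, 0.10, 0.20, 0.30, 0.40, 0.50)


def bin_recombination_class(r: float) -> int:
    """Bin a recombination-loss coefficient into classes 0-6.

    Class 0 is exactly 0; then right-closed 10-point bands ((0, 0.10] -> 1,
    (0.10, 0.20] -> 2, ...) with everything above 0.50 in class 6.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"recombination loss must be in [0, 1], got {r}")
    if r == 0.0:
        return 0
    for k, hi in enumerate(_REC_EDGES[1:], start=1):
        if r <= hi + 1e-12:
            return k
    return 6


def coefficient_table(
    ped: pd.DataFrame, founder_comps: dict[str, BreedComposition]
) -> pd.DataFrame:
    """Per-animal heterosis / recombination-loss / class table.

    Founders get coefficient 0 under their own purebred (or supplied)
    composition mated to itself — i.e. no expected excess heterozygosity.
    """
    comps = breed_composition(ped, founder_comps)
    rows = []
    for aid, sire, dam in _as_records(ped):
        if sire == "0" and dam == "0":
            het = recl = 0.0
        else:
            het = heterosis_coefficient(comps[sire], comps[dam])
            recl = recombination_loss(comps[sire], comps[dam])
        rows.append(
            {
                "animal_id": aid,
                "heterosis": het,
                "rec_loss": recl,
                "rec_class": bin_recombination_class(recl),
            }
        )
    return pd.DataFrame(rows)


def build_nrm_with_groups(
    ped: pd.DataFrame,
    founder_comps: dict[str, BreedComposition] | None = None,
    group_rule: str = "majority_breed",
) -> PedigreeModel:
    """Numerator relationship matrix A and genetic-group incidence Q.

    A follows the tabular (Henderson) recursion with founders unrelated and
    non-inbred.  Each founder's unknown parents are replaced by phantom
    parents belonging to one genetic group — under the default rule, the
    group of the founder's majority breed (lexicographic tie-break).  Q
    accumulates expected phantom-group fractions down the pedigree
    (founder row = its group's unit vector, offspring row = parental mean),
    so every row sums to 1.
    """
    recs = _as_records(ped)
    ids = [a for a, _, _ in recs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate animal ids in pedigree")
    index = {a: i for i, a in enumerate(ids)}
    n = len(ids)

    for aid, sire, dam in recs:
        for p in (sire, dam):
            if p != "0" and index.get(p, n) >= index[aid]:
                raise ValueError(f"pedigree not sorted parents-first at {aid} (parent {p})")

    # group assignment for founders
    founder_ids = [a for a, s, d in recs if s == "0" and d == "0"]
    if group_rule == "majority_breed" and founder_comps:
        groups = {f: founder_comps[f].majority_breed() if f in founder_comps else "unknown"
                  for f in founder_ids}
    else:
        groups = {f: "founders" for f in founder_ids}
    group_labels = sorted(set(groups.values()))
    # a non-founder with one unknown parent gets that side from a catch-all group
    if any((s == "0") != (d == "0") for _, s, d in recs):
        if "unknown" not in group_labels:
            group_labels.append("unknown")
            group_labels.sort()
    gidx = {g: k for k, g in enumerate(group_labels)}

    A = np.zeros((n, n))
    Q = np.zeros((n, len(group_labels)))
    for aid, sire, dam in recs:
        i = index[aid]
        si = index.get(sire, -1) if sire != "0" else -1
        di = index.get(dam, -1) if dam != "0" else -1
        if si < 0 and di < 0:
            A[i, i] = 1.0
            Q[i, gidx[groups[aid]]] = 1.0
            continue
        # tabular rules: a_ij = (a_j,sire + a_j,dam)/2; a_ii = 1 + a_sire,dam/2
        for j in range(i):
            a_js = A[j, si] if si >= 0 else 0.0
            a_jd = A[j, di] if di >= 0 else 0.0
            A[i, j] = A[j, i] = 0.5 * (a_js + a_jd)
        A[i, i] = 1.0 + (0.5 * A[si, di] if si >= 0 and di >= 0 else 0.0)
        Q[i] = 0.5 * (Q[si] if si >= 0 else 0) + 0.5 * (Q[di] if di >= 0 else 0)
        if si < 0:
            Q[i, gidx["unknown"]] += 0.5
        if di < 0:
            Q[i, gidx["unknown"]] += 0.5
    return PedigreeModel(animals=ids, A=A, Q=Q, group_labels=group_labels)
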