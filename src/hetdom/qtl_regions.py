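"""Collapse significant SNPs into QTL regions via local LD.

Around each significant SNP, every same-chromosome SNP within a distance
window (default +/- 0.5 Mb) whose genotypic r-squared with it reaches the
threshold (default 0.5) joins that SNP's candidate region; overlapping or
abutting candidates on a chromosome are merged transitively into one QTL
region.  The lead SNP of a region is its most significant member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix

__all__ = ["QTLRegion", "ld_r2", "build_regions", "regions_to_bed"]


@dataclass
class QTLRegion:
    chrom: str
    start_bp: int
    end_bp: int
    member_snps: list[str]
    n_significant: int
    lead_snp: str
    lead_p: float


def ld_r2(g: GenotypeMatrix, snp_i: int, snp_j: int) -> float:
    """Genotypic (composite, phase-free) LD: squared Pearson correlation of
    the two dosage vectors over jointly called animals.

    Returns NaN when fewer than three animals are jointly called or either
    dosage is constant among them.
    """
    a = g.dosage[:, snp_i].astype(float)
    b = g.dosage[:, snp_j].astype(float)
    ok = (g.dosage[:, snp_i] != MISSING) & (g.dosage[:, snp_j] != MISSING)
    a, b = a[ok], b[ok]
    if a.size < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def build_regions(
    sig_snps: pd.DataFrame,
    g: GenotypeMatrix,
    window_bp: int = 500_000,
    r2_min: float = 0.5,
    centered_window: bool = True,
) -> list[QTLRegion]:
    """QTL regions from a table of significant SNPs.

    ``sig_snps`` needs columns snp_id, chrom, pos_bp and p_value.  With the
    default ``centered_window`` the window is +/- ``window_bp`` around each
    significant SNP; otherwise ``window_bp`` is the total span.  LD is
    evaluated against the significant SNP itself (transitivity enters only
    through region merging).  Lead-SNP ties on p break on smaller position,
    then id.
    """
    if sig_snps.empty:
        return []
    half = window_bp if centered_window else window_bp // 2
    snp_index = {s.snp_id: j for j, s in enumerate(g.snps)}
    chroms = np.array([s.chrom for s in g.snps])
    pos = np.array([s.pos_bp for s in g.snps])

    # candidate region per significant SNP
    candidates: list[dict] = []
    for _, row in sig_snps.iterrows():
        j = snp_index[row["snp_id"]]
        near = np.flatnonzero(
            (chroms == g.snps[j].chrom) & (np.abs(pos - g.snps[j].pos_bp) <= half)
        )
        members = [j] + [
            int(k) for k in near if k != j and (ld_r2(g, j, k) or 0) >= r2_min
        ]
        mpos = pos[members]
        candidates.append(
            {
                "chrom": g.snps[j].chrom,
                "start": int(mpos.min()),
                "end": int(mpos.max()),
                "members": set(members),
                "sig": {(float(row["p_value"]), int(g.snps[j].pos_bp), row["snp_id"])},
            }
        )

    # transitive merge of overlapping/abutting candidates per chromosome
    merged: list[dict] = []
    for c in sorted(candidates, key=lambda c: (c["chrom"], c["start"], c["end"])):
        if merged and merged[-1]["chrom"] == c["chrom"] and c["start"] <= merged[-1]["end"] + 1:
            m = merged[-1]
            m["end"] = max(m["end"], c["end"])
            m["members"] |= c["members"]
            m["sig"] |= c["sig"]
        else:
            merged.append(c)

    out = []
    for m in merged:
        lead_p, _, lead_id = min(m["sig"])
        out.append(
            QTLRegion(
                chrom=m["chrom"],
                start_bp=m["start"],
                end_bp=m["end"],
                member_snps=sorted(g.snps[k].snp_id for k in m["members"]),
                n_significant=len(m["sig"]),
                lead_snp=lead_id,
                lead_p=lead_p,
            )
        )
    return out


def regions_to_bed(regions: list[QTLRegion]) -> pd.DataFrame:
    """Regions as 0-based half-open BED intervals (from 1-based closed)."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start_bp - 1 for r in regions],
            "end": [r.end_bp for r in regions],
            "name": [r.lead_snp for r in regions],
            "n_significant": [r.n_significant for r in regions],
        }
    )
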