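"""Two-stage genome-wide additive + dominance scan.

Stage one adjusts the phenotypes for nuisance fixed effects and the
polygenic background via a mixed model with the genomic relationship
matrix; stage two regresses the stage-one residuals, SNP by SNP, on an
additive code (0/1/2 copies of allele b) and a dominance code (1 for the
heterozygote, 0 for homozygotes):

    e = mu + b1 * add + b2 * dom + error

b2 is the dominance deviation of the heterozygote from the homozygote
midpoint.  p-values for b1 and b2 (t reference, df = n_used - 3) are
converted to q-values separately per family by the Storey procedure, with
significance declared at q <= 0.01.  A genomic inflation factor per family
diagnoses residual stratification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING, GenotypeMatrix, PhenotypeRecord
from .mixed_models import MixedModelFit, MixedModelSpec, design_from_phenotypes, fit_lmm
from .relationship_grm import GRM

__all__ = [
    "AdjustedPhenotypes",
    "ScanDiagnostics",
    "adjust_phenotypes",
    "scan_locus",
    "run_scan",
    "genomic_lambda",
    "qvalues",
]

# median of the chi-square(1) distribution
_CHI2_1_MEDIAN = stats.chi2.ppf(0.5, df=1)

_SCAN_FACTORS = ("dam_parity", "birth_herd", "twin", "contemporary_group")


@dataclass
class AdjustedPhenotypes:
    animals: list[str]
    residuals: np.ndarray
    fit_meta: MixedModelFit


@dataclass
class ScanDiagnostics:
    lambda_additive: float
    lambda_dominance: float


def adjust_phenotypes(
    records: list[PhenotypeRecord], grm: GRM
) -> AdjustedPhenotypes:
    """Pre-adjust phenotypes for fixed effects and the polygenic term.

    Fixed effects: contemporary group, birth herd type, dam parity and twin
    status (no heterozygosity covariate here); random effect: animal with
    covariance G sigma_a^2.  Returns the residual e = y - X beta - a_hat
    used as the response of the per-SNP scan.
    """
    y, X, names, animals = design_from_phenotypes(records, factors=_SCAN_FACTORS)
    missing = [a for a in animals if a not in set(grm.samples)]
    if missing:
        raise ValueError(f"animals missing from the GRM: {missing[:10]}")
    idx = [grm.samples.index(a) for a in animals]
    K = grm.G[np.ix_(idx, idx)]
    fit = fit_lmm(MixedModelSpec(y=y, X=X, K=K, x_names=names))
    return AdjustedPhenotypes(animals=animals, residuals=fit.residuals, fit_meta=fit)


def _ols_add_dom(e: np.ndarray, add: np.ndarray) -> dict:
    """OLS of e on [1, additive code, dominance code] with t-test p-values."""
    n = e.size
    dom = (add == 1).astype(float)
    Xk = np.column_stack([np.ones(n), add.astype(float), dom])
    XtX = Xk.T @ Xk
    coef = np.linalg.solve(XtX, Xk.T @ e)
    r = e - Xk @ coef
    dof = n - 3
    s2 = float(r @ r) / dof
    cov = s2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):  # exact fits: se == 0
        t1, t2 = coef[1] / se[1], coef[2] / se[2]
    return {
        "b1": coef[1],
        "se1": se[1],
        "p_add": 2.0 * stats.t.sf(abs(t1), dof),
        "b2": coef[2],
        "se2": se[2],
        "p_dom": 2.0 * stats.t.sf(abs(t2), dof),
        "n_used": n,
        "het_freq": float(dom.mean()),
    }


def scan_locus(
    adj: AdjustedPhenotypes | np.ndarray, g: GenotypeMatrix, snp: int
) -> dict:
    """Per-SNP additive + dominance regression row.

    Animals with a missing call at the SNP are dropped from the locus
    regression.  When fewer than three genotype classes are present the
    dominance (or both) coefficients are not estimable and come back NaN.
    """
    e = adj.residuals if isinstance(adj, AdjustedPhenotypes) else np.asarray(adj, float)
    dos = g.dosage[:, snp]
    called = dos != MISSING
    add = dos[called].astype(float)
    ek = e[called]
    classes = np.unique(add)
    base = {
        "snp_id": g.snps[snp].snp_id,
        "chrom": g.snps[snp].chrom,
        "pos_bp": g.snps[snp].pos_bp,
        "n_used": int(called.sum()),
        "het_freq": float((add == 1).mean()) if add.size else np.nan,
    }
    nan_row = {
        "b1": np.nan, "se1": np.nan, "p_add": np.nan,
        "b2": np.nan, "se2": np.nan, "p_dom": np.nan,
    }
    if classes.size < 2 or add.size < 4:
        return {**base, **nan_row}
    if classes.size < 3:
        return {**base, **nan_row}
    return {**base, **_ols_add_dom(ek, add)}


def genomic_lambda(p_values: np.ndarray) -> float:
    """Genomic inflation factor from a family of p-values.

    lambda = median(qchisq(1 - p, 1)) / qchisq(0.5, 1); values near 1 mean
    the test statistics follow their null scale.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 100:
        raise ValueError("need at least 100 p-values for a stable lambda")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / _CHI2_1_MEDIAN)


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey pi0 via the lambda-grid smoother (grid 0–0.90, step 0.05).

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)); a cubic least-squares
    fit over the grid is evaluated at the largest lambda, then clamped to
    (0, 1].
    """
    if lambdas is None:
        lambdas = np.arange(0.0, 0.901, 0.05)
    m = p.size
    pi0_l = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lambdas])
    if np.all(pi0_l == pi0_l[0]):
        pi0 = pi0_l[0]
    else:
        coefs = np.polynomial.polynomial.polyfit(lambdas, pi0_l, deg=3)
        pi0 = float(np.polynomial.polynomial.polyval(lambdas[-1], coefs))
    return float(min(max(pi0, 1.0 / m), 1.0))


def qvalues(p_values: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey q-values; with ``pi0=1`` this is exactly Benjamini-Hochberg.

    q_(i) = min_{t >= p_(i)} pi0 * m * t / #{p <= t}, computed by the usual
    reverse cumulative minimum over the sorted p-values; output order
    matches the input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_scan(
    adj: AdjustedPhenotypes | np.ndarray,
    g: GenotypeMatrix,
    fdr_threshold: float = 0.01,
) -> tuple[pd.DataFrame, ScanDiagnostics]:
    """Scan every SNP, FDR-correct each effect family, attach diagnostics.

    Returns the per-SNP table (with q_add / q_dom and significance flags at
    ``fdr_threshold``) and the per-family genomic inflation factors.  Rows
    that were not estimable keep NaN statistics and are excluded from the
    FDR families.
    """
    e = adj.residuals if isinstance(adj, AdjustedPhenotypes) else np.asarray(adj, float)
    rows = [scan_locus(e, g, j) for j in range(g.n_snps)]
    df = pd.DataFrame(rows)
    for fam in ("add", "dom"):
        pcol, qcol = f"p_{fam}", f"q_{fam}"
        ok = df[pcol].notna().to_numpy()
        q = np.full(len(df), np.nan)
        if ok.any():
            q[ok] = qvalues(df.loc[ok, pcol].to_numpy())
        df[qcol] = q
        df[f"sig_{fam}"] = df[qcol] <= fdr_threshold
    diag = ScanDiagnostics(
        lambda_additive=genomic_lambda(df["p_add"].dropna().to_numpy()),
        lambda_dominance=genomic_lambda(df["p_dom"].dropna().to_numpy()),
    )
    return df, diag
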