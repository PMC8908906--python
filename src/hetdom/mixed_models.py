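"""Single-random-effect linear mixed models against an arbitrary kinship.

The model is y = X beta + Z a + e with a ~ N(0, K sigma_a^2) and
e ~ N(0, I sigma_e^2), where K is any symmetric PSD relatedness matrix —
the pedigree numerator relationship matrix (with genetic-group covariates
appended to X) for the heterozygosity-association model, or the genomic
relationship matrix for phenotype pre-adjustment.

Variance components are estimated by REML, profiling the variance ratio
lambda = sigma_a^2 / sigma_e^2 on the eigendecomposition of Z K Z', which
reduces every likelihood evaluation to diagonal weighted least squares
(the EMMA device).  A coarse log-grid locates the optimum and Brent's
method refines it; lambda = 0 is handled as a boundary estimate.
The ML likelihood is computed alongside for AIC, because models compared
on AIC here differ in their fixed effects and REML likelihoods are not
comparable across fixed-effect structures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import PhenotypeRecord

logger = logging.getLogger("hetdom")

__all__ = [
    "MixedModelSpec",
    "MixedModelFit",
    "fit_lmm",
    "het_association",
    "vif",
    "model_aic",
    "design_from_phenotypes",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class MixedModelSpec:
    y: np.ndarray
    X: np.ndarray
    K: np.ndarray
    Z: np.ndarray | None = None
    x_names: list[str] | None = None


@dataclass
class MixedModelFit:
    beta: np.ndarray
    beta_se: np.ndarray
    sigma_a2: float
    sigma_e2: float
    blup: np.ndarray
    residuals: np.ndarray
    logL_reml: float
    logL_ml: float
    aic: float
    x_names: list[str] = field(default_factory=list)
    boundary: bool = False
    n_fixed: int = 0
    n_obs: int = 0

    @property
    def h2(self) -> float:
        """Narrow-sense heritability on the K scale."""
        return self.sigma_a2 / (self.sigma_a2 + self.sigma_e2)


def _drop_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Keep a maximal linearly independent column subset (pivoted QR)."""
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    if rank < X.shape[1]:
        dropped = [names[j] for j in sorted(set(range(X.shape[1])) - set(keep))]
        logger.warning("dropping collinear design columns: %s", dropped)
    return X[:, keep], [names[j] for j in keep]


def _profiled_terms(lam, d, ys, Xs):
    """WLS pieces at variance ratio lam: beta, weighted RSS, log-dets."""
    w = 1.0 / (lam * d + 1.0)
    XtWX = Xs.T @ (w[:, None] * Xs)
    XtWy = Xs.T @ (w * ys)
    beta = np.linalg.solve(XtWX, XtWy)
    r = ys - Xs @ beta
    rss = float(np.sum(w * r * r))
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^{-1}X not positive definite")
    return beta, rss, float(np.sum(np.log(lam * d + 1.0))), logdet_XtWX, XtWX


def reml_loglik(lam: float, d: np.ndarray, ys: np.ndarray, Xs: np.ndarray) -> float:
    """Profiled restricted log-likelihood at variance ratio ``lam``.

    Uses the Patterson-Thompson form
    l_R = -1/2 [ log|V| + log|X'V^{-1}X| + y'Py + (n-p) log 2 pi ]
    with sigma_e^2 profiled out as RSS/(n-p).
    """
    n, p = Xs.shape
    _, rss, logdet_V0, logdet_XtWX, _ = _profiled_terms(lam, d, ys, Xs)
    s2 = rss / (n - p)
    return -0.5 * (
        (n - p) * np.log(s2)
        + logdet_V0
        + logdet_XtWX
        + (n - p)
        + (n - p) * _LOG2PI
    )


def ml_loglik(lam: float, d: np.ndarray, ys: np.ndarray, Xs: np.ndarray) -> float:
    """Profiled (over beta and sigma_e^2) maximum log-likelihood at ``lam``."""
    n, _ = Xs.shape
    _, rss, logdet_V0, _, _ = _profiled_terms(lam, d, ys, Xs)
    s2 = rss / n
    return -0.5 * (n * np.log(s2) + logdet_V0 + n + n * _LOG2PI)


def loglik_at(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    sigma_a2: float,
    sigma_e2: float,
    Z: np.ndarray | None = None,
    reml: bool = True,
) -> float:
    """Restricted (or full, with GLS beta) log-likelihood at fixed variance
    components, evaluated through the eigendecomposition path."""
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    Z = Z if Z is not None else np.eye(n)
    H = Z @ K @ Z.T
    d, U = np.linalg.eigh((H + H.T) / 2.0)
    d = np.clip(d, 0.0, None)
    ys, Xs = U.T @ y, U.T @ X
    v = sigma_a2 * d + sigma_e2  # eigenvalues of V
    Xw = Xs / v[:, None]
    XtVinvX = Xs.T @ Xw
    beta = np.linalg.solve(XtVinvX, Xw.T @ ys)
    r = ys - Xs @ beta
    quad = float(np.sum(r * r / v))
    logdetV = float(np.sum(np.log(v)))
    if reml:
        sign, logdet_XtVinvX = np.linalg.slogdet(XtVinvX)
        return -0.5 * (logdetV + logdet_XtVinvX + quad + (n - p) * _LOG2PI)
    return -0.5 * (logdetV + quad + n * _LOG2PI)


def _optimize_ratio(obj, lo=1e-6, hi=1e6, n_grid=51) -> float:
    """Maximise ``obj`` over the ratio, log-grid then Brent; 0 allowed."""
    grid = np.concatenate([[0.0], np.logspace(np.log10(lo), np.log10(hi), n_grid)])
    vals = np.array([obj(l) for l in grid])
    k = int(np.argmax(vals))
    if k == 0:
        # check boundary against the smallest interior point
        if vals[0] >= vals[1]:
            return 0.0
        k = 1
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, len(grid) - 1)]
    if a == 0.0:
        a = lo * 1e-3
    res = optimize.minimize_scalar(
        lambda t: -obj(np.exp(t)), bounds=(np.log(a), np.log(b)), method="bounded",
        options={"xatol": 1e-10},
    )
    lam = float(np.exp(res.x))
    return lam if obj(lam) >= vals[k] else float(grid[k])


def fit_lmm(spec: MixedModelSpec) -> MixedModelFit:
    """REML fit of the single-random-effect mixed model.

    Returns fixed-effect solutions with GLS standard errors, variance
    components, BLUPs of the random effect, residuals
    y - X beta - Z a_hat, and both REML and ML log-likelihoods (the latter
    maximised separately for AIC).
    """
    y = np.asarray(spec.y, dtype=float)
    X = np.atleast_2d(np.asarray(spec.X, dtype=float))
    n = y.size
    names = spec.x_names or [f"x{j}" for j in range(X.shape[1])]
    X, names = _drop_collinear(X, list(names))
    p = X.shape[1]
    if n < p + 2:
        raise ValueError(f"need n >= p + 2 observations, got n={n}, p={p}")
    Z = spec.Z if spec.Z is not None else np.eye(n)
    K = np.asarray(spec.K, dtype=float)
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("K must be symmetric")
    H = Z @ K @ Z.T
    d, U = np.linalg.eigh((H + H.T) / 2.0)
    if d.min() < -1e-6 * max(1.0, d.max()):
        raise ValueError(f"K is not PSD within tolerance (min eigenvalue {d.min():.3g})")
    d = np.clip(d, 0.0, None)
    ys = U.T @ y
    Xs = U.T @ X

    lam = _optimize_ratio(lambda l: reml_loglik(l, d, ys, Xs))
    boundary = lam == 0.0
    beta, rss, _, _, XtWX = _profiled_terms(lam, d, ys, Xs)
    sigma_e2 = rss / (n - p)
    sigma_a2 = lam * sigma_e2
    beta_cov = sigma_e2 * np.linalg.inv(XtWX)
    beta_se = np.sqrt(np.diag(beta_cov))
    logL_reml = reml_loglik(lam, d, ys, Xs)

    lam_ml = _optimize_ratio(lambda l: ml_loglik(l, d, ys, Xs))
    logL_ml = ml_loglik(lam_ml, d, ys, Xs)
    n_params = p + 2  # fixed effects + two variance components
    aic = -2.0 * logL_ml + 2.0 * n_params

    # BLUP: a_hat = sigma_a^2 K Z' V^{-1} (y - X beta); V^{-1} = U W U' / sigma_e^2
    resid_fixed = y - X @ beta
    w = 1.0 / (lam * d + 1.0)
    vinv_r = U @ (w * (U.T @ resid_fixed))  # (lam H + I)^{-1} r
    blup = lam * (K @ (Z.T @ vinv_r))
    residuals = resid_fixed - Z @ blup

    return MixedModelFit(
        beta=beta,
        beta_se=beta_se,
        sigma_a2=float(sigma_a2),
        sigma_e2=float(sigma_e2),
        blup=blup,
        residuals=residuals,
        logL_reml=float(logL_reml),
        logL_ml=float(logL_ml),
        aic=float(aic),
        x_names=names,
        boundary=boundary,
        n_fixed=p,
        n_obs=n,
    )


def model_aic(fit: MixedModelFit) -> float:
    """AIC = -2 logL_ML + 2 (n_fixed + n_varcomp)."""
    return fit.aic


def vif(X_cov: np.ndarray, names: list[str] | None = None) -> pd.Series:
    """Variance inflation factor 1/(1 - R^2_j) per covariate column.

    Perfect collinearity is reported as ``inf``.  Columns are centered, so
    an intercept need not be included.
    """
    X = np.atleast_2d(np.asarray(X_cov, dtype=float))
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two covariates")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("VIF undefined for a constant covariate")
    Xc = X - X.mean(axis=0)
    out = []
    for j in range(X.shape[1]):
        others = np.delete(Xc, j, axis=1)
        coef, res, rank, _ = np.linalg.lstsq(others, Xc[:, j], rcond=None)
        sst = float(Xc[:, j] @ Xc[:, j])
        pred = others @ coef
        ssr = float(((Xc[:, j] - pred) ** 2).sum())
        r2 = 1.0 - ssr / sst
        out.append(np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2))
    idx = names or [f"x{j}" for j in range(X.shape[1])]
    return pd.Series(out, index=idx, name="vif")


_FACTORS = ("dam_parity", "birth_herd", "twin", "rec_loss_class", "contemporary_group")


def design_from_phenotypes(
    records: list[PhenotypeRecord],
    factors: tuple[str, ...] = _FACTORS,
    min_level_count: int = 2,
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Response vector and fixed-effects design from phenotype records.

    Returns (y, X, column names, animal ids).  Factors become treatment
    dummies against the first observed level; levels with fewer than
    ``min_level_count`` observations are merged into the reference level
    with a warning.
    """
    df = pd.DataFrame(
        [
            {
                "animal_id": r.animal_id,
                "trait_value": r.trait_value,
                "dam_parity": str(r.dam_parity),
                "birth_herd": r.birth_herd,
                "twin": str(r.twin),
                "rec_loss_class": str(r.rec_loss_class),
                "contemporary_group": r.contemporary_group,
            }
            for r in records
        ]
    )
    y = df["trait_value"].to_numpy(dtype=float)
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for f in factors:
        levels = df[f].value_counts()
        rare = set(levels[levels < min_level_count].index)
        if rare:
            logger.warning("factor %s: merging rare levels %s into reference", f, sorted(rare))
        vals = df[f].where(~df[f].isin(rare), other="_ref")
        uniq = [l for l in pd.unique(vals) if l != "_ref"]
        for lev in uniq[1:] if "_ref" not in set(vals) else uniq:
            cols.append((vals == lev).to_numpy(dtype=float))
            names.append(f"{f}[{lev}]")
    X = np.column_stack(cols)
    return y, X, names, list(df["animal_id"])


def het_association(
    records: list[PhenotypeRecord],
    covariates: pd.DataFrame,
    pedmodel,
    measures: list[str],
    covariate_sds: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Association between heterozygosity measures and a trait (model with
    pedigree kinship and genetic-group means).

    ``covariates`` is an animal-indexed DataFrame holding the candidate
    regressors (e.g. columns het, oh, hl, rohet_count); ``measures`` names
    the combination to fit simultaneously.  OH and HL together are refused
    on collinearity grounds (their VIF blows up: both track the same
    genome-wide heterozygosity).  Returns one row per fitted measure with
    the solution, its SE, a t-based p-value, the VIF, and — when
    ``covariate_sds`` is given — the per-SD-scaled coefficient.
    """
    if {"oh", "hl"} <= {m.lower() for m in measures}:
        raise ValueError("OH and HL cannot be fitted together: collinear measures")
    y, X, names, animals = design_from_phenotypes(records)
    C = covariates.loc[animals, measures].to_numpy(dtype=float)
    if np.any(np.ptp(C, axis=0) == 0):
        raise ValueError("zero-variance heterozygosity covariate")
    vifs = vif(C, measures) if len(measures) >= 2 else pd.Series([1.0], index=measures)
    # genetic-group means as fixed covariates (drop one: rows of Q sum to 1)
    aidx = [pedmodel.animals.index(a) for a in animals]
    Q = pedmodel.Q[aidx][:, 1:]
    qnames = [f"group[{g}]" for g in pedmodel.group_labels[1:]]
    Xfull = np.column_stack([X, Q, C])
    K = pedmodel.A[np.ix_(aidx, aidx)]
    fit = fit_lmm(
        MixedModelSpec(y=y, X=Xfull, K=K, x_names=names + qnames + list(measures))
    )
    rows = []
    dof = fit.n_obs - fit.n_fixed
    for m in measures:
        j = fit.x_names.index(m)
        b, se = fit.beta[j], fit.beta_se[j]
        t = b / se
        rows.append(
            {
                "measure": m,
                "coefficient": b,
                "se": se,
                "p_value": 2.0 * stats.t.sf(abs(t), dof),
                "vif": float(vifs[m]),
                "coefficient_per_sd": b * covariate_sds[m] if covariate_sds else np.nan,
                "aic": fit.aic,
            }
        )
    return pd.DataFrame(rows)
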