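"""Per-variant association testing.

The quantitative GWAS regresses the average phenylephrine infusion rate on
each variant's additive dosage plus covariates by ordinary least squares;
per-variant effects are computed after residualizing the phenotype and the
dosages on the covariate design (Frisch-Waugh-Lovell), which is exact OLS
for complete data and falls back to a per-variant fit when a variant has
missing dosages. Subgroup validation uses logistic regression (IRLS via
statsmodels) of resistant-vs-sensitive or resistant-vs-pooled status.
Interaction models add a SNP x modifier product term and report the
interaction coefficient.

Conventions: the effect allele is the VCF alt allele; tests are two-sided;
sex is coded F = 1, M = 0; models are complete-case with dropped counts
logged per variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from pressorgwas.genoqc import GenotypeMatrix

__all__ = [
    "AssocResult",
    "LogisticResult",
    "screen_covariates",
    "gwas_linear",
    "logistic_assoc",
    "interaction_test",
    "results_table",
    "encode_sex",
]


@dataclass(frozen=True)
class AssocResult:
    """One variant's linear association: beta is mcg/min per effect allele."""

    variant_id: str
    n: int
    effect_allele: str
    eaf: float
    beta: float
    se: float
    statistic: float
    p: float
    status: str = "ok"  # ok | monomorphic | collinear | not_converged


@dataclass(frozen=True)
class LogisticResult:
    variant_id: str
    n_case: int
    n_control: int
    odds_ratio: float
    ci95: tuple[float, float]
    log_or: float
    se: float
    p: float
    status: str = "ok"


def encode_sex(sex) -> np.ndarray:
    """F = 1, M = 0 (female-protective orientation for resistant status)."""
    return (np.asarray(sex) == "F").astype(float)


# ---------------------------------------------------------------------------
# Covariate screening
# ---------------------------------------------------------------------------


def screen_covariates(
    y: np.ndarray,
    candidates: pd.DataFrame,
    categorical: tuple[str, ...] = ("anesthesia_type",),
    alpha: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Single multivariable OLS of the phenotype on all candidate covariates.

    Numeric candidates are retained when their Wald P < alpha; each
    categorical candidate enters as an indicator set and is retained jointly
    by an F-test on the set. Collinear candidates are reported with status
    ``collinear`` rather than silently dropped.

    Returns (selected column names, per-covariate table with beta/se/p).
    """
    y = np.asarray(y, dtype=float)
    X_parts: list[pd.DataFrame] = []
    groups: dict[str, list[str]] = {}
    for col in candidates.columns:
        if col in categorical:
            dummies = pd.get_dummies(
                candidates[col], prefix=col, drop_first=True, dtype=float
            )
            X_parts.append(dummies)
            groups[col] = list(dummies.columns)
        else:
            X_parts.append(candidates[[col]].astype(float))
            groups[col] = [col]
    if not X_parts:
        table = pd.DataFrame(columns=["covariate", "beta", "se", "p", "status"])
        return [], table
    X = pd.concat(X_parts, axis=1)
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    rank = np.linalg.matrix_rank(design)
    fit = sm.OLS(y, design).fit()
    colnames = ["const"] + list(X.columns)

    rows = []
    selected: list[str] = []
    for cov, members in groups.items():
        idx = [colnames.index(m) for m in members]
        collinear = rank < design.shape[1]
        if len(members) == 1:
            beta, se = fit.params[idx[0]], fit.bse[idx[0]]
            p = fit.pvalues[idx[0]]
        else:
            contrast = np.zeros((len(idx), design.shape[1]))
            for r, j in enumerate(idx):
                contrast[r, j] = 1.0
            p = float(fit.f_test(contrast).pvalue)
            beta, se = np.nan, np.nan
        status = "collinear" if collinear and not np.isfinite(p) else "ok"
        rows.append(
            {"covariate": cov, "beta": beta, "se": se, "p": p, "status": status}
        )
        if np.isfinite(p) and p < alpha:
            selected.append(cov)
    return selected, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Linear GWAS
# ---------------------------------------------------------------------------


def _covariate_design(covariates: pd.DataFrame | np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = (
        covariates.to_numpy(dtype=float)
        if isinstance(covariates, pd.DataFrame)
        else np.asarray(covariates, dtype=float)
    )
    if C.ndim == 1:
        C = C[:, None]
    return np.column_stack([np.ones(len(C)), C])


def gwas_linear(
    gm: GenotypeMatrix,
    y: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> list[AssocResult]:
    """Additive linear GWAS: per variant, OLS of y on [1, dosage, covariates].

    Reports beta, SE, and the two-sided t-test P for the dosage term.
    Samples with a missing dosage are dropped for that variant only.
    Monomorphic and covariate-collinear variants are flagged in ``status``
    instead of raising.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    n = len(y)
    if n != gm.n_samples:
        raise ValueError("phenotype length does not match sample count")
    X = _covariate_design(covariates, n)
    p_cov = X.shape[1]
    if n <= p_cov + 1:
        raise ValueError(f"design underdetermined: n={n}, covariates={p_cov}")
    if np.linalg.matrix_rank(X) < p_cov:
        raise ValueError("covariate matrix is rank-deficient")

    # Frisch-Waugh-Lovell: residualize y and all complete-dosage columns once
    Q, _ = np.linalg.qr(X)
    ry = y - Q @ (Q.T @ y)
    G = gm.dosages
    complete = ~np.isnan(G).any(axis=0)
    RG = np.empty_like(G)
    RG[:, complete] = G[:, complete] - Q @ (Q.T @ G[:, complete])

    eaf = gm.allele_freq()
    alts = gm.variants["alt"].to_numpy()
    ids = gm.variants["id"].to_numpy()
    df = n - p_cov - 1
    results: list[AssocResult] = []
    ryy = float(ry @ ry)
    for j in range(gm.n_variants):
        if complete[j]:
            g = G[:, j]
            if np.nanstd(g) == 0:
                results.append(
                    AssocResult(ids[j], n, alts[j], eaf[j], np.nan, np.nan, np.nan, np.nan, "monomorphic")
                )
                continue
            rg = RG[:, j]
            gg = float(rg @ rg)
            if gg <= 1e-12 * n:
                results.append(
                    AssocResult(ids[j], n, alts[j], eaf[j], np.nan, np.nan, np.nan, np.nan, "collinear")
                )
                continue
            beta = float(rg @ ry) / gg
            rss = ryy - beta * beta * gg
            sigma2 = max(rss, 0.0) / df
            se = np.sqrt(sigma2 / gg)
            results.append(_t_result(ids[j], n, alts[j], eaf[j], beta, se, df))
        else:
            results.append(
                _fit_incomplete(ids[j], alts[j], G[:, j], y, X)
            )
    return results


def _t_result(vid, n, allele, eaf, beta, se, df) -> AssocResult:
    if se == 0:
        return AssocResult(vid, n, allele, eaf, beta, se, np.inf, 0.0, "ok")
    t = beta / se
    p = 2 * stats.t.sf(abs(t), df)
    return AssocResult(vid, n, allele, float(eaf), beta, float(se), float(t), float(p), "ok")


def _fit_incomplete(vid, allele, g, y, X) -> AssocResult:
    keep = ~np.isnan(g)
    n = int(keep.sum())
    if n <= X.shape[1] + 1:
        return AssocResult(vid, n, allele, np.nan, np.nan, np.nan, np.nan, np.nan, "collinear")
    gk, yk, Xk = g[keep], y[keep], X[keep]
    eaf = gk.mean() / 2
    if gk.std() == 0:
        return AssocResult(vid, n, allele, eaf, np.nan, np.nan, np.nan, np.nan, "monomorphic")
    design = np.column_stack([Xk, gk])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        return AssocResult(vid, n, allele, eaf, np.nan, np.nan, np.nan, np.nan, "collinear")
    beta_hat, rss, *_ = np.linalg.lstsq(design, yk, rcond=None)
    resid = yk - design @ beta_hat
    df = n - design.shape[1]
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(design.T @ design)
    se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
    return _t_result(vid, n, allele, eaf, float(beta_hat[-1]), se, df)


# ---------------------------------------------------------------------------
# Logistic subgroup association
# ---------------------------------------------------------------------------


def _logit_fit(design: np.ndarray, status: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(status, design)
        return model.fit(disp=0, maxiter=50, tol=1e-8)


def logistic_assoc(
    gm: GenotypeMatrix,
    status: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    variant_ids: list[str] | None = None,
) -> list[LogisticResult]:
    """Per-variant logistic regression of case status on dosage + covariates.

    ``status`` is 0/1 with cases (resistant) coded 1. Reports Wald OR, 95%
    CI, and two-sided P for the dosage term; quasi-separated or
    non-converging fits get status ``not_converged``.
    """
    status = np.asarray(status, dtype=float)
    if set(np.unique(status)) - {0.0, 1.0}:
        raise ValueError("status must be coded 0/1")
    if len(np.unique(status)) < 2:
        raise ValueError("both classes must be present")
    X = _covariate_design(covariates, len(status))
    if variant_ids is None:
        variant_ids = list(gm.variants["id"])
    n_case = int(status.sum())
    n_control = int(len(status) - n_case)
    out: list[LogisticResult] = []
    for vid in variant_ids:
        g = gm.column(vid)
        keep = ~np.isnan(g)
        gk, sk, Xk = g[keep], status[keep], X[keep]
        if gk.std() == 0:
            out.append(
                LogisticResult(vid, n_case, n_control, np.nan, (np.nan, np.nan), np.nan, np.nan, np.nan, "monomorphic")
            )
            continue
        design = np.column_stack([Xk, gk])
        try:
            fit = _logit_fit(design, sk)
            if not fit.mle_retvals.get("converged", False):
                raise RuntimeError("IRLS did not converge")
            log_or = float(fit.params[-1])
            se = float(fit.bse[-1])
            if not np.isfinite(se) or se > 50:
                raise RuntimeError("quasi-separation (unbounded SE)")
            z = log_or / se
            p = 2 * stats.norm.sf(abs(z))
            ci = (np.exp(log_or - 1.959964 * se), np.exp(log_or + 1.959964 * se))
            out.append(
                LogisticResult(vid, n_case, n_control, float(np.exp(log_or)), ci, log_or, se, float(p), "ok")
            )
        except (RuntimeError, np.linalg.LinAlgError, ValueError):
            out.append(
                LogisticResult(vid, n_case, n_control, np.nan, (np.nan, np.nan), np.nan, np.nan, np.nan, "not_converged")
            )
    return out


# ---------------------------------------------------------------------------
# Interaction models
# ---------------------------------------------------------------------------


def interaction_test(
    gm: GenotypeMatrix,
    outcome: np.ndarray,
    modifier: np.ndarray,
    variant_ids: list[str] | None = None,
    binary: bool = False,
) -> pd.DataFrame:
    """SNP x modifier interaction: fit outcome ~ SNP + modifier + SNP*modifier.

    The reported row per variant is the *interaction* coefficient (beta for a
    quantitative outcome, log-OR for a binary one) with its SE and two-sided
    P. The main-effect parameterization shifts when the modifier is centered
    but the interaction coefficient does not.
    """
    outcome = np.asarray(outcome, dtype=float)
    modifier = np.asarray(modifier, dtype=float)
    if variant_ids is None:
        variant_ids = list(gm.variants["id"])
    rows = []
    for vid in variant_ids:
        g = gm.column(vid)
        keep = ~np.isnan(g) & np.isfinite(outcome) & np.isfinite(modifier)
        gk, yk, mk = g[keep], outcome[keep], modifier[keep]
        design = np.column_stack([np.ones(len(gk)), gk, mk, gk * mk])
        try:
            if binary:
                fit = _logit_fit(design, yk)
                coef, se = float(fit.params[-1]), float(fit.bse[-1])
                p = 2 * stats.norm.sf(abs(coef / se))
            else:
                fit = sm.OLS(yk, design).fit()
                coef, se = float(fit.params[-1]), float(fit.bse[-1])
                p = float(fit.pvalues[-1])
            status = "ok"
        except (np.linalg.LinAlgError, ValueError, RuntimeError):
            coef = se = p = np.nan
            status = "not_converged"
        rows.append(
            {"variant_id": vid, "interaction_coef": coef, "se": se, "p": p, "status": status}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Summary-statistics table
# ---------------------------------------------------------------------------


def results_table(results: list[AssocResult], gm: GenotypeMatrix) -> pd.DataFrame:
    """Summary statistics, one row per variant, consumable by the meta module."""
    meta = gm.variants.set_index("id")
    rows = []
    for r in results:
        v = meta.loc[r.variant_id]
        rows.append(
            {
                "id": r.variant_id,
                "chrom": v["chrom"],
                "pos": int(v["pos"]),
                "effect_allele": r.effect_allele,
                "other_allele": v["ref"],
                "eaf": r.eaf,
                "n": r.n,
                "beta": r.beta,
                "se": r.se,
                "stat": r.statistic,
                "p": r.p,
                "status": r.status,
            }
        )
    return pd.DataFrame(rows)
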