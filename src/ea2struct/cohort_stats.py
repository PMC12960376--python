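"""Cohort statistics: correlations, BH-FDR, random-intercept mixed models.

These are the analyses run on the per-patient table (structure metrics
against Wechsler indices): Pearson correlation with Fisher-z 95% CI for the
normally-treated predictor (TM-score), Spearman rank correlation otherwise
(AA%), Benjamini–Hochberg FDR adjustment pooled across the correlation
family, variance inflation factors, mean ± SD summaries, and linear mixed
models with a family random intercept.

The mixed model is fitted by profiling the variance ratio
λ = σ²_family / σ²_residual (closed-form GLS at each λ) under ML or REML.
Inference on the fixed effects uses t statistics with Satterthwaite
degrees of freedom, computed from finite differences of the coefficient
variance and the curvature of the deviance in the two variance components
— the lme4/lmerTest recipe.  ML with Satterthwaite intervals is the
default because it is the convention the reference results follow.

Important scale note: Spearman and the mixed models must see the
*unrounded* AA fraction.  The 1-decimal display AA% creates spurious rank
ties (82.1 appears four times) that visibly change ρ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "LmmResult",
    "SummaryRow",
    "pearson",
    "spearman",
    "bh_fdr",
    "fit_lmm_random_intercept",
    "vif_two_predictors",
    "summarize",
    "load_ea2_cohort",
    "COGNITIVE_INDICES",
    "ZeroVarianceError",
]

COGNITIVE_INDICES = ("FSIQ", "VCI", "PRI", "WMI", "PSI")


class ZeroVarianceError(ValueError):
    """An input vector is constant."""


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "pearson" | "spearman"
    r: float
    p: float
    ci95: tuple[float, float] | None
    p_fdr: float | None = None
    n: int = 0


@dataclass(frozen=True)
class LmmResult:
    term: str
    beta: float
    se: float
    ci95: tuple[float, float]
    p: float
    df: float
    var_family: float
    var_resid: float
    converged: bool


@dataclass(frozen=True)
class SummaryRow:
    index_name: str
    mean: float
    sd: float


def _check_xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("inputs must be equal-length vectors with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("zero variance")
    return x, y


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation; two-sided t test p; Fisher-z 95% CI."""
    x, y = _check_xy(x, y)
    res = stats.pearsonr(x, y)
    lo, hi = res.confidence_interval(0.95)
    return CorrelationResult("pearson", float(res.statistic), float(res.pvalue),
                             (float(lo), float(hi)), n=x.size)


def spearman(x, y) -> CorrelationResult:
    """Rank correlation (mean ranks for ties); p via the t approximation."""
    x, y = _check_xy(x, y)
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult("spearman", float(rho), float(p), None, n=x.size)


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("invalid p-value")
    return multipletests(p, method="fdr_bh")[1]


def adjust_fdr(results: list[CorrelationResult]) -> list[CorrelationResult]:
    """Fill ``p_fdr`` across one pooled family of correlation results."""
    adj = bh_fdr([r.p for r in results])
    return [replace(r, p_fdr=float(q)) for r, q in zip(results, adj)]


def vif_two_predictors(x1, x2) -> float:
    """Variance inflation factor for a two-predictor design: 1/(1−r²)."""
    x1, x2 = _check_xy(x1, x2)
    r = float(stats.pearsonr(x1, x2).statistic)
    if abs(r) >= 1.0 - 1e-12:
        raise ValueError("perfect collinearity")
    return round(1.0 / (1.0 - r * r), 2)


def summarize(cohort: pd.DataFrame, columns=COGNITIVE_INDICES) -> list[SummaryRow]:
    """Mean ± SD per index, 1 decimal.  SD uses divisor n (population form),
    the convention that matches the reference summary values."""
    if cohort.empty:
        raise ValueError("empty cohort")
    rows = []
    for col in columns:
        vals = cohort[col].to_numpy(dtype=float)
        rows.append(SummaryRow(col, round(float(vals.mean()), 1),
                               round(float(vals.std(ddof=0)), 1)))
    return rows


# ---------------------------------------------------------------------------
# Random-intercept linear mixed model
# ---------------------------------------------------------------------------

class _RISummaries:
    """Per-group sufficient statistics for the random-intercept model.

    With V0 = I + λ ZZ' block-diagonal by group, Woodbury gives
    V0_g⁻¹ = I − w_g 11' with w_g = λ/(1 + λ m_g), so every GLS quantity
    is a weighted combination of per-group cross-products — O(n p²)
    regardless of cohort size.
    """

    def __init__(self, X, y, groups):
        codes, _ = pd.factorize(np.asarray(groups))
        m = int(codes.max()) + 1
        n, p = X.shape
        self.n, self.p, self.m = n, p, m
        self.sizes = np.bincount(codes).astype(float)
        self.S = np.zeros((m, p))  # per-group column sums of X
        self.U = np.zeros(m)  # per-group sums of y
        np.add.at(self.S, codes, X)
        np.add.at(self.U, codes, y)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)


def _gls(summ: _RISummaries, lam: float):
    """GLS at variance ratio λ: returns (β, q, log|V0|, log|A|, A)."""
    w = lam / (1.0 + lam * summ.sizes)
    A = summ.XtX - (summ.S * w[:, None]).T @ summ.S
    c = summ.Xty - summ.S.T @ (w * summ.U)
    d = summ.yty - float(w @ (summ.U * summ.U))
    beta = np.linalg.solve(A, c)
    q = max(d - float(c @ beta), 1e-300)
    logdetV0 = float(np.log1p(lam * summ.sizes).sum())
    _, logdetA = np.linalg.slogdet(A)
    return beta, q, logdetV0, logdetA, A


def _profiled_deviance(log_lam, summ, reml):
    lam = math.exp(log_lam)
    _, q, logdetV0, logdetA0, _ = _gls(summ, lam)
    if reml:
        return (summ.n - summ.p) * math.log(q) + logdetV0 + logdetA0
    return summ.n * math.log(q) + logdetV0


def _fd_gradient(f, u):
    h = np.array([max(1e-7, 1e-5 * abs(u[i])) for i in range(len(u))])
    g = np.zeros(len(u))
    for i in range(len(u)):
        e = np.zeros(len(u))
        e[i] = h[i]
        g[i] = (f(u + e) - f(u - e)) / (2 * h[i])
    return g


def _fd_hessian(f, u):
    h = np.array([max(1e-6, 1e-4 * abs(u[i])) for i in range(len(u))])
    H = np.zeros((len(u), len(u)))
    f0 = f(u)
    for i in range(len(u)):
        ei = np.zeros(len(u))
        ei[i] = h[i]
        H[i, i] = (f(u + ei) - 2 * f0 + f(u - ei)) / h[i] ** 2
        for j in range(i + 1, len(u)):
            ej = np.zeros(len(u))
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(u + ei + ej) - f(u + ei - ej) - f(u - ei + ej) + f(u - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def _satterthwaite_df(summ, theta, sigma, j, reml):
    """Degrees of freedom for fixed effect j by the Satterthwaite method.

    Works on the (θ, σ) scale — θ the ratio of family to residual SD, σ
    the residual SD — where the deviance is smooth and even in θ, so the
    σ²_family = 0 boundary needs no one-sided treatment.  The variance of
    the variance-parameter estimates is 2 H⁻¹ with H the deviance Hessian.
    """
    n, p = summ.n, summ.p

    def dev(u):
        th, sg = u
        sg2 = sg * sg
        _, q, logdetV0, logdetA0, _ = _gls(summ, th * th)
        d = n * math.log(sg2) + logdetV0 + q / sg2
        if reml:
            d += logdetA0 - p * math.log(sg2)
        return d

    def f_var(u):
        th, sg = u
        _, _, _, _, A = _gls(summ, th * th)
        return float(sg * sg * np.linalg.inv(A)[j, j])

    u0 = np.array([theta, sigma])
    H = _fd_hessian(dev, u0)
    try:
        cov_u = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    g = _fd_gradient(f_var, u0)
    denom = float(g @ cov_u @ g)
    if denom <= 0:
        return None
    return 2.0 * f_var(u0) ** 2 / denom


def fit_lmm_random_intercept(
    y,
    x,
    groups,
    method: str = "ml",
    add_intercept: bool = True,
    term_names=None,
    satterthwaite: bool = True,
) -> list[LmmResult]:
    """Fit y = Xβ + (1|group) + ε and return inference per fixed effect.

    Parameters
    ----------
    y, x, groups
        Outcome vector, predictor vector or (n, k) matrix (without the
        intercept column), and group labels for the random intercept.
    method
        "ml" (default) or "reml".  The variance ratio is profiled by 1-D
        optimization with closed-form GLS at each ratio; a zero family
        variance is handled by clamping to the boundary.
    satterthwaite
        When False, skip the Satterthwaite computation and use residual
        degrees of freedom n − p (cheap; for bulk simulation).

    Returns one :class:`LmmResult` per predictor column (intercept
    excluded), with Satterthwaite-df t-based p-values and 95% CIs.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(x, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if add_intercept:
        X = np.column_stack([np.ones(n), X])
    if term_names is None:
        term_names = [f"x{i + 1}" for i in range(k)]
    if n < X.shape[1] + 2:
        raise ValueError("too few observations for the fixed-effect design")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear fixed effects")
    reml = method.lower() == "reml"
    p = X.shape[1]
    summ = _RISummaries(X, y, groups)

    opt = optimize.minimize_scalar(
        _profiled_deviance, bounds=(-16.0, 16.0), args=(summ, reml),
        method="bounded", options={"xatol": 1e-10},
    )
    converged = bool(opt.success)
    lam = math.exp(opt.x)
    # prefer the boundary when it is as good as the interior optimum
    _, q0, _, logdetA0, _ = _gls(summ, 0.0)
    dev_zero = ((n - p) * math.log(q0) + logdetA0) if reml else n * math.log(q0)
    # the criterion is flat in λ when groups are uninformative; a boundary
    # fit that matches the interior optimum to numerical noise wins
    if dev_zero <= opt.fun + 1e-6 * max(1.0, abs(opt.fun)) or lam < 1e-7:
        lam = 0.0

    beta, q, _, _, A = _gls(summ, lam)
    se2 = q / (n - p) if reml else q / n
    sf2 = lam * se2
    cov_beta = se2 * np.linalg.inv(A)

    theta_ratio = math.sqrt(lam)
    sigma = math.sqrt(se2)
    results = []
    for j in range(1 if add_intercept else 0, p):
        b = float(beta[j])
        se = float(math.sqrt(cov_beta[j, j]))
        df_j = (_satterthwaite_df(summ, theta_ratio, sigma, j, reml)
                if satterthwaite else None)
        df = float(min(max(df_j, 1.0), 10 * n)) if df_j is not None else float(n - p)
        tval = b / se
        pv = 2.0 * stats.t.sf(abs(tval), df)
        tc = stats.t.ppf(0.975, df)
        results.append(LmmResult(
            term=term_names[j - 1 if add_intercept else j],
            beta=b, se=se, ci95=(b - tc * se, b + tc * se), p=float(pv),
            df=df, var_family=float(sf2), var_resid=float(se2),
            converged=converged,
        ))
    return results


# ---------------------------------------------------------------------------
# Packaged cohort fixture
# ---------------------------------------------------------------------------

def load_ea2_cohort() -> pd.DataFrame:
    """The 13-patient EA2 cohort table packaged with the library.

    Columns: patient_id, family_id, the five Wechsler indices, tm_score,
    hgvs_c/hgvs_p, predicted protein length and wild-type length; plus the
    derived ``aa_raw`` (unrounded percent), ``aa_fraction`` (0-1, the mixed
    -model predictor scale) and ``aa_percent`` (1-decimal display value).
    """
    from .variant_engine import aa_percent

    with resources.files("ea2struct").joinpath("data/ea2_cohort.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["aa_raw"] = 100.0 * df["predicted_length"] / df["wildtype_length"]
    df["aa_fraction"] = df["predicted_length"] / df["wildtype_length"]
    df["aa_percent"] = [
        aa_percent(int(l), int(w))
        for l, w in zip(df["predicted_length"], df["wildtype_length"])
    ]
    return df
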