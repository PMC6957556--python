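"""Inferential machinery: correlations, bootstrapped hierarchical regression
with BCa intervals, standardized betas, and Benjamini-Hochberg FDR.

The regression design enters predictors in ordered blocks (age first, then
the network measure of interest, then mean relative RMS motion, optionally
sex or education as a sensitivity block) and reports the coefficients of the
final nested model. Uncertainty comes from a case-resampling bootstrap of
whole rows (default 2000 replicates): each coefficient gets a
bias-corrected and accelerated (BCa) 95% interval and an accompanying
P value (P_bca) defined by confidence-interval inversion — the smallest
alpha, on a grid of step 0.001 floored at 1/n_boot, at which the (1-alpha)
BCa interval excludes zero. Subnetwork P values are corrected per family
with the Benjamini-Hochberg step-up rule at q = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RegressionBlocks",
    "ModelFit",
    "CoefficientResult",
    "BootstrapRegressionResult",
    "MultipleTestingResult",
    "correlate",
    "hierarchical_fit",
    "bca_interval",
    "bootstrap_regression",
    "standardized_beta",
    "fdr_bh",
    "residualize_pair",
    "partial_correlation",
]


@dataclass
class RegressionBlocks:
    """Ordered predictor blocks for one outcome (hierarchical entry)."""

    outcome: str
    blocks: list[list[str]]

    def __post_init__(self) -> None:
        flat = [p for b in self.blocks for p in b]
        if len(flat) != len(set(flat)):
            raise ValueError("a predictor appears in more than one block")
        if not all(self.blocks):
            raise ValueError("blocks must be non-empty")

    def predictors_through(self, k: int) -> list[str]:
        return [p for b in self.blocks[: k + 1] for p in b]

    @property
    def all_predictors(self) -> list[str]:
        return self.predictors_through(len(self.blocks) - 1)


@dataclass
class ModelFit:
    predictors: list[str]
    coef: dict[str, float]          # includes "const"
    se: dict[str, float]
    beta: dict[str, float]          # standardized; not defined for the intercept
    r2: float
    n: int


@dataclass
class CoefficientResult:
    name: str
    b: float
    se: float
    beta: float
    ci_low: float
    ci_high: float
    p_bca: float
    p_at_floor: bool = False        # CI excluded 0 at the smallest grid alpha
    bca_clamped: bool = False       # degenerate z0 was clamped


@dataclass
class BootstrapRegressionResult:
    outcome: str
    models: list[ModelFit]
    coefficients: list[CoefficientResult]   # final-model, excluding intercept
    n_boot: int
    seed: int
    n: int

    def to_frame(self) -> pd.DataFrame:
        """Regression-table layout: B, SE, CI bounds, beta, P_bca, model R^2."""
        rows = []
        for c in self.coefficients:
            rows.append(
                {
                    "outcome": self.outcome,
                    "predictor": c.name,
                    "B": c.b,
                    "SE": c.se,
                    "CI_low": c.ci_low,
                    "CI_high": c.ci_high,
                    "Beta": c.beta,
                    "P_bca": c.p_bca,
                    "R2": self.models[-1].r2,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class MultipleTestingResult:
    raw: dict[str, float]
    adjusted: dict[str, float]
    reject: dict[str, bool]
    q: float


def correlate(x, y, method: str = "auto") -> tuple[float, float, str]:
    """Pearson or Spearman correlation with two-sided P.

    ``auto`` uses Spearman when either variable fails a Shapiro-Wilk
    normality check at alpha = 0.05, Pearson otherwise. Returns
    (coefficient, P, method_used).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need equal-length samples with n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for constant input")
    if method == "auto":
        normal = sps.shapiro(x).pvalue >= 0.05 and sps.shapiro(y).pvalue >= 0.05
        method = "pearson" if normal else "spearman"
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p), method


def _design(data: pd.DataFrame, outcome: str, predictors: list[str]):
    cols = [outcome] + predictors
    sub = data[cols].dropna()  # listwise deletion
    y = sub[outcome].to_numpy(float)
    X = np.column_stack([np.ones(len(sub))] + [sub[p].to_numpy(float) for p in predictors])
    return X, y, sub


def _ols(X: np.ndarray, y: np.ndarray):
    n, p = X.shape
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise np.linalg.LinAlgError("rank-deficient design")
    resid = y - X @ coef
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    sigma2 = rss / (n - p) if n > p else np.nan
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    return coef, se, r2


def hierarchical_fit(data: pd.DataFrame, blocks: RegressionBlocks) -> list[ModelFit]:
    """Sequence of nested OLS fits: block 1, blocks 1-2, blocks 1-3, ..."""
    fits = []
    for k in range(len(blocks.blocks)):
        predictors = blocks.predictors_through(k)
        X, y, sub = _design(data, blocks.outcome, predictors)
        if X.shape[0] <= X.shape[1]:
            raise ValueError("too few complete rows for the requested predictors")
        try:
            coef, se, r2 = _ols(X, y)
        except np.linalg.LinAlgError:
            corr = sub[predictors].corr().abs()
            np.fill_diagonal(corr.values, 0)
            worst = corr.stack().idxmax()
            raise ValueError(f"rank-deficient design; near-collinear columns {worst}")
        names = ["const"] + predictors
        y_sd = y.std(ddof=1)
        beta = {
            p: standardized_beta(coef[i + 1], sub[p].to_numpy(float).std(ddof=1), y_sd)
            for i, p in enumerate(predictors)
        }
        fits.append(
            ModelFit(
                predictors=predictors,
                coef=dict(zip(names, coef)),
                se=dict(zip(names, se)),
                beta=beta,
                r2=r2,
                n=X.shape[0],
            )
        )
    return fits


def standardized_beta(b: float, x_sd: float, y_sd: float) -> float:
    """beta = B * sd(x) / sd(y), on the original (non-bootstrap) sample."""
    if x_sd <= 0 or y_sd <= 0:
        raise ValueError("standard deviations must be positive")
    return float(b * x_sd / y_sd)


def bca_interval(
    point_estimate: float,
    bootstrap_replicates: np.ndarray,
    jackknife_estimates: np.ndarray,
    level: float = 0.95,
) -> tuple[float, float, dict]:
    """Bias-corrected and accelerated bootstrap interval.

    z0 is the normal quantile of the fraction of replicates below the point
    estimate; the acceleration a comes from the jackknife skewness. A fully
    one-sided replicate distribution makes z0 infinite; it is then clamped
    to the quantile of 1/(2B) (or its complement) and flagged in the
    diagnostics rather than hidden.
    """
    boots = np.asarray(bootstrap_replicates, float)
    if not np.isfinite(boots).all():
        raise ValueError("non-finite bootstrap replicates")
    if boots.std() == 0:
        raise ValueError("zero-variance bootstrap replicates")
    b = len(boots)
    frac = np.mean(boots < point_estimate) + 0.5 * np.mean(boots == point_estimate)
    clamped = False
    if frac <= 0 or frac >= 1:
        frac = np.clip(frac, 0.5 / b, 1 - 0.5 / b)
        clamped = True
    z0 = sps.norm.ppf(frac)
    jack = np.asarray(jackknife_estimates, float)
    d = jack.mean() - jack
    denom = (d**2).sum() ** 1.5
    a = float((d**3).sum() / (6.0 * denom)) if denom > 0 else 0.0
    alpha = 1.0 - level
    lo, hi = _bca_endpoints(boots, z0, a, np.array([alpha / 2.0]), np.array([1 - alpha / 2.0]))
    return float(lo[0]), float(hi[0]), {"z0": float(z0), "a": a, "clamped": clamped}


def _bca_endpoints(boots, z0, a, q_lo, q_hi):
    """Vectorized BCa endpoints for arrays of nominal quantile levels."""
    def adjust(q):
        z = sps.norm.ppf(q)
        arg = z0 + (z0 + z) / (1.0 - a * (z0 + z))
        return np.clip(sps.norm.cdf(arg), 0.0, 1.0)

    lo = np.quantile(boots, adjust(q_lo))
    hi = np.quantile(boots, adjust(q_hi))
    return lo, hi


def _p_by_ci_inversion(boots, z0, a, n_boot, step: float = 0.001):
    """Smallest alpha whose (1-alpha) BCa interval excludes zero."""
    floor = max(step, 1.0 / n_boot)
    alphas = np.arange(step, 1.0, step)
    lo, hi = _bca_endpoints(boots, z0, a, alphas / 2.0, 1.0 - alphas / 2.0)
    excludes = (lo > 0) | (hi < 0)
    if not excludes.any():
        return 1.0, False
    p = float(alphas[int(np.argmax(excludes))])
    if p < floor:
        return floor, True
    return p, p <= floor


def _batched_ols_coefs(X: np.ndarray, y: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, int]:
    """Coefficients for each resample given an index matrix (B, n).

    Returns (coefs (B, p), n_failed). Singular resamples are refit by
    pseudoinverse and counted as failures.
    """
    Xb = X[idx]                      # (B, n, p)
    yb = y[idx]                      # (B, n)
    G = np.einsum("bni,bnj->bij", Xb, Xb)
    h = np.einsum("bni,bn->bi", Xb, yb)
    n_failed = 0
    try:
        coefs = np.linalg.solve(G, h[..., None])[..., 0]
    except np.linalg.LinAlgError:
        coefs = np.empty((idx.shape[0], X.shape[1]))
        for i in range(idx.shape[0]):
            try:
                coefs[i] = np.linalg.solve(G[i], h[i][:, None])[:, 0]
            except np.linalg.LinAlgError:
                coefs[i] = np.linalg.lstsq(Xb[i], yb[i], rcond=None)[0]
                n_failed += 1
    return coefs, n_failed


def bootstrap_regression(
    data: pd.DataFrame,
    blocks: RegressionBlocks,
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
    alpha_step: float = 0.001,
) -> BootstrapRegressionResult:
    """Case-resampling bootstrap of the hierarchical regression.

    Whole rows are resampled with replacement ``n_boot`` times; the
    final-model coefficients get BCa intervals and inversion P values.
    Deterministic given ``seed``. Aborts if more than 1% of bootstrap
    designs are rank-deficient.
    """
    fits = hierarchical_fit(data, blocks)
    final = fits[-1]
    predictors = final.predictors
    X, y, sub = _design(data, blocks.outcome, predictors)
    n, p = X.shape

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boots, n_failed = _batched_ols_coefs(X, y, idx)
    if n_failed > 0.01 * n_boot:
        raise RuntimeError(
            f"{n_failed}/{n_boot} bootstrap designs rank-deficient; "
            "check predictor variance and sample size"
        )
    jack_idx = np.array([np.delete(np.arange(n), i) for i in range(n)])
    jacks, _ = _batched_ols_coefs(X, y, jack_idx)

    coefficients = []
    for j, name in enumerate(predictors):
        col = j + 1  # skip intercept
        theta = final.coef[name]
        lo, hi, diag = bca_interval(theta, boots[:, col], jacks[:, col], level=level)
        p_bca, at_floor = _p_by_ci_inversion(
            boots[:, col], diag["z0"], diag["a"], n_boot, step=alpha_step
        )
        coefficients.append(
            CoefficientResult(
                name=name,
                b=theta,
                se=final.se[name],
                beta=final.beta[name],
                ci_low=lo,
                ci_high=hi,
                p_bca=p_bca,
                p_at_floor=at_floor,
                bca_clamped=diag["clamped"],
            )
        )
    return BootstrapRegressionResult(
        outcome=blocks.outcome,
        models=fits,
        coefficients=coefficients,
        n_boot=n_boot,
        seed=seed,
        n=n,
    )


def fdr_bh(pvalues: dict[str, float], q: float = 0.05) -> MultipleTestingResult:
    """Benjamini-Hochberg step-up control of the false discovery rate."""
    labels = list(pvalues)
    raw = np.array([pvalues[k] for k in labels], float)
    if ((raw < 0) | (raw > 1)).any() or not np.isfinite(raw).all():
        raise ValueError("P values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(raw, alpha=q, method="fdr_bh")
    return MultipleTestingResult(
        raw=dict(zip(labels, raw)),
        adjusted=dict(zip(labels, adjusted)),
        reject=dict(zip(labels, reject)),
        q=q,
    )


def residualize_pair(y, x, covariates) -> tuple[np.ndarray, np.ndarray]:
    """Residuals of y and x after OLS on the covariates (with intercept).

    The Pearson correlation of the residuals is the partial correlation
    given the covariates (the quantity shown in partial-correlation plots).
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    Z = np.asarray(covariates, float)
    if Z.ndim == 1:
        Z = Z[:, None]
    Zc = np.column_stack([np.ones(len(y)), Z])
    coef_y, _, rank, _ = np.linalg.lstsq(Zc, y, rcond=None)
    if rank < Zc.shape[1]:
        raise ValueError("ill-conditioned covariate design")
    coef_x = np.linalg.lstsq(Zc, x, rcond=None)[0]
    return y - Zc @ coef_y, x - Zc @ coef_x


def partial_correlation(y, x, covariates) -> tuple[float, float]:
    """Partial Pearson correlation of y and x controlling for covariates."""
    ry, rx = residualize_pair(y, x, covariates)
    if ry.std() < 1e-12 * max(1.0, np.abs(np.asarray(y)).max()) or rx.std() == 0:
        raise ValueError("residual variance ~ 0: partial correlation undefined")
    r, p = sps.pearsonr(rx, ry)
    return float(r), float(p)
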