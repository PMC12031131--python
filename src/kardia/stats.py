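"""Nonparametric cohort statistics for HRV group studies.

The analysis recipe implemented here mirrors the common clinical-HRV
workflow: a Shapiro–Wilk normality gate, Mann–Whitney U for the group
contrast, per-group descriptives, Pearson/Spearman correlation matrices
with age partialed out, a strict significance filter, and post-hoc power
from the observed group means and SDs.

Conventions fixed for reproducibility:

* The reported U is ``min(U_x, U_y)`` with a two-tailed p; the exact p by
  full enumeration of labelings is used for ``n_x + n_y ≤ 20`` without
  ties, otherwise a tie- and continuity-corrected normal approximation.
* Partial Spearman correlations residualise the *ranked* variables (and
  ranked covariates) by least squares; p-values come from the
  t-transform with ``n − 2 − k`` degrees of freedom for k covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "Descriptives",
    "CorrelationReport",
    "descriptives",
    "shapiro_wilk",
    "mann_whitney_u",
    "correlation_matrix",
    "significance_filter",
    "posthoc_power",
]

EXACT_ENUMERATION_LIMIT = 20


@dataclass(frozen=True)
class Descriptives:
    """Summary statistics for one numeric sample (sample-SD conventions)."""

    n: int
    mean: float
    median: float
    sd: float
    se: float
    variance: float
    min: float
    max: float
    skewness: float
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return {
            "n": self.n, "mean": self.mean, "median": self.median,
            "sd": self.sd, "se": self.se, "variance": self.variance,
            "min": self.min, "max": self.max, "skewness": self.skewness,
        }


@dataclass
class CorrelationReport:
    """Correlation matrix with p-values, covariates and a significance mask."""

    method: str
    coefficients: pd.DataFrame
    p_values: pd.DataFrame
    covariates: list[str] = field(default_factory=list)
    alpha: float = 0.001

    @property
    def significant(self) -> pd.DataFrame:
        mask = significance_filter(self.p_values.to_numpy(), self.alpha)
        out = pd.DataFrame(mask, index=self.p_values.index,
                           columns=self.p_values.columns)
        np.fill_diagonal(out.values, False)
        return out


def descriptives(values: np.ndarray) -> Descriptives:
    """n, mean, median, SD, SE, variance, min, max, adjusted skewness.

    SD/variance use the N−1 denominator; se = sd/√n; skewness is the
    adjusted Fisher–Pearson coefficient (bias-corrected, as spreadsheet and
    JMP-style software report it).  A constant sample reports skewness 0
    with the ``degenerate`` flag set.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise ValueError(f"descriptives need n ≥ 2, got {n}")
    sd = float(np.std(x, ddof=1))
    degenerate = sd == 0.0
    if degenerate or n < 3:
        skew = 0.0
    else:
        skew = float(sps.skew(x, bias=False))
    return Descriptives(
        n=n,
        mean=float(np.mean(x)),
        median=float(np.median(x)),
        sd=sd,
        se=sd / float(np.sqrt(n)),
        variance=sd**2,
        min=float(np.min(x)),
        max=float(np.max(x)),
        skewness=skew,
        degenerate=degenerate,
    )


def shapiro_wilk(values: np.ndarray) -> tuple[float, float]:
    """Shapiro–Wilk W and p (3 ≤ n ≤ 5000; constant samples are an error)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 ≤ n ≤ 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk W is undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def _u_from_ranks(ranks_x: np.ndarray, n_x: int, n_y: int) -> float:
    return float(np.sum(ranks_x) - n_x * (n_x + 1) / 2.0)


def _exact_two_tailed_p(pooled: np.ndarray, n_x: int, u_obs_min: float) -> float:
    """Exact two-tailed p by full enumeration of the C(n, n_x) labelings."""
    n = pooled.size
    ranks = sps.rankdata(pooled)
    total = comb(n, n_x)
    n_y = n - n_x
    max_u = n_x * n_y
    count = 0
    idx = np.arange(n)
    for combo in combinations(idx, n_x):
        ux = _u_from_ranks(ranks[list(combo)], n_x, n_y)
        u_min = min(ux, max_u - ux)
        if u_min <= u_obs_min + 1e-12:
            # each labeling with min-U at least as extreme counts once;
            # min-U folding makes this inherently two-tailed
            count += 1
    return count / total


def mann_whitney_u(x: np.ndarray, y: np.ndarray,
                   mode: str = "auto") -> tuple[float, float]:
    """Mann–Whitney U (reported as min(U_x, U_y)) with two-tailed p.

    ``mode='exact'`` enumerates all labelings (ties not supported);
    ``'normal'`` uses the tie-corrected normal approximation with
    continuity correction; ``'auto'`` picks exact when
    ``n_x + n_y ≤ 20`` and there are no ties.

    The identity ``U_x + U_y = n_x·n_y`` holds by construction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in {"exact", "normal", "auto"}:
        raise ValueError(f"mode must be 'exact', 'normal' or 'auto', got {mode!r}")
    n_x, n_y = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_x = _u_from_ranks(ranks[:n_x], n_x, n_y)
    u_y = n_x * n_y - u_x
    u_min = min(u_x, u_y)

    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if (n_x + n_y <= EXACT_ENUMERATION_LIMIT and not has_ties) \
            else "normal"
    if mode == "exact":
        if has_ties:
            raise ValueError("exact enumeration does not support tied values")
        p = _exact_two_tailed_p(pooled, n_x, u_min)
        return u_min, min(1.0, p)

    n = n_x + n_y
    mu = n_x * n_y / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    sigma_sq = n_x * n_y / 12.0 * ((n + 1) - tie_term)
    if sigma_sq <= 0:
        return u_min, 1.0  # all values tied: no evidence either way
    z = (u_min - mu + 0.5) / np.sqrt(sigma_sq)  # continuity correction
    p = 2.0 * sps.norm.cdf(z)
    return u_min, float(min(1.0, p))


def _residualize(values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(values.size), covariates])
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    return values - design @ beta


def _corr_p(rho: float, n: int, k: int) -> float:
    df = n - 2 - k
    if df <= 0 or not np.isfinite(rho) or abs(rho) >= 1.0:
        return 0.0 if abs(rho) >= 1.0 and df > 0 else np.nan
    t = rho * np.sqrt(df / (1.0 - rho**2))
    return float(2.0 * sps.t.sf(abs(t), df))


def correlation_matrix(
    table: pd.DataFrame,
    variables: list[str],
    method: str = "spearman",
    control: list[str] | None = None,
    alpha: float = 0.001,
) -> CorrelationReport:
    """Pairwise (partial) correlation matrix over ``variables``.

    Spearman is Pearson on midranks.  With covariates, both variables (and,
    for Spearman, the covariates too) are residualised on the covariates by
    least squares and the residuals correlated; p-values use the
    t-transform with ``n − 2 − k`` df.  Missing values are handled
    pairwise-complete.  Zero-variance variables get NaN rows/columns.
    """
    if method not in {"spearman", "pearson"}:
        raise ValueError(f"method must be 'spearman' or 'pearson', got {method!r}")
    control = list(control or [])
    k = len(control)
    p_dim = len(variables)
    coef = np.full((p_dim, p_dim), np.nan)
    pval = np.full((p_dim, p_dim), np.nan)
    np.fill_diagonal(coef, 1.0)
    np.fill_diagonal(pval, 0.0)

    for i, j in combinations(range(p_dim), 2):
        cols = [variables[i], variables[j], *control]
        sub = table[cols].dropna()
        n = len(sub)
        if n < 4 + k:
            continue
        xi = sub[variables[i]].to_numpy(dtype=float)
        xj = sub[variables[j]].to_numpy(dtype=float)
        cov = sub[control].to_numpy(dtype=float) if k else None
        if np.ptp(xi) == 0 or np.ptp(xj) == 0:
            continue  # undefined: leave NaN
        if method == "spearman":
            xi = sps.rankdata(xi)
            xj = sps.rankdata(xj)
            if cov is not None:
                cov = np.column_stack([sps.rankdata(c) for c in cov.T])
        if cov is not None:
            si, sj = float(np.std(xi)), float(np.std(xj))
            xi = _residualize(xi, cov)
            xj = _residualize(xj, cov)
            # variables fully explained by the covariates leave only float
            # noise behind: no partial association remains
            if np.std(xi) < 1e-8 * si or np.std(xj) < 1e-8 * sj:
                coef[i, j] = coef[j, i] = 0.0
                pval[i, j] = pval[j, i] = 1.0
                continue
        rho = float(np.corrcoef(xi, xj)[0, 1])
        coef[i, j] = coef[j, i] = rho
        pval[i, j] = pval[j, i] = _corr_p(rho, n, k)

    return CorrelationReport(
        method=method,
        coefficients=pd.DataFrame(coef, index=variables, columns=variables),
        p_values=pd.DataFrame(pval, index=variables, columns=variables),
        covariates=control,
        alpha=alpha,
    )


def significance_filter(p_matrix: np.ndarray, alpha: float = 0.001) -> np.ndarray:
    """Boolean mask, True iff p < alpha (strict); NaN p never passes."""
    p = np.asarray(p_matrix, dtype=float)
    with np.errstate(invalid="ignore"):
        return (p < alpha) & np.isfinite(p)


def posthoc_power(mean1: float, sd1: float, n1: int,
                  mean2: float, sd2: float, n2: int,
                  alpha: float = 0.05, method: str = "t_noncentral") -> float:
    """Achieved power for a two-tailed two-sample comparison.

    Cohen's d from the pooled SD; noncentrality ``d·√(n1·n2/(n1+n2))``;
    power under the noncentral t with ``n1+n2−2`` df.  ``method='mw_are'``
    scales the effective sample sizes by the 0.955 asymptotic relative
    efficiency of the rank test against the t-test.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be ≥ 2")
    if method not in {"t_noncentral", "mw_are"}:
        raise ValueError(f"unknown method {method!r}")
    are = 0.955 if method == "mw_are" else 1.0
    e1, e2 = n1 * are, n2 * are
    pooled_sd = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    d = abs(mean1 - mean2) / pooled_sd
    ncp = d * np.sqrt(e1 * e2 / (e1 + e2))
    df = e1 + e2 - 2
    t_crit = sps.t.ppf(1 - alpha / 2.0, df)
    power = sps.nct.sf(t_crit, df, ncp) + sps.nct.cdf(-t_crit, df, ncp)
    if not np.isfinite(power):
        # large-df fallback: the noncentral t degenerates to a shifted normal
        power = sps.norm.sf(t_crit - ncp) + sps.norm.cdf(-t_crit - ncp)
    return float(power)
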