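"""Statistical primitives shared by the genome scans.

Every scan in the pipeline reduces to a small set of classical tests:
Grubbs' single-outlier test (applied iteratively to chromosome-level
summaries), the Mann-Whitney U test (per-gene rate comparisons), Fisher's
exact test, Pearson/Spearman correlation, and a binomial logistic
regression (heterozygosity gradients along a chromosome).

The implementations favour exactness at small sample sizes: the
Mann-Whitney p-value is computed by enumerating the permutation null
(with midrank ties) whenever the smaller group has at most
``EXACT_MWU_MIN_GROUP`` observations and the enumeration is tractable,
falling back to the tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "OutlierReport",
    "GradientFit",
    "MannWhitneyResult",
    "grubbs_test",
    "iterative_outlier_scan",
    "mann_whitney_u",
    "fisher_exact",
    "correlation",
    "logistic_fit",
]

# Exact Mann-Whitney enumeration is used when the smaller group has at most
# this many observations and the rank-sum dynamic programme stays small.
EXACT_MWU_MIN_GROUP = 8
EXACT_MWU_MAX_TOTAL = 40


# ---------------------------------------------------------------------------
# Grubbs' outlier test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutlierReport:
    """One detection from an iterative Grubbs scan."""

    label: str
    G: float
    p: float
    iteration: int


def grubbs_test(values, candidate_index: int) -> tuple[float, float]:
    """Grubbs' test of a designated candidate against the full sample.

    The statistic is ``G = |x_c - mean| / sd`` with the sample standard
    deviation (n-1 denominator) computed over *all* values including the
    candidate.  The two-sided p-value uses the closed form that relates G
    to a t(n-2) quantile with a Bonferroni factor of n.

    Raises ``ValueError`` for n < 4 or zero standard deviation (the test
    is undefined there rather than merely unreliable).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError(f"Grubbs test requires n >= 4, got n={n}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("Grubbs test undefined for zero-variance sample")
    G = abs(x[candidate_index] - x.mean()) / sd
    # Invert G -> t:  G = (n-1)/sqrt(n) * sqrt(t^2 / (n-2+t^2))
    gmax2 = (n - 1) ** 2 / n  # squared maximum attainable G
    if G * G >= gmax2:
        p = 0.0
    else:
        t2 = (n - 2) * G * G / (gmax2 - G * G)
        p = 2.0 * n * sps.t.sf(math.sqrt(t2), n - 2)
        p = min(1.0, max(0.0, p))
    return float(G), float(p)


def iterative_outlier_scan(values, labels, alpha: float = 0.05) -> list[OutlierReport]:
    """Detect-and-remove Grubbs scan.

    At each iteration the most deviant remaining value is tested; if
    significant at ``alpha`` it is recorded and removed, and the scan
    repeats on the reduced sample.  Stops when no outlier is found or
    fewer than 4 values remain.
    """
    x = list(map(float, values))
    labs = list(labels)
    if len(x) != len(labs):
        raise ValueError("values and labels must have equal length")
    if len(x) < 5:
        raise ValueError("iterative scan requires n >= 5")
    out: list[OutlierReport] = []
    iteration = 0
    while len(x) >= 4:
        arr = np.asarray(x)
        cand = int(np.argmax(np.abs(arr - arr.mean())))
        if arr.std(ddof=1) == 0:
            break
        G, p = grubbs_test(arr, cand)
        if p < alpha:
            out.append(OutlierReport(label=labs[cand], G=G, p=p, iteration=iteration))
            del x[cand]
            del labs[cand]
            iteration += 1
        else:
            break
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MannWhitneyResult:
    test: str
    U: float
    p: float
    n_x: int
    n_y: int
    method: str  # "exact" | "normal"


def _mwu_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x: wins over y, ties counted 1/2 (midrank convention)."""
    ranks = sps.rankdata(np.concatenate([x, y]))
    rx = ranks[: x.size].sum()
    return float(rx - x.size * (x.size + 1) / 2.0)


def _exact_mwu_pvalue(combined: np.ndarray, n: int, u_obs: float) -> float:
    """Two-sided exact p by enumerating the rank-sum permutation null.

    Dynamic programme over midranks (doubled to keep integer sums):
    counts of ways to choose k items with a given doubled rank sum.
    """
    ranks2 = np.round(2 * sps.rankdata(combined)).astype(int)
    max_sum = int(ranks2.sum())
    # dp[k] maps doubled-rank-sum -> count
    dp = [dict() for _ in range(n + 1)]
    dp[0][0] = 1
    for r in ranks2:
        for k in range(min(n, len(dp)) - 1, -1, -1):
            if not dp[k]:
                continue
            tgt = dp[k + 1]
            for s, c in dp[k].items():
                tgt[s + r] = tgt.get(s + r, 0) + c
    dist = dp[n]
    total = sum(dist.values())
    # U = R_x - n(n+1)/2; doubled: 2U = s - n(n+1)
    u2_obs = int(round(2 * u_obs))
    off = n * (n + 1)
    le = sum(c for s, c in dist.items() if s - off <= u2_obs)
    ge = sum(c for s, c in dist.items() if s - off >= u2_obs)
    p = 2.0 * min(le, ge) / total
    return min(1.0, p)


def mann_whitney_u(x, y) -> MannWhitneyResult:
    """Mann-Whitney U test, exact for small groups, normal otherwise.

    U is reported for the first sample with midrank tie handling.  The
    exact two-sided p is ``2 * min(P(U* <= U), P(U* >= U))`` over the
    permutation null; the approximation uses the tie-corrected normal
    variance without continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    n, m = x.size, y.size
    combined = np.concatenate([x, y])
    U = _mwu_statistic(x, y)
    use_exact = min(n, m) <= EXACT_MWU_MIN_GROUP and n + m <= EXACT_MWU_MAX_TOTAL
    if use_exact:
        p = _exact_mwu_pvalue(combined, n, U)
        method = "exact"
    else:
        N = n + m
        _, counts = np.unique(combined, return_counts=True)
        tie_term = float(((counts**3 - counts).sum()) / (N * (N - 1)))
        var = n * m / 12.0 * ((N + 1) - tie_term)
        if var <= 0:
            return MannWhitneyResult("mann-whitney-u", U, float("nan"), n, m, "degenerate")
        z = (U - n * m / 2.0) / math.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
        method = "normal"
    return MannWhitneyResult("mann-whitney-u", U, p, n, m, method)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def fisher_exact(table) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of
    tables (at fixed margins) no more probable than the observed one."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("fisher_exact needs a nonnegative 2x2 table")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        return float("nan")  # empty margin: undefined-flagged
    _, p = sps.fisher_exact(t, alternative="two-sided")
    return float(p)


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def correlation(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation; (nan, nan) on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("correlation needs paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Binomial logistic regression
# ---------------------------------------------------------------------------

@dataclass
class GradientFit:
    """Fit of a per-bin success proportion against a covariate (logit link)."""

    beta: float
    intercept: float
    se_beta: float
    se_intercept: float
    p_beta: float
    p_intercept: float
    n_bins: int
    converged: bool = True
    separation: bool = False
    notes: str = ""


def logistic_fit(successes, totals, covariate) -> GradientFit:
    """Binomial GLM (logit link) of successes/totals on one covariate.

    Fitted by iteratively reweighted least squares (convergence tolerance
    1e-8, at most 100 iterations).  Complete or quasi-complete separation
    is reported via the ``separation`` flag instead of raising.
    """
    import statsmodels.api as sm

    s = np.asarray(successes, dtype=float)
    t = np.asarray(totals, dtype=float)
    c = np.asarray(covariate, dtype=float)
    keep = t > 0
    s, t, c = s[keep], t[keep], c[keep]
    if s.size < 2:
        raise ValueError("logistic_fit needs at least 2 non-empty bins")
    if (s > t).any() or (s < 0).any():
        raise ValueError("successes must lie in [0, totals]")
    endog = np.column_stack([s, t - s])
    exog = sm.add_constant(c)
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=100, tol=1e-8)
    except Exception as exc:  # PerfectSeparation and numerical failures
        return GradientFit(
            beta=float("nan"), intercept=float("nan"),
            se_beta=float("nan"), se_intercept=float("nan"),
            p_beta=float("nan"), p_intercept=float("nan"),
            n_bins=int(s.size), converged=False, separation=True,
            notes=f"fit failed: {type(exc).__name__}",
        )
    eta = res.predict(exog, which="linear")
    separated = bool(
        not np.isfinite(res.bse).all()
        or np.abs(eta).max() > 30
        or not res.converged
    )
    return GradientFit(
        beta=float(res.params[1]),
        intercept=float(res.params[0]),
        se_beta=float(res.bse[1]),
        se_intercept=float(res.bse[0]),
        p_beta=float(res.pvalues[1]),
        p_intercept=float(res.pvalues[0]),
        n_bins=int(s.size),
        converged=bool(res.converged),
        separation=separated,
    )
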