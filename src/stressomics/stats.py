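"""Statistical kernels: BH FDR, one-sample t, hypergeometric enrichment,
weighted proportional-odds ordinal regression, and differential-expression
table utilities.

The proportional-odds model here supports fractional observation weights so
that relative-abundance stoichiometries (e.g. methyl-state fractions) can be
used directly as ordinal data; integer-count expansion is the weights-of-n
special case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps

__all__ = [
    "bh_fdr",
    "one_sample_t",
    "EnrichmentResult",
    "hypergeometric_enrichment",
    "OrdinalModelFit",
    "proportional_odds_fit",
    "classify_de",
    "filter_low_counts",
]


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Order-preserving with the input; ties handled by the cumulative-minimum
    formulation q_(i) = min_{j>=i} p_(j) * m / j, clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def one_sample_t(values: Sequence[float], mu0: float = 0.0) -> tuple[float, float]:
    """Two-sided one-sample t-test of the mean against ``mu0``.

    Returns ``(t, p)``.  Raises for n < 2; a zero-variance sample has no
    distributional basis, so ``(nan, nan)`` is returned with a warning and
    the caller decides how to treat it.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("one_sample_t needs at least two values")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("zero-variance sample: t-test undefined", stacklevel=2)
        return (np.nan, np.nan)
    t = (x.mean() - mu0) / (sd / np.sqrt(x.size))
    p = 2.0 * sps.t.sf(abs(t), df=x.size - 1)
    return (float(t), float(p))


@dataclass(frozen=True)
class EnrichmentResult:
    """Over-representation of one annotation term in a study set."""

    term: str
    k: int  # study hits
    n: int  # study size
    K: int  # background hits
    N: int  # background size
    p_value: float
    q_value: float


def hypergeometric_enrichment(
    study: Iterable[str],
    background: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation test per term, with BH
    correction across all tested terms.

    The study set must be a subset of the background; annotations are
    restricted to background genes.  Terms with no study hit are skipped
    (their under-representation is not of interest here).  Results are
    sorted by p-value.
    """
    study_set = set(study)
    background_set = set(background)
    stray = study_set - background_set
    if stray:
        raise ValueError(f"study gene(s) absent from background: {sorted(stray)[:5]}")
    N = len(background_set)
    n = len(study_set)
    rows = []
    for term in sorted(annotations):
        genes = set(annotations[term]) & background_set
        K = len(genes)
        k = len(genes & study_set)
        if k == 0:
            continue
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, p))
    if not rows:
        return []
    q = bh_fdr([p for *_ignored, p in rows])
    results = [
        EnrichmentResult(term=term, k=k, n=n, K=K, N=N, p_value=p, q_value=float(qv))
        for (term, k, K, p), qv in zip(rows, q)
    ]
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


# ---------------------------------------------------------------------------
# proportional-odds (cumulative logit) ordinal regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrdinalModelFit:
    """Fit of the cumulative-logit model P(Y <= j | x) = logistic(c_j - b'x)."""

    cutpoints: np.ndarray  # strictly increasing, length n_states - 1
    coefficients: np.ndarray  # per-covariate slopes b
    log_likelihood: float
    converged: bool
    beta_se: np.ndarray  # Wald standard errors of the slopes
    n_iter: int

    def wald_test(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-coefficient Wald z statistics and two-sided normal p-values."""
        z = self.coefficients / self.beta_se
        return z, 2.0 * sps.norm.sf(np.abs(z))


def _po_negloglik_grad(params, y, X, w, n_states):
    """Weighted negative log-likelihood and gradient in the natural
    parameterization (c_1..c_{J-1}, beta), assuming ordered cutpoints."""
    J = n_states
    c = params[: J - 1]
    beta = params[J - 1:]
    xb = X @ beta
    # eta for upper and lower cumulative bounds of each observation's state
    upper = np.where(y < J - 1, c[np.minimum(y, J - 2)] - xb, np.inf)
    lower = np.where(y > 0, c[np.maximum(y - 1, 0)] - xb, -np.inf)
    Fu = special.expit(upper)
    Fl = special.expit(lower)
    pi = np.clip(Fu - Fl, 1e-300, None)
    nll = -np.sum(w * np.log(pi))

    fu = Fu * (1.0 - Fu)  # logistic density at the bounds (0 at +/-inf)
    fl = Fl * (1.0 - Fl)
    du = w * fu / pi  # d loglik / d upper-eta
    dl = -w * fl / pi
    grad_c = np.zeros(J - 1)
    has_upper = y < J - 1
    np.add.at(grad_c, np.minimum(y[has_upper], J - 2), du[has_upper])
    has_lower = y > 0
    np.add.at(grad_c, np.maximum(y[has_lower] - 1, 0), dl[has_lower])
    grad_beta = -X.T @ (du + dl)
    return nll, -np.concatenate([grad_c, grad_beta])


def proportional_odds_fit(
    y: Sequence[int],
    X: np.ndarray,
    weights: Sequence[float] | None = None,
    max_iter: int = 200,
    gtol: float = 1e-8,
) -> OrdinalModelFit:
    """Maximum-likelihood fit of the proportional-odds model.

    Parameters
    ----------
    y
        Ordinal state indices 0..J-1 (J >= 2 distinct states observed;
        J = 2 reduces exactly to binary logistic regression).
    X
        Covariate matrix, one row per observation.
    weights
        Optional non-negative observation weights (fractional weights
        supported; default all ones).

    The ordered-cutpoint constraint is enforced by optimizing over the
    first cutpoint and log-gaps; convergence requires gradient norm below
    ``gtol``.  Separation or non-convergence is reported through the
    ``converged`` flag, never silently.
    """
    y = np.asarray(y, dtype=int)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    if X.shape[0] != y.size:
        raise ValueError("X and y have incompatible shapes")
    w = np.ones(y.size) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    states = np.unique(y[w > 0])
    if states.size < 2:
        raise ValueError("need at least two observed states")
    # relabel to contiguous 0..J-1
    y = np.searchsorted(states, y)
    J = states.size
    n_beta = X.shape[1]

    def unpack(theta):
        c1 = theta[0]
        gaps = np.exp(theta[1: J - 1])
        c = np.concatenate([[c1], c1 + np.cumsum(gaps)])
        return c, theta[J - 1:]

    def objective(theta):
        c, beta = unpack(theta)
        params = np.concatenate([c, beta])
        nll, grad = _po_negloglik_grad(params, y, X, w, J)
        # chain rule back to (c1, log-gaps, beta)
        gc = grad[: J - 1]
        gtheta = np.empty_like(theta)
        gtheta[0] = gc.sum()
        for j in range(1, J - 1):
            gtheta[j] = gc[j:].sum() * np.exp(theta[j])
        gtheta[J - 1:] = grad[J - 1:]
        return nll, gtheta

    # start from the empirical cumulative logits at beta = 0
    totals = np.array([w[y == j].sum() for j in range(J)])
    cum = np.cumsum(totals)[:-1] / totals.sum()
    cum = np.clip(cum, 1e-4, 1 - 1e-4)
    c0 = special.logit(cum)
    theta0 = np.concatenate(
        [[c0[0]], np.log(np.maximum(np.diff(c0), 1e-4)), np.zeros(n_beta)]
    )
    res = optimize.minimize(
        objective,
        theta0,
        jac=True,
        method="BFGS",
        options={"gtol": gtol, "maxiter": max_iter},
    )
    # polish with a second pass if the line search stalled early
    if np.linalg.norm(res.jac, ord=np.inf) > gtol:
        res2 = optimize.minimize(
            objective, res.x, jac=True, method="BFGS",
            options={"gtol": gtol, "maxiter": max_iter},
        )
        if res2.fun <= res.fun:
            res = res2
    cutpoints, beta = unpack(res.x)
    converged = bool(np.linalg.norm(res.jac, ord=np.inf) < 1e-5)

    # observed-information standard errors for beta (finite differences of
    # the analytic gradient in the natural parameterization)
    params_hat = np.concatenate([cutpoints, beta])
    se = _wald_se(params_hat, y, X, w, J, n_beta)
    return OrdinalModelFit(
        cutpoints=cutpoints,
        coefficients=beta,
        log_likelihood=-float(res.fun),
        converged=converged,
        beta_se=se,
        n_iter=int(res.nit),
    )


def _wald_se(params_hat, y, X, w, J, n_beta):
    k = params_hat.size
    hess = np.empty((k, k))
    eps = 1e-5
    for i in range(k):
        step = np.zeros(k)
        step[i] = eps
        _, gp = _po_negloglik_grad(params_hat + step, y, X, w, J)
        _, gm = _po_negloglik_grad(params_hat - step, y, X, w, J)
        hess[i] = (gp - gm) / (2 * eps)
    hess = (hess + hess.T) / 2
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov)[J - 1:], 0, None))
    except np.linalg.LinAlgError:
        se = np.full(n_beta, np.nan)
    return se


# ---------------------------------------------------------------------------
# differential-expression table utilities
# ---------------------------------------------------------------------------

def classify_de(
    table: pd.DataFrame,
    fc_threshold: float = 0.8,
    p_threshold: float = 0.05,
    fc_column: str = "log2_fc",
    p_column: str = "adj_p",
) -> pd.DataFrame:
    """Classify genes as up/down/unchanged from a DE results table.

    A gene is down when log2 FC <= -fc_threshold (inclusive) with adjusted
    p strictly below p_threshold, and up symmetrically.  Rows with missing
    adjusted p are classified unchanged with a warning.
    """
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    out = table.copy()
    fc = out[fc_column].astype(float)
    p = out[p_column].astype(float)
    n_missing = int(p.isna().sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} row(s) with missing adjusted p classified unchanged",
            stacklevel=2,
        )
    significant = p < p_threshold
    call = np.where(
        significant & (fc >= fc_threshold),
        "up",
        np.where(significant & (fc <= -fc_threshold), "down", "unchanged"),
    )
    out["call"] = call
    return out


def filter_low_counts(counts: pd.DataFrame, min_total: int = 2) -> pd.DataFrame:
    """Drop genes (rows) whose summed read count across samples is below
    ``min_total`` (default: remove rows summing to <= 1)."""
    values = counts.to_numpy()
    if (values < 0).any():
        raise ValueError("negative counts")
    return counts[counts.sum(axis=1) >= min_total]
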