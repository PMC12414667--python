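"""Per-variant, per-stratum carrier association statistics.

Quantitative phenotypes (serum labs) are tested with ordinary least squares
on a carrier indicator plus covariates (age, sex, 10 genetic PCs).  Binary
phenotypes (diagnosis categories, medication use) are tested with Fisher's
exact test; when there are at least 10 events per model variable a
Firth-penalized logistic regression is additionally available for reporting.
Per-stratum results can be pooled by inverse-variance fixed-effect
meta-analysis, with a weighted-Z fallback for binary phenotypes whose odds
ratios are infinite (common when a variant has only a handful of carriers).

Conventions that matter downstream:

* Fisher's two-sided p sums the probabilities of all tables (at fixed
  margins) no more probable than the observed one; two-sided exact
  conventions differ between packages, so this one is pinned by tests
  against a direct hypergeometric enumeration oracle.
* The odds ratio is the sample odds ratio ``ad/bc``, reported as infinite
  when ``bc = 0`` (no continuity correction enters any p-value; the
  Haldane-Anscombe 0.5 correction is applied only to *displayed* odds
  ratios via :func:`display_odds_ratio`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    variant_id: str | None
    stratum: str | None
    phenotype: str
    kind: str                      # "quantitative" | "binary"
    beta: float
    se: float
    p_value: float
    method: str                    # "ols" | "fisher" | "firth" | "meta"
    odds_ratio: float | None = None
    n_carriers: int | None = None
    n_events: int | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value):
            self.p_value = float(min(max(self.p_value, np.nextafter(0.0, 1.0)), 1.0))


@dataclass
class MetaResult:
    beta: float
    se: float
    p_value: float
    strata: list
    heterogeneity_q: float | None = None
    note: str = ""


# ---------------------------------------------------------------------------
# quantitative: OLS carrier effect
# ---------------------------------------------------------------------------

def ols_carrier_beta(y, carrier, covariates=None,
                     variant_id=None, stratum=None,
                     phenotype="lab") -> AssociationResult:
    """Carrier effect on a quantitative lab by ordinary least squares.

    ``beta`` is the coefficient of the carrier indicator in
    ``y ~ 1 + carrier + covariates``; the two-sided p comes from the t
    statistic.  Collinear covariate columns are dropped with a warning;
    zero residual degrees of freedom is an error.
    """
    y = np.asarray(y, dtype=float)
    carrier = np.asarray(carrier, dtype=float)
    if carrier.sum() < 1:
        raise ValueError("need at least one carrier with a non-missing response")
    cols = [np.ones_like(y), carrier]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(y):
            cov = cov.T
        for j in range(cov.shape[1]):
            cols.append(cov[:, j])
    X = np.column_stack(cols)
    # drop collinear covariate columns (never the intercept or carrier)
    keep = [0, 1]
    for j in range(2, X.shape[1]):
        if np.linalg.matrix_rank(X[:, keep + [j]]) > len(keep):
            keep.append(j)
        else:
            logger.warning("dropping collinear covariate column %d", j - 2)
    X = X[:, keep]
    if len(y) - X.shape[1] <= 0:
        raise ValueError("zero residual degrees of freedom")
    if np.ptp(y) == 0.0:
        # constant response: the carrier effect is exactly zero
        return AssociationResult(variant_id, stratum, phenotype, "quantitative",
                                 beta=0.0, se=0.0, p_value=1.0, method="ols",
                                 n_carriers=int(carrier.sum()))
    fit = sm.OLS(y, X).fit()
    return AssociationResult(
        variant_id, stratum, phenotype, "quantitative",
        beta=float(fit.params[1]), se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]), method="ols",
        n_carriers=int(carrier.sum()),
    )


class CarrierOLS:
    """Shared-projection OLS for scoring many variants against one lab.

    The covariate design (intercept, age, sex, PCs) is identical for every
    variant in a stratum, so the lab is residualized on it once; each
    variant's carrier beta then follows from the
    Frisch-Waugh-Lovell identities in O(carriers x covariates) time.
    Numerically identical (to ~1e-10) to refitting the full OLS per variant.
    """

    def __init__(self, y, X):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.n, self.d = self.X.shape
        self.xtx_inv = np.linalg.pinv(self.X.T @ self.X)
        gamma = self.xtx_inv @ (self.X.T @ self.y)
        self.resid = self.y - self.X @ gamma
        self.ssr = float(self.resid @ self.resid)
        self.dof = self.n - self.d - 1

    def carrier_beta(self, idx) -> tuple[float, float, float] | None:
        """(beta, se, p) for a carrier set given as row indices; ``None``
        when the carrier indicator is collinear with the covariates."""
        idx = np.asarray(idx, dtype=int)
        k = len(idx)
        if k == 0 or self.dof <= 0:
            return None
        u = self.X[idx].sum(axis=0)
        cmc = k - float(u @ self.xtx_inv @ u)
        if cmc <= 1e-10:
            return None
        beta = float(self.resid[idx].sum() / cmc)
        sigma2 = max((self.ssr - beta * beta * cmc) / self.dof, 0.0)
        if sigma2 == 0.0:
            return (beta, 0.0, 1.0 if beta == 0.0 else 0.0)
        se = float(np.sqrt(sigma2 / cmc))
        t = beta / se
        p = float(2.0 * stats.t.sf(abs(t), self.dof))
        return (beta, se, min(max(p, np.nextafter(0.0, 1.0)), 1.0))


# ---------------------------------------------------------------------------
# binary: Fisher's exact test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1 << 20)
def _fisher_cached(a: int, b: int, c: int, d: int) -> float:
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fisher_carrier_enrichment(a: int, b: int, c: int, d: int,
                              variant_id=None, stratum=None,
                              phenotype="binary") -> AssociationResult:
    """Two-sided Fisher's exact test on the 2x2 table
    ``[[carriers with event, carriers without], [non-carriers with, without]]``.
    """
    for v in (a, b, c, d):
        if int(v) != v or v < 0:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if a + b + c + d == 0:
        raise ValueError("all-zero 2x2 table")
    if a + b < 1:
        raise ValueError("need at least one carrier")
    p = min(_fisher_cached(a, b, c, d), 1.0)
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    beta = float(np.log(odds)) if np.isfinite(odds) and odds > 0 else float(np.sign(a * d - b * c)) * np.inf
    if a * d == 0 and b * c == 0:
        beta = 0.0
    return AssociationResult(
        variant_id, stratum, phenotype, "binary",
        beta=beta, se=float("nan"), p_value=p, method="fisher",
        odds_ratio=odds, n_carriers=a + b, n_events=a + c,
    )


def display_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Haldane-Anscombe 0.5-corrected odds ratio, for display only."""
    return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))


# ---------------------------------------------------------------------------
# binary: Firth-penalized logistic regression
# ---------------------------------------------------------------------------

def _firth_fit(X: np.ndarray, y: np.ndarray, max_iter: int, tol: float,
               fixed_zero: tuple[int, ...] = ()):
    """Maximize the Jeffreys-penalized log-likelihood
    ``l(b) + 0.5 * log det I(b)`` by Newton iteration with Firth's
    hat-matrix-adjusted score and step-halving.

    ``fixed_zero`` constrains the listed coefficients to zero while the
    penalty is still evaluated on the full design — the profile penalized
    likelihood needed for a dimension-consistent likelihood-ratio test.
    """
    n, p = X.shape
    free = np.array([j for j in range(p) if j not in fixed_zero])
    beta = np.zeros(p)

    def penalized_ll(b):
        eta = X @ b
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
        ll = float(y @ np.log(mu) + (1 - y) @ np.log(1.0 - mu))
        W = mu * (1.0 - mu)
        info = (X * W[:, None]).T @ X
        sign, logdet = np.linalg.slogdet(info)
        if sign <= 0:
            return -np.inf, None, None
        return ll + 0.5 * logdet, mu, info

    pll, mu, info = penalized_ll(beta)
    for _ in range(max_iter):
        W = mu * (1.0 - mu)
        info_inv = np.linalg.inv(info)
        h = np.einsum("ij,jk,ik->i", X, info_inv, X * W[:, None])
        score = (X.T @ (y - mu + h * (0.5 - mu)))[free]
        if np.max(np.abs(score)) < tol:
            return beta, pll, info
        step_free = np.linalg.solve(info[np.ix_(free, free)], score)
        step = np.zeros(p)
        step[free] = step_free
        # step-halving to guarantee monotone penalized likelihood
        for _ in range(30):
            cand = beta + step
            pll_new, mu_new, info_new = penalized_ll(cand)
            if pll_new >= pll - 1e-12:
                break
            step *= 0.5
        else:
            raise RuntimeError("Firth step-halving failed to find an uphill step")
        if abs(pll_new - pll) < tol and np.max(np.abs(cand - beta)) < np.sqrt(tol):
            return cand, pll_new, info_new
        beta, pll, mu, info = cand, pll_new, mu_new, info_new
    raise RuntimeError(
        f"Firth logistic regression did not converge in {max_iter} iterations "
        f"(last penalized log-likelihood {pll:.6g}, max |score| "
        f"{np.max(np.abs(score)):.3g})"
    )


def firth_logistic(y, carrier, covariates=None, max_iter=100, tol=1e-8,
                   enforce_events=True, variant_id=None, stratum=None,
                   phenotype="binary") -> AssociationResult:
    """Firth-penalized logistic regression of a binary phenotype on a
    carrier indicator (plus covariates).

    The Jeffreys-prior penalty keeps the carrier log-odds finite even under
    complete separation.  The p-value is a penalized likelihood-ratio test
    comparing the fit with and without the carrier term.  By default the
    10-events-per-variable precondition is enforced (callers with fewer
    events should use Fisher's exact test instead).
    """
    y = np.asarray(y, dtype=float)
    carrier = np.asarray(carrier, dtype=float)
    cols = [np.ones_like(y), carrier]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(y):
            cov = cov.T
        cols.extend(cov[:, j] for j in range(cov.shape[1]))
    X = np.column_stack(cols)
    n_events = int(min(y.sum(), len(y) - y.sum()))
    if enforce_events and n_events < 10 * X.shape[1]:
        raise ValueError(
            f"{n_events} events for {X.shape[1]} variables is below the "
            "10-events-per-variable precondition; use Fisher's exact test"
        )
    beta, pll_full, info = _firth_fit(X, y, max_iter, tol)
    _, pll_null, _ = _firth_fit(X, y, max_iter, tol, fixed_zero=(1,))
    lr = max(2.0 * (pll_full - pll_null), 0.0)
    p = float(stats.chi2.sf(lr, df=1))
    se = float(np.sqrt(np.linalg.inv(info)[1, 1]))
    return AssociationResult(
        variant_id, stratum, phenotype, "binary",
        beta=float(beta[1]), se=se, p_value=p, method="firth",
        odds_ratio=float(np.exp(beta[1])),
        n_carriers=int(carrier.sum()), n_events=n_events,
    )


def select_test(n_events: int, n_variables: int) -> list[str]:
    """Which binary-phenotype tests to run.

    Fisher's exact test always feeds the score pipeline; the Firth
    regression is additionally run, for reporting, when there are at least
    10 events per variable.
    """
    if n_events < 0 or n_variables < 0:
        raise ValueError("counts must be non-negative")
    if n_events and n_variables and n_events / n_variables >= 10:
        return ["fisher", "firth"]
    return ["fisher"]


# ---------------------------------------------------------------------------
# cross-stratum meta-analysis
# ---------------------------------------------------------------------------

def meta_fixed_effect(results: list[AssociationResult]) -> MetaResult:
    """Inverse-variance fixed-effect pooling of per-stratum results.

    ``pooled beta = sum(w_i b_i) / sum(w_i)`` with ``w_i = se_i^-2``;
    ``pooled se = (sum w_i)^-1/2`` (never larger than the smallest
    component se); two-sided normal p.
    """
    usable = [r for r in results
              if np.isfinite(r.beta) and np.isfinite(r.se) and r.se > 0]
    if not usable:
        raise ValueError("no stratum with finite beta and positive se")
    w = np.array([r.se ** -2 for r in usable])
    b = np.array([r.beta for r in usable])
    pooled_beta = float((w * b).sum() / w.sum())
    pooled_se = float(w.sum() ** -0.5)
    z = pooled_beta / pooled_se
    p = float(2.0 * stats.norm.sf(abs(z)))
    q = float((w * (b - pooled_beta) ** 2).sum()) if len(usable) > 1 else None
    note = ""
    if len(usable) < len(results):
        note = f"{len(results) - len(usable)} stratum result(s) dropped (non-finite beta/se)"
    return MetaResult(beta=pooled_beta, se=pooled_se,
                      p_value=min(max(p, np.nextafter(0.0, 1.0)), 1.0),
                      strata=[r.stratum for r in usable],
                      heterogeneity_q=q, note=note)


def stouffer_meta(p_values, signs, weights=None) -> float:
    """Weighted-Z combination of signed two-sided p-values.

    Used for binary phenotypes whose per-stratum odds ratios are infinite
    (no finite log-OR to pool): each p is converted to a signed Z and
    combined as ``sum(w_i z_i) / sqrt(sum w_i^2)``.
    """
    p_values = np.asarray(p_values, dtype=float)
    signs = np.sign(np.asarray(signs, dtype=float))
    if weights is None:
        weights = np.ones_like(p_values)
    weights = np.asarray(weights, dtype=float)
    z = -stats.norm.ppf(np.clip(p_values, 1e-300, 1.0) / 2.0) * signs
    pooled_z = float((weights * z).sum() / np.sqrt((weights ** 2).sum()))
    return float(min(max(2.0 * stats.norm.sf(abs(pooled_z)), np.nextafter(0.0, 1.0)), 1.0))
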