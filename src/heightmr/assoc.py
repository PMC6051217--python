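"""One-sample association of a genetic risk score with case-control status.

Covariate-adjusted logistic regression of disease status on the score —
continuous (odds ratio per SD of genetically predicted height), by tertile
with a trend test, and expanded in a restricted cubic spline to test
departure from log-linearity.  The logistic fitter is a plain Newton/IRLS
maximum-likelihood routine with step-halving, which the rest of the package
shares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm

from .grs import ScoreVector, TertileAssignment

__all__ = [
    "SeparationError",
    "LogisticFit",
    "AssocResult",
    "TertileAssociation",
    "NonlinearityTest",
    "fit_logistic",
    "grs_association",
    "tertile_association",
    "rcs_basis",
    "nonlinearity_test",
]

#: normal quantile used for 95% confidence intervals
Z95 = 1.959964

SUBTYPES = ("adenocarcinoma", "squamous", "other")


class SeparationError(RuntimeError):
    """Raised when logistic maximum likelihood diverges (separated data)."""


@dataclass
class LogisticFit:
    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    n_iter: int
    loglik_path: np.ndarray
    converged: bool


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> LogisticFit:
    """Logistic regression by iteratively reweighted least squares.

    Newton updates with step-halving so the log-likelihood never decreases;
    convergence when the log-likelihood change falls below ``tol``.  Standard
    errors come from the observed information at the optimum.  Perfect or
    quasi-complete separation (a coefficient past 15 while steps are still
    large) and rank-deficient designs raise errors rather than returning
    garbage.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, np.newaxis]
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("y and X have inconsistent lengths")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("y must be binary 0/1")
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    if y.min() == y.max():
        raise SeparationError("outcome is constant")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")

    # column scales make the divergence check invariant to covariate units
    col_scale = X.std(axis=0)
    col_scale[col_scale == 0] = 1.0
    beta = np.zeros(p)
    eta = X @ beta
    ll = _loglik(y, eta)
    path = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        H = (X * w[:, np.newaxis]).T @ X
        g = X.T @ (y - mu)
        try:
            delta = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise ValueError("information matrix is singular") from exc
        step = 1.0
        for _ in range(40):
            cand = beta + step * delta
            eta_c = X @ cand
            ll_c = _loglik(y, eta_c)
            if ll_c >= ll - 1e-12:
                break
            step *= 0.5
        beta, eta = cand, eta_c
        path.append(ll_c)
        step_norm = float(np.max(np.abs(step * delta) * col_scale))
        if np.max(np.abs(beta) * col_scale) > 15.0 and step_norm > 1e-2:
            raise SeparationError(
                "coefficients diverging without likelihood convergence "
                "(perfect or quasi-complete separation)"
            )
        if abs(ll_c - ll) < tol:
            ll = ll_c
            converged = True
            break
        ll = ll_c

    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    H = (X * w[:, np.newaxis]).T @ X
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov))
    return LogisticFit(beta, se, cov, ll, it, np.asarray(path), converged)


@dataclass(frozen=True)
class AssocResult:
    """A single log-odds coefficient with its Wald inference."""

    term: str
    beta: float
    se: float
    p: float
    n_cases: int
    n_controls: int

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            float(np.exp(self.beta - Z95 * self.se)),
            float(np.exp(self.beta + Z95 * self.se)),
        )

    def to_dict(self) -> dict:
        lo, hi = self.ci95
        return {
            "term": self.term,
            "beta": self.beta,
            "se": self.se,
            "or": self.or_,
            "ci_low": lo,
            "ci_high": hi,
            "p": self.p,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
        }


def _wald(term: str, beta: float, se: float, n_cases: int, n_controls: int) -> AssocResult:
    z = beta / se
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return AssocResult(term, float(beta), float(se), p, n_cases, n_controls)


def _merged_frame(
    subject_ids: Sequence[str],
    values: pd.DataFrame,
    phenotypes: pd.DataFrame,
    subtype_filter: str,
) -> pd.DataFrame:
    if subtype_filter not in ("all",) + SUBTYPES:
        raise ValueError(f"unknown subtype filter {subtype_filter!r}")
    df = values.merge(phenotypes, on="subject_id", how="inner")
    if subtype_filter != "all":
        # subtype contrasts drop cases of the other subtypes, keep all controls
        df = df[(df["status"] == 0) | (df["subtype"] == subtype_filter)]
    n_cases = int((df["status"] == 1).sum())
    n_controls = int((df["status"] == 0).sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError(
            f"no {'cases' if n_cases == 0 else 'controls'} left after filtering "
            f"(subtype={subtype_filter!r})"
        )
    return df.reset_index(drop=True)


def _design(df: pd.DataFrame, covariate_names: Sequence[str], extra: np.ndarray) -> np.ndarray:
    cols = [np.ones(len(df))]
    for c in covariate_names:
        if c not in df.columns:
            raise ValueError(f"covariate {c!r} missing from phenotype table")
        cols.append(df[c].to_numpy(dtype=float))
    X = np.column_stack(cols)
    extra = np.asarray(extra, dtype=float)
    if extra.ndim == 1:
        extra = extra[:, np.newaxis]
    if extra.shape[1]:
        X = np.column_stack([X, extra])
    return X


def grs_association(
    scores: ScoreVector,
    phenotypes: pd.DataFrame,
    covariate_names: Sequence[str] = (),
    subtype_filter: str = "all",
) -> AssocResult:
    """Odds ratio of case status per unit of the (weighted) score.

    For a weighted score this is the odds ratio per SD of genetically
    predicted height.  Subtype analyses keep all controls and only cases of
    the requested histology.
    """
    df = _merged_frame(scores.subject_ids, scores.to_frame(), phenotypes, subtype_filter)
    y = df["status"].to_numpy(dtype=float)
    X = _design(df, covariate_names, df["grs"].to_numpy(dtype=float))
    fit = fit_logistic(y, X)
    return _wald(
        "grs",
        fit.beta[-1],
        fit.se[-1],
        int(y.sum()),
        int((1 - y).sum()),
    )


@dataclass
class TertileAssociation:
    q2: AssocResult
    q3: AssocResult
    trend: AssocResult
    trend_method: str = "wald"


def _score_test(y: np.ndarray, X0: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Rao score test for adding column ``x`` to a fitted null design ``X0``."""
    fit0 = fit_logistic(y, X0)
    mu = expit(X0 @ fit0.beta)
    w = mu * (1.0 - mu)
    U = float(x @ (y - mu))
    X0w = X0 * w[:, np.newaxis]
    A = np.linalg.solve(X0w.T @ X0, X0.T @ (w * x))
    V = float((x * w) @ x - (X0.T @ (w * x)) @ A)
    stat = U * U / V
    return stat, float(chi2.sf(stat, 1))


def tertile_association(
    tertiles: TertileAssignment,
    phenotypes: pd.DataFrame,
    covariate_names: Sequence[str] = (),
    subtype_filter: str = "all",
    trend: str = "wald",
) -> TertileAssociation:
    """Per-tertile odds ratios (Q1 reference) and a trend test.

    Q2 and Q3 enter as indicators against Q1; the trend test treats the
    ordinal coding 0/1/2 as a single covariate, by default as a Wald test
    (``trend="score"`` uses the Rao score test instead).
    """
    values = tertiles.to_frame()
    df = _merged_frame(tertiles.subject_ids, values, phenotypes, subtype_filter)
    y = df["status"].to_numpy(dtype=float)
    cat = df["grs_tertile"]
    d_q2 = (cat == "Q2").to_numpy(dtype=float)
    d_q3 = (cat == "Q3").to_numpy(dtype=float)
    ordinal = cat.map({"Q1": 0.0, "Q2": 1.0, "Q3": 2.0}).to_numpy(dtype=float)
    n_cases, n_controls = int(y.sum()), int((1 - y).sum())

    X_ind = _design(df, covariate_names, np.column_stack([d_q2, d_q3]))
    fit = fit_logistic(y, X_ind)
    q2 = _wald("Q2", fit.beta[-2], fit.se[-2], n_cases, n_controls)
    q3 = _wald("Q3", fit.beta[-1], fit.se[-1], n_cases, n_controls)

    if trend == "wald":
        X_tr = _design(df, covariate_names, ordinal)
        ft = fit_logistic(y, X_tr)
        tr = _wald("trend", ft.beta[-1], ft.se[-1], n_cases, n_controls)
    elif trend == "score":
        X0 = _design(df, covariate_names, np.empty((len(df), 0)))
        stat, p = _score_test(y, X0, ordinal)
        # report the ordinal Wald coefficient alongside the score p-value
        X_tr = _design(df, covariate_names, ordinal)
        ft = fit_logistic(y, X_tr)
        tr = AssocResult("trend", float(ft.beta[-1]), float(ft.se[-1]), p, n_cases, n_controls)
    else:
        raise ValueError(f"trend must be 'wald' or 'score', got {trend!r}")
    return TertileAssociation(q2, q3, tr, trend)


def rcs_basis(x: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    """Restricted cubic spline basis (Harrell / Durrleman-Simon form).

    Returns columns ``[x, s_1(x), ..., s_{k-2}(x)]`` for ``k`` strictly
    increasing knots ``t``::

        s_j(x) = [ (x - t_j)+^3
                   - (x - t_{k-1})+^3 (t_k - t_j) / (t_k - t_{k-1})
                   + (x - t_k)+^3 (t_{k-1} - t_j) / (t_k - t_{k-1}) ]
                 / (t_k - t_1)^2

    The construction is twice continuously differentiable and linear beyond
    the boundary knots.
    """
    t = np.asarray(knots, dtype=float)
    if t.ndim != 1 or t.size < 3:
        raise ValueError("need at least 3 knots")
    if np.any(np.diff(t) <= 0):
        raise ValueError("knots must be strictly increasing and distinct")
    x = np.asarray(x, dtype=float)
    k = t.size
    scale = (t[-1] - t[0]) ** 2

    def pos3(v: np.ndarray) -> np.ndarray:
        return np.clip(v, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        term = (
            pos3(x - t[j])
            - pos3(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + pos3(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        ) / scale
        cols.append(term)
    return np.column_stack(cols)


@dataclass(frozen=True)
class NonlinearityTest:
    statistic: float
    df: int
    p: float
    knots: tuple[float, ...]


def nonlinearity_test(
    scores: ScoreVector,
    phenotypes: pd.DataFrame,
    covariate_names: Sequence[str] = (),
    n_knots: int = 4,
    knot_quantiles: Sequence[float] = (0.05, 0.35, 0.65, 0.95),
    subtype_filter: str = "all",
) -> NonlinearityTest:
    """Likelihood-ratio test of spline vs linear score effect.

    Knots sit at the stated quantiles of the score (Harrell's default
    placement for 4 knots); the test has ``n_knots - 2`` degrees of freedom.
    A small p-value indicates departure from log-linearity of risk in the
    genetically predicted height.
    """
    if n_knots != len(knot_quantiles):
        raise ValueError("n_knots must match the number of knot quantiles")
    df = _merged_frame(scores.subject_ids, scores.to_frame(), phenotypes, subtype_filter)
    y = df["status"].to_numpy(dtype=float)
    x = df["grs"].to_numpy(dtype=float)
    knots = np.quantile(x, knot_quantiles)
    if np.any(np.diff(knots) <= 0):
        raise ValueError("degenerate score distribution: knots are not distinct")
    basis = rcs_basis(x, knots)
    X_lin = _design(df, covariate_names, x)
    X_full = _design(df, covariate_names, basis)
    fit_lin = fit_logistic(y, X_lin)
    fit_full = fit_logistic(y, X_full)
    stat = max(0.0, 2.0 * (fit_full.loglik - fit_lin.loglik))
    dof = n_knots - 2
    return NonlinearityTest(stat, dof, float(chi2.sf(stat, dof)), tuple(knots))
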