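"""Top-quintile labelling and the 19-indicator logistic regression.

The outcome is membership in the top 20% of antibiotic recipients (most
courses by age 5); the model is a Bernoulli-logit regression of that label
on an intercept plus one indicator per PMCA body system, fitted by
iteratively reweighted least squares (Newton's method on the log-likelihood).
Inference is Wald: OR = exp(beta), CI = exp(beta +/- z * se), two-sided
p-values against the normal reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SEPARATION_BOUND = 15.0


class SeparationError(RuntimeError):
    """Complete or quasi-separation: a coefficient is diverging."""


@dataclass
class LogisticFit:
    coef: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    converged: bool
    n_iter: int
    loglik: float
    n: int
    names: list[str]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.names, "beta": self.coef, "se": self.se})


def label_top_quantile(per_child: pd.Series | np.ndarray, q: float = 0.20, weights=None):
    """Binary top-q labels on counts: 1 iff count > t, where t is the smallest
    count value whose strict upper-tail (weight) fraction is <= q.

    Deterministic and tie-safe: all children sharing the boundary count get
    the same label (0), so the labelled fraction is <= q.  If all counts are
    equal no child is labelled.
    """
    counts = np.asarray(per_child, dtype=float)
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    w = np.ones(len(counts)) if weights is None else np.asarray(weights, dtype=float)
    total = w.sum()
    values = np.unique(counts)  # ascending
    # tail(> v) as a function of the candidate threshold v
    for v in values:
        tail = w[counts > v].sum() / total
        if tail <= q:
            return (counts > v).astype(int)
    return np.zeros(len(counts), dtype=int)  # unreachable: tail(>max) = 0


def fit_logistic_irls(
    design: np.ndarray | pd.DataFrame,
    labels: np.ndarray | pd.Series,
    tol: float = 1e-8,
    max_iter: int = 50,
    names: list[str] | None = None,
) -> LogisticFit:
    """Maximum-likelihood Bernoulli-logit fit by IRLS (Newton).

    Iterates beta <- beta + (X'WX)^-1 X'(y - p) with W = diag(p(1-p)) until
    the gradient norm falls below ``tol``.  Raises on rank-deficient designs
    and on separation (any |beta| exceeding 15 during iteration, reported
    with the offending covariate's name).
    """
    if isinstance(design, pd.DataFrame):
        names = names or list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
    y = np.asarray(labels, dtype=float)
    n, p = X.shape
    names = names or [f"x{j}" for j in range(p)]
    if len(y) != n:
        raise ValueError("design and labels must align")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("labels must be binary")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")

    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu)
        wdiag = mu * (1.0 - mu)
        H = X.T @ (X * wdiag[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as e:
            raise SeparationError(
                "singular information matrix during IRLS (fitted probabilities "
                "degenerate); check for separation"
            ) from e
        beta = beta + step
        over = np.abs(beta) > SEPARATION_BOUND
        if over.any():
            bad = [names[j] for j in np.nonzero(over)[0]]
            raise SeparationError(
                f"complete or quasi-separation detected: coefficient(s) {bad} "
                f"exceeded |beta| = {SEPARATION_BOUND} during iteration"
            )
        if np.linalg.norm(X.T @ (y - 1.0 / (1.0 + np.exp(-(X @ beta))))) < tol:
            converged = True
            break

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    wdiag = mu * (1.0 - mu)
    H = X.T @ (X * wdiag[:, None])
    cov = np.linalg.inv(H)
    cov = (cov + cov.T) / 2
    loglik = float(y @ eta - np.log1p(np.exp(eta)).sum())
    return LogisticFit(
        coef=beta,
        se=np.sqrt(np.diag(cov)),
        cov=cov,
        converged=converged,
        n_iter=it,
        loglik=loglik,
        n=n,
        names=list(names),
    )


def odds_ratios(fit: LogisticFit, alpha: float = 0.05) -> pd.DataFrame:
    """Per-term OR, Wald CI, and two-sided p-value from a converged fit."""
    if not fit.converged:
        raise ValueError("fit did not converge; odds ratios not reported")
    z = stats.norm.ppf(1 - alpha / 2)
    wald = fit.coef / fit.se
    return pd.DataFrame(
        {
            "term": fit.names,
            "beta": fit.coef,
            "se": fit.se,
            "odds_ratio": np.exp(fit.coef),
            "ci_lo": np.exp(fit.coef - z * fit.se),
            "ci_hi": np.exp(fit.coef + z * fit.se),
            "p": 2 * stats.norm.sf(np.abs(wald)),
        }
    )


def highuse_regression(
    per_child_counts: pd.Series,
    condition_flags: pd.DataFrame,
    q: float = 0.20,
    label_weights=None,
) -> tuple[LogisticFit, pd.DataFrame]:
    """Label the top-q recipients and fit the all-systems logistic model.

    ``condition_flags``: boolean child x body-system matrix indexed by
    child_id, aligned to ``per_child_counts``.  Labels default to unweighted
    counts (pass ``label_weights`` for the weighted variant); the regression
    itself is unweighted.
    """
    flags = condition_flags.loc[per_child_counts.index]
    constant = [c for c in flags.columns if flags[c].nunique() < 2]
    if constant:
        logger.warning(
            "dropping %d constant condition indicator(s) from the design: %s",
            len(constant), constant,
        )
        flags = flags.drop(columns=constant)
    labels = label_top_quantile(per_child_counts.to_numpy(), q=q, weights=label_weights)
    X = np.column_stack([np.ones(len(flags)), flags.to_numpy(dtype=float)])
    names = ["intercept", *flags.columns]
    fit = fit_logistic_irls(X, labels, names=names)
    return fit, odds_ratios(fit)
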