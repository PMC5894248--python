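"""Conditional logistic regression over individually matched sets.

Each stratum holds one case and up to k matched controls.  Conditioning
on "exactly one case per stratum" eliminates the stratum-specific
intercept: the contribution of stratum s is a softmax over its members,

    log P(case = observed | stratum) = x_case . beta - log sum_j exp(x_j . beta),

which is exact for this design.  Covariates constant within every
stratum (the matching variables when matching is exact) carry no
information and are dropped with a warning before fitting; residual
within-stratum variation — e.g. age inside a ±5-year caliper — keeps a
matched covariate estimable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

Z975 = 1.959963984540054


@dataclass
class Stratum:
    """One matched set: outcome vector (exactly one 1) and covariate rows."""

    stratum_id: int
    y: np.ndarray  # (m,) with exactly one 1
    X: np.ndarray  # (m, k)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != len(self.y):
            raise ValueError("y/X length mismatch")
        if int(self.y.sum()) != 1 or set(np.unique(self.y)) - {0.0, 1.0}:
            raise ValueError("stratum must contain exactly one case (y has one 1)")
        if len(self.y) < 2:
            raise ValueError("stratum needs at least one control")


@dataclass
class ConditionalFit:
    beta: np.ndarray
    cov: np.ndarray
    se: np.ndarray
    or_: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    loglik: float
    converged: bool
    n_informative_strata: int
    term_names: list[str]
    dropped_terms: list[str]


class NoInformativeStrataError(ValueError):
    pass


def conditional_loglik(beta, strata: list[Stratum]) -> float:
    """Sum over strata of x_case . beta - log sum_j exp(x_j . beta)."""
    beta = np.asarray(beta, dtype=float)
    total = 0.0
    for s in strata:
        if s.X.shape[1] != len(beta):
            raise ValueError(
                f"beta has {len(beta)} components but stratum {s.stratum_id} has "
                f"{s.X.shape[1]} covariates"
            )
        eta = s.X @ beta
        total += float(eta @ s.y - logsumexp(eta))
    return total


def _grad_hess(beta: np.ndarray, strata: list[Stratum]) -> tuple[float, np.ndarray, np.ndarray]:
    k = len(beta)
    ll = 0.0
    grad = np.zeros(k)
    hess = np.zeros((k, k))
    for s in strata:
        eta = s.X @ beta
        lse = logsumexp(eta)
        p = np.exp(eta - lse)
        xbar = p @ s.X
        ll += float(eta @ s.y - lse)
        grad += s.y @ s.X - xbar
        hess -= (s.X * p[:, None]).T @ s.X - np.outer(xbar, xbar)
    return ll, grad, hess


def informative_columns(strata: list[Stratum]) -> np.ndarray:
    """Boolean mask of covariates varying within at least one stratum."""
    k = strata[0].X.shape[1]
    varies = np.zeros(k, dtype=bool)
    for s in strata:
        varies |= np.ptp(s.X, axis=0) > 0
    return varies


def fit_conditional_logistic(
    strata: list[Stratum],
    term_names: list[str] | None = None,
    max_iter: int = 100,
    grad_tol: float = 1e-8,
) -> ConditionalFit:
    """Newton–Raphson maximization of the one-case-per-stratum
    conditional likelihood, with step-halving.

    Covariates constant within every stratum are dropped (their
    coefficients are not identified); strata with no within-stratum
    variation in the remaining covariates contribute a constant to the
    likelihood and are counted out of ``n_informative_strata``.
    Within-stratum separation — the phenotype perfectly predicting the
    case — surfaces as a flagged non-converged fit.
    """
    if not strata:
        raise NoInformativeStrataError("no strata supplied")
    k_full = strata[0].X.shape[1]
    names = term_names or [f"x{j}" for j in range(k_full)]
    keep = informative_columns(strata)
    dropped = [names[j] for j in range(k_full) if not keep[j]]
    if dropped:
        logger.warning("dropping covariates constant within every stratum: %s", dropped)
    if not keep.any():
        raise NoInformativeStrataError("no covariate varies within any stratum")
    reduced = [
        Stratum(s.stratum_id, s.y, s.X[:, keep]) for s in strata
    ]
    informative = [s for s in reduced if np.any(np.ptp(s.X, axis=0) > 0)]
    n_informative = len(informative)
    if n_informative == 0:
        raise NoInformativeStrataError("no informative strata after dropping constants")

    k = int(keep.sum())
    beta = np.zeros(k)
    ll, grad, hess = _grad_hess(beta, informative)
    converged = False
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < grad_tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            break
        new_beta = beta + step
        new_ll = conditional_loglik(new_beta, informative)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll = conditional_loglik(new_beta, informative)
            halvings += 1
        if new_ll - ll <= (abs(ll) + 1.0) * 1e-14:
            # likelihood at its floating-point floor; accept if the
            # gradient is small on the likelihood's own scale (covariates
            # such as age in years keep the raw gradient above grad_tol)
            converged = np.max(np.abs(grad)) < 1e-6 * (abs(ll) + 1.0)
            if new_ll >= ll:
                beta = new_beta
                ll, grad, hess = _grad_hess(beta, informative)
            break
        beta = new_beta
        ll, grad, hess = _grad_hess(beta, informative)
    if np.max(np.abs(beta)) > 30 or not np.all(np.isfinite(beta)):
        converged = False  # separation: MLE at infinity
    if ll > -1e-6:
        converged = False  # perfect prediction of every informative stratum
    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
        converged = False
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        z = beta / se
        p = 2 * stats.norm.sf(np.abs(z))
        ci_low, ci_high = np.exp(beta - Z975 * se), np.exp(beta + Z975 * se)
    fit = ConditionalFit(
        beta=beta,
        cov=cov,
        se=se,
        or_=np.exp(beta),
        ci_low=ci_low,
        ci_high=ci_high,
        p=p,
        loglik=ll,
        converged=converged,
        n_informative_strata=n_informative,
        term_names=[names[j] for j in range(k_full) if keep[j]],
        dropped_terms=dropped,
    )
    return fit


def build_strata(
    matched_sets: pd.DataFrame,
    covariates: pd.DataFrame,
    columns: list[str],
) -> tuple[list[Stratum], list[str]]:
    """Assemble strata from a long (stratum_id, role, subject_id) table.

    ``covariates`` is indexed by subject_id; non-numeric columns are
    factor-coded against their first sorted level (levels taken over the
    full table so coding is stable across strata).  Strata whose case or
    controls are missing from ``covariates`` are skipped with a warning.
    """
    # stable factor coding over the full covariate table
    design_cols: list[tuple[str, pd.Series]] = []
    for c in columns:
        v = covariates[c]
        if pd.api.types.is_numeric_dtype(v):
            design_cols.append((c, v.astype(float)))
        else:
            for lev in sorted(v.unique())[1:]:
                design_cols.append((f"{c}[{lev}]", (v == lev).astype(float)))
    names = [nm for nm, _ in design_cols]
    design = pd.concat([s.rename(nm) for nm, s in design_cols], axis=1)

    strata = []
    n_skipped = 0
    for sid, grp in matched_sets.groupby("stratum_id", sort=True):
        ids = grp["subject_id"].tolist()
        if (
            not set(ids) <= set(design.index)
            or (grp["role"] == "case").sum() != 1
            or (grp["role"] == "control").sum() == 0
        ):
            n_skipped += 1
            continue
        y = (grp["role"] == "case").to_numpy(dtype=float)
        X = design.loc[ids].to_numpy(dtype=float)
        strata.append(Stratum(int(sid), y, X))
    if n_skipped:
        logger.warning(
            "%d strata skipped (missing case, missing controls, or missing covariates)",
            n_skipped,
        )
    return strata, names
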