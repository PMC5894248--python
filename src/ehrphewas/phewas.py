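"""Phenome-wide association scan.

For every phecode, each subject is classified as a phenotype *case*
(codes mapping into the phecode, including positional descendants, on at
least two distinct days), a *control* (no codes mapping into the
phecode's related set — the phecode, its descendants, and its exclusion
range), or *excluded* (anything in between: a single-instance code,
which may be a rule-out or billing error, or a related-range code
without two target dates).  Phecodes with at least ``min_cases``
phenotype cases (default 20) are "testable"; each gets a covariate-
adjusted unconditional logistic regression of phenotype status on the
exposure, and Benjamini–Hochberg adjustment is applied across exactly
the testable set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .phecode_map import PhecodeMap, descendant_closure, related_phecodes

logger = logging.getLogger(__name__)

STATUS_CASE = 1
STATUS_CONTROL = 0
STATUS_EXCLUDED = -1

RESULT_COLUMNS = [
    "phecode", "description", "category", "n_case", "n_control",
    "beta", "se", "odds_ratio", "ci_low", "ci_high", "p", "fdr_p", "converged",
]

Z975 = 1.959963984540054  # Phi^{-1}(0.975)


# ---------------------------------------------------------------------------
# phenotype status assignment
# ---------------------------------------------------------------------------

def assign_phecode_status(
    events: pd.DataFrame, phecode: str, pmap: PhecodeMap
) -> pd.Series:
    """Classify every subject in ``events`` for one phecode.

    Returns a Series indexed by subject_id with values in
    {STATUS_CASE, STATUS_CONTROL, STATUS_EXCLUDED}.  Subjects absent
    from ``events`` are (vacuously) controls and do not appear.
    """
    wide = assign_statuses(events, [phecode], pmap)
    return wide[phecode]


def assign_statuses(
    events: pd.DataFrame, phecodes: list[str], pmap: PhecodeMap
) -> pd.DataFrame:
    """Vectorized status assignment for many phecodes at once.

    Returns a subjects × phecodes int8 DataFrame (1 case / 0 control /
    -1 excluded).  Only ICD-9 events that map into the phecode map
    contribute; unmapped codes are ignored.
    """
    for p in phecodes:
        if p not in pmap:
            raise KeyError(f"phecode {p!r} not in map")
    ev = events[events["vocabulary"] == "ICD9CM"]
    icd_lookup = {e.icd9_code: e.phecode for e in pmap.entries}
    ev = ev.assign(phecode=ev["code"].map(icd_lookup)).dropna(subset=["phecode"])
    dates = pd.to_datetime(ev["date"]).dt.normalize()
    # distinct (subject, phecode) date counts
    counts = (
        ev.assign(date=dates)
        .drop_duplicates(["subject_id", "phecode", "date"])
        .groupby(["subject_id", "phecode"])
        .size()
        .unstack(fill_value=0)
    )
    subjects = counts.index
    out = pd.DataFrame(
        STATUS_CONTROL, index=subjects, columns=phecodes, dtype="int8"
    )
    for target in phecodes:
        closure = descendant_closure(target, pmap)
        related = related_phecodes(target, pmap)
        present = [c for c in counts.columns if c in closure]
        n_target = counts[present].sum(axis=1) if present else pd.Series(0, index=subjects)
        rel_present = [c for c in counts.columns if c in related]
        any_related = (
            (counts[rel_present].sum(axis=1) > 0)
            if rel_present
            else pd.Series(False, index=subjects)
        )
        col = np.full(len(subjects), STATUS_EXCLUDED, dtype="int8")
        col[(n_target >= 2).to_numpy()] = STATUS_CASE
        col[(~any_related).to_numpy()] = STATUS_CONTROL
        out[target] = col
    out.index.name = "subject_id"
    return out


# ---------------------------------------------------------------------------
# logistic regression (IRLS)
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    beta: np.ndarray
    cov: np.ndarray
    converged: bool
    n_iter: int
    loglik: float


class DegenerateOutcomeError(ValueError):
    """The outcome vector contains a single class."""


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1+exp(eta)), stable via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    max_iter: int = 50,
    score_tol: float = 1e-8,
    ll_tol: float = 1e-10,
) -> LogisticFit:
    """Maximum-likelihood logistic regression via iteratively reweighted
    least squares (Newton scoring).

    ``X`` must include the intercept column.  Convergence when the max
    absolute score drops below ``score_tol`` or the relative
    log-likelihood change below ``ll_tol``.  (Quasi-)separation or
    failure to converge is reported through ``converged=False`` — no
    silent penalization.  Wald covariance is the inverse observed
    information at the optimum.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.min() == y.max():
        raise DegenerateOutcomeError("outcome has a single class")
    n, k = X.shape
    beta = np.zeros(k)
    ll = _loglik(y, X @ beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        score = X.T @ (y - p)
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        new_beta = beta + step
        new_ll = _loglik(y, X @ new_beta)
        # step-halving if the likelihood worsens (rare; heavy separation)
        halvings = 0
        while new_ll < ll and halvings < 20:
            step *= 0.5
            new_beta = beta + step
            new_ll = _loglik(y, X @ new_beta)
            halvings += 1
        beta = new_beta
        if ll != 0 and abs(new_ll - ll) < ll_tol * abs(ll):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
        converged = False
    # separation guard: runaway coefficients mean the MLE is at infinity
    if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 30:
        converged = False
    return LogisticFit(beta=beta, cov=cov, converged=converged, n_iter=it, loglik=_loglik(y, X @ beta))


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adj(i) = min_{j >= i} p(j) * m / j over the sorted p-values, capped
    at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def count_fdr_significant(results: pd.DataFrame, alpha: float) -> int:
    """Number of results with BH-adjusted p <= alpha."""
    if len(results) == 0:
        return 0
    return int((results["fdr_p"] <= alpha).sum())


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

@dataclass
class RegressionSpec:
    """One PheWAS analysis: exposure, covariates, testability and FDR knobs."""

    exposure: str
    covariates: list[str] = field(default_factory=list)
    min_cases: int = 20
    fdr_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.min_cases < 1:
            raise ValueError("min_cases must be >= 1")
        if not (0 < self.fdr_alpha < 1):
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if self.exposure in self.covariates:
            raise ValueError("exposure must not also be a covariate")


def _design(subjects: pd.DataFrame, columns: list[str]) -> tuple[np.ndarray, list[str]]:
    """Numeric design matrix with intercept; non-numeric columns are
    factor-coded against their first sorted level."""
    cols = [np.ones(len(subjects))]
    names = ["intercept"]
    for c in columns:
        v = subjects[c]
        if not pd.api.types.is_numeric_dtype(v):
            levels = sorted(v.unique())
            for lev in levels[1:]:
                cols.append((v == lev).to_numpy(dtype=float))
                names.append(f"{c}[{lev}]")
            continue
        cols.append(v.to_numpy(dtype=float))
        names.append(c)
    return np.column_stack(cols), names


def _drop_constant(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop non-intercept columns constant in-sample (rank guard)."""
    keep = [0] + [j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0]
    dropped = [names[j] for j in range(1, X.shape[1]) if j not in keep]
    if dropped:
        logger.info("dropping constant design columns: %s", dropped)
    return X[:, keep], [names[j] for j in keep]


def run_phewas(
    statuses: pd.DataFrame,
    subjects: pd.DataFrame,
    spec: RegressionSpec,
    pmap: PhecodeMap | None = None,
) -> pd.DataFrame:
    """Fit one adjusted logistic regression per testable phecode.

    Parameters
    ----------
    statuses : subjects × phecodes int8 frame from :func:`assign_statuses`
        (1 case / 0 control / -1 excluded).
    subjects : DataFrame indexed by subject_id carrying the exposure and
        covariate columns for every subject in ``statuses``.
    spec : exposure/covariates/min_cases/fdr_alpha.
    pmap : optional map supplying description/category labels.

    Returns
    -------
    DataFrame with one row per testable phecode (columns
    :data:`RESULT_COLUMNS`), BH-adjusted across the converged fits of
    this run, sorted by fdr_p.
    """
    subjects = subjects.loc[statuses.index]
    X_full, full_names = _design(subjects, [spec.exposure] + list(spec.covariates))
    status_mat = statuses.to_numpy()
    rows = []
    for col_idx, phecode in enumerate(statuses.columns):
        status = status_mat[:, col_idx]
        mask = status != STATUS_EXCLUDED
        y = (status[mask] == STATUS_CASE).astype(float)
        n_case = int(y.sum())
        n_control = int(len(y) - y.sum())
        if n_case < spec.min_cases:
            continue
        X, names = _drop_constant(X_full[mask], full_names)
        exposure_idx = next(
            (j for j, nm in enumerate(names) if nm == spec.exposure or nm.startswith(spec.exposure + "[")),
            None,
        )
        entry = pmap.entry_for_phecode(phecode) if (pmap is not None and phecode in pmap) else None
        if exposure_idx is None or n_control == 0:
            fit, beta, se = None, np.nan, np.nan
            converged = False
        else:
            try:
                fit = fit_logistic(y, X)
            except DegenerateOutcomeError:
                fit, converged = None, False
                beta = se = np.nan
            else:
                beta = fit.beta[exposure_idx]
                se = float(np.sqrt(fit.cov[exposure_idx, exposure_idx]))
                converged = fit.converged and np.isfinite(se)
        if converged and se > 0:
            z = beta / se
            p = float(2 * stats.norm.sf(abs(z)))
            with np.errstate(over="ignore"):
                ci_low, ci_high = np.exp(beta - Z975 * se), np.exp(beta + Z975 * se)
        else:
            p = np.nan
            ci_low = ci_high = np.nan
        rows.append(
            {
                "phecode": phecode,
                "description": entry.description if entry else "",
                "category": entry.category if entry else "",
                "n_case": n_case,
                "n_control": n_control,
                "beta": beta,
                "se": se,
                "odds_ratio": np.exp(beta) if np.isfinite(beta) else np.nan,
                "ci_low": ci_low,
                "ci_high": ci_high,
                "p": p,
                "fdr_p": np.nan,
                "converged": converged,
            }
        )
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if len(results) == 0:
        logger.warning("no testable phecodes (min_cases=%d)", spec.min_cases)
        return results
    ok = results["converged"] & results["p"].notna()
    if ok.any():
        results.loc[ok, "fdr_p"] = bh_adjust(results.loc[ok, "p"].to_numpy())
    logger.info(
        "PheWAS: %d testable phenotypes, %d converged, %d FDR-significant at %.3g",
        len(results), int(ok.sum()), count_fdr_significant(results.dropna(subset=["fdr_p"]), spec.fdr_alpha),
        spec.fdr_alpha,
    )
    return results.sort_values("fdr_p", na_position="last", kind="stable").reset_index(drop=True)
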