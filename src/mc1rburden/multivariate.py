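"""Covariate-adjusted association via in-package logistic regression.

Case/control status is regressed on carriage of a variant class plus the
four ordinal pigmentation covariates (hair colour, eye colour, Fitzpatrick
skin type, nevus count), each entered as a single ordinal score by default.
The fit is maximum likelihood by iteratively reweighted least squares
(IRLS) with Wald confidence intervals exp(beta +- z*SE).  Complete
separation is detected and reported rather than silently diverging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .classify import VariantClass
from .variants import VariantRecord

COVARIATES = ("hair_colour", "eye_colour", "skin_type", "nevus_count")


@dataclass(frozen=True)
class SubjectRecord:
    """One diploid subject: two haplotypes of variant identifiers plus
    ordinal pigmentation covariates (``None`` = missing)."""

    id: str
    status: str  # "case" | "control"
    haplotype1: tuple[str, ...] = ()
    haplotype2: tuple[str, ...] = ()
    hair_colour: Optional[int] = None
    eye_colour: Optional[int] = None
    skin_type: Optional[int] = None
    nevus_count: Optional[int] = None
    age_at_diagnosis: Optional[float] = None

    def __post_init__(self) -> None:
        if self.status not in ("case", "control"):
            raise ValueError(f"{self.id}: status must be 'case' or 'control'")

    @property
    def is_case(self) -> bool:
        return self.status == "case"

    def allele_count(self, members: frozenset[str] | set[str]) -> int:
        """Number of haplotypes carrying any variant id in ``members``."""
        return sum(
            1
            for hap in (self.haplotype1, self.haplotype2)
            if any(v in members for v in hap)
        )


@dataclass(frozen=True)
class LogisticFit:
    terms: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    odds_ratios: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_wald: np.ndarray
    converged: bool
    iterations: int
    log_likelihood: float
    loglik_trace: tuple[float, ...] = ()
    separation: bool = False

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "se": self.standard_errors,
                "odds_ratio": self.odds_ratios,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p_wald,
            },
            index=list(self.terms),
        )


def encode_design(
    subjects: Sequence[SubjectRecord],
    class_of_variant: Mapping[str, VariantClass | str],
    genetic_terms: Mapping[str, Iterable[VariantClass | str]],
    covariates: Sequence[str] = COVARIATES,
    coding: str = "carriage",
) -> tuple[pd.DataFrame, np.ndarray, int]:
    """Build the design matrix and response for a class-adjusted fit.

    Each entry of ``genetic_terms`` maps a column name to the set of
    variant classes whose carriage (default) or allele dosage forms the
    predictor.  Ordinal covariates enter as their integer codes.  Subjects
    with any missing requested covariate are dropped (complete-case);
    the number dropped is returned alongside the matrix.
    """
    if coding not in ("carriage", "dosage"):
        raise ValueError(f"unknown genetic coding {coding!r}")
    class_of = {k: VariantClass(v) for k, v in class_of_variant.items()}
    term_members: dict[str, frozenset[str]] = {}
    for name, classes in genetic_terms.items():
        wanted = {VariantClass(c) for c in classes}
        term_members[name] = frozenset(
            vid for vid, k in class_of.items() if k in wanted
        )
    rows, y = [], []
    n_dropped = 0
    for s in subjects:
        covs = [getattr(s, c) for c in covariates]
        if any(v is None for v in covs):
            n_dropped += 1
            continue
        genetic = []
        for name in term_members:
            n = s.allele_count(term_members[name])
            genetic.append(min(n, 1) if coding == "carriage" else n)
        rows.append(covs + genetic)
        y.append(1 if s.is_case else 0)
    X = pd.DataFrame(rows, columns=list(covariates) + list(term_members))
    return X, np.asarray(y, dtype=float), n_dropped


class SeparationError(RuntimeError):
    """Complete (or quasi-complete) separation: the MLE does not exist."""


def log_likelihood(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ beta
    # log(1+e^eta) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    design: pd.DataFrame | np.ndarray,
    response: Sequence[float] | np.ndarray,
    tolerance: float = 1e-8,
    max_iter: int = 50,
    add_intercept: bool = True,
    level: float = 0.95,
) -> LogisticFit:
    """Maximum-likelihood logistic fit via IRLS.

    Convergence is declared when the largest coefficient change falls
    below ``tolerance``.  Non-convergence raises ``RuntimeError`` unless
    caused by separation, which raises :class:`SeparationError` naming the
    diagnostic (coefficients running away with fitted probabilities at the
    boundary).
    """
    if isinstance(design, pd.DataFrame):
        terms = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        terms = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(response, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("design/response shape mismatch")
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        terms = ["intercept"] + terms
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more observations ({n}) than terms ({k})")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient (duplicated column?)")

    beta = np.zeros(k)
    trace = [log_likelihood(beta, X, y)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ Xw, X.T @ (w * z))
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                f"weighted normal equations singular at iteration {it}"
            ) from exc
        step = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        trace.append(log_likelihood(beta, X, y))
        if step < tolerance:
            converged = True
            break
    mu = expit(X @ beta)
    boundary = np.mean((mu < 1e-8) | (mu > 1 - 1e-8))
    separated = bool(np.max(np.abs(beta)) > 15 and boundary > 0)
    if not converged:
        if separated:
            raise SeparationError(
                "complete separation suspected: coefficients diverging "
                f"(max |beta| = {np.max(np.abs(beta)):.1f}) with fitted "
                "probabilities at the boundary"
            )
        raise RuntimeError(f"IRLS did not converge in {max_iter} iterations")

    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    se = np.sqrt(np.diag(cov))
    z_crit = stats.norm.ppf(0.5 + level / 2)
    zstat = beta / se
    return LogisticFit(
        terms=tuple(terms),
        coefficients=beta,
        standard_errors=se,
        odds_ratios=np.exp(beta),
        ci_low=np.exp(beta - z_crit * se),
        ci_high=np.exp(beta + z_crit * se),
        p_wald=2 * stats.norm.sf(np.abs(zstat)),
        converged=converged,
        iterations=it,
        log_likelihood=trace[-1],
        loglik_trace=tuple(trace),
        separation=separated,
    )


@dataclass(frozen=True)
class AgeComparison:
    mean_with: float
    mean_without: float
    p: float
    n_with: int
    n_without: int


def compare_age_at_diagnosis(
    ages_with_class: Sequence[float], ages_without: Sequence[float]
) -> AgeComparison:
    """Welch (unequal-variance) two-sample comparison of diagnosis ages.

    Two identical degenerate groups (zero variance, equal means) return
    p = 1 by convention; a zero-variance difference in means returns p = 0.
    """
    a = np.asarray(ages_with_class, dtype=float)
    b = np.asarray(ages_without, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return AgeComparison(
        mean_with=float(a.mean()),
        mean_without=float(b.mean()),
        p=p,
        n_with=len(a),
        n_without=len(b),
    )
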