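"""Odds ratios for diagnosis combinations: 2x2 tables and adjusted fits.

For a combination X the cohort cross-tabulates carrier status against
in-hospital death:

                died    survived
    carriers      a        b
    others        c        d

The unadjusted odds ratio is ad/bc with a Wald 95% CI on the log scale,
exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)); tables containing a zero
cell get the Haldane-Anscombe +0.5 correction to every cell and are
flagged. The adjusted odds ratio comes from a maximum-likelihood
logistic regression (iteratively reweighted least squares, written out
here rather than delegated, since the fit is part of what this package
is for) of death on the carrier indicator controlling for age (years,
continuous), sex (reference: Male) and race (reference: White) — one
regression per rule.

``reconstruct_table`` inverts published summary percentages (coverage
and confidence at one decimal, plus the cohort totals N and D) back
into an integer 2x2 table. This is the consistency oracle used to check
reported odds ratios: the rounding of the printed percentages bounds
the achievable agreement at a few percent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .code_mapping import IndicatorMatrix

logger = logging.getLogger("ihtminer")

_Z975 = float(norm.ppf(0.975))
_SEPARATION_BOUND = 15.0


class EstimationError(ValueError):
    """Raised for infeasible tables or degenerate designs."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 combination-by-death counts (a, b: carriers; c, d: others)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            if getattr(self, name) < 0:
                raise EstimationError(f"negative cell {name} = {getattr(self, name)}")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def D(self) -> int:
        return self.a + self.c

    def swapped_rows(self) -> "ContingencyTable":
        return ContingencyTable(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class OddsRatio:
    value: float
    ci_low: float
    ci_high: float
    corrected: bool = False  # Haldane-Anscombe +0.5 applied

    def __post_init__(self) -> None:
        if not self.ci_low <= self.value <= self.ci_high:
            raise EstimationError("CI must bracket the point estimate")


@dataclass
class LogisticFit:
    """IRLS maximum-likelihood fit with observed-information standard errors."""

    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    deviance: float
    n_iter: int
    converged: bool
    separation_flag: bool
    n_obs: int

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        z = float(norm.ppf(0.5 + level / 2))
        return pd.DataFrame(
            {"low": self.params - z * self.bse, "high": self.params + z * self.bse}
        )


@dataclass
class EffectEstimate:
    """Unadjusted and covariate-adjusted odds ratios for one combination."""

    or_unadjusted: OddsRatio
    aor: float
    aor_ci: tuple[float, float]
    coefficients: pd.DataFrame  # columns: coef, se
    convergence_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.aor_ci[0] <= self.aor <= self.aor_ci[1]:
            raise EstimationError("aOR CI must bracket the point estimate")


def contingency_from_indicators(
    matrix: IndicatorMatrix, antecedent: Sequence[str]
) -> ContingencyTable:
    """Exact integer cross-tabulation of carrier status by death."""
    carrier = matrix.carriers(antecedent)
    died = matrix.died.astype(bool)
    a = int((carrier & died).sum())
    b = int((carrier & ~died).sum())
    c = int((~carrier & died).sum())
    d = int((~carrier & ~died).sum())
    return ContingencyTable(a, b, c, d)


def reconstruct_table(
    N: int, D: int, coverage_pct: float, confidence_pct: float
) -> ContingencyTable:
    """Invert printed (coverage %, confidence %) summaries to a 2x2 table.

    ``n1 = round(coverage * N / 100)`` carriers, of whom
    ``a = round(confidence * n1 / 100)`` died; the remaining cells follow
    from the cohort margins N and D. Implied negative cells mean the
    printed summaries are inconsistent with the margins.
    """
    if not 0 < coverage_pct <= 100:
        raise EstimationError("coverage must lie in (0, 100]")
    if not 0 <= confidence_pct <= 100:
        raise EstimationError("confidence must lie in [0, 100]")
    n1 = round(coverage_pct * N / 100.0)
    a = round(confidence_pct * n1 / 100.0)
    b = n1 - a
    c = D - a
    d = N - n1 - c
    for cell, value in (("a", a), ("b", b), ("c", c), ("d", d)):
        if value < 0:
            raise EstimationError(
                f"implied cell {cell} = {value} is negative; printed summaries "
                f"are infeasible for N={N}, D={D}"
            )
    return ContingencyTable(a, b, c, d)


def estimate_or(table: ContingencyTable) -> OddsRatio:
    """Cross-product odds ratio with a Wald CI on the log scale."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a == 0 and b == 0) or (c == 0 and d == 0) or (a == 0 and c == 0) or (b == 0 and d == 0):
        raise EstimationError("odds ratio undefined: an entire row or column is zero")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        logger.info("zero cell in 2x2 table; Haldane-Anscombe +0.5 applied")
    value = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(value)
    return OddsRatio(
        value=float(value),
        ci_low=float(np.exp(log_or - _Z975 * se)),
        ci_high=float(np.exp(log_or + _Z975 * se)),
        corrected=corrected,
    )


def _as_design(design, add_intercept: bool) -> pd.DataFrame:
    X = pd.DataFrame(design).copy()
    X.columns = [str(c) for c in X.columns]
    if add_intercept:
        if "intercept" in X.columns:
            raise EstimationError("design already contains an 'intercept' column")
        X.insert(0, "intercept", 1.0)
    return X.astype(float)


def fit_logistic(
    design,
    outcome,
    add_intercept: bool = True,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS.

    Converges when the deviance changes by less than ``tol`` (or after
    ``max_iter`` Newton steps); standard errors come from the inverse
    observed information. A coefficient wandering beyond +/-15 on the
    log-odds scale flags probable separation. Constant columns other
    than the intercept, or collinear columns, raise a rank-deficiency
    error naming the offending columns.
    """
    X = _as_design(design, add_intercept)
    y = np.asarray(outcome, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise EstimationError("outcome length does not match design rows")
    if n <= p:
        raise EstimationError(f"need more observations ({n}) than parameters ({p})")
    if not np.isin(y, (0.0, 1.0)).all():
        raise EstimationError("outcome must be 0/1")

    Xv = X.to_numpy()
    rank = np.linalg.matrix_rank(Xv)
    if rank < p:
        # Name the dependent columns via pivoted QR: the columns pivoted
        # past the numerical rank are the collinear ones.
        from scipy.linalg import qr

        _, R, piv = qr(Xv, mode="economic", pivoting=True)
        bad = sorted(X.columns[j] for j in piv[rank:])
        raise EstimationError(f"design is rank deficient; collinear columns: {bad}")

    beta = np.zeros(p)
    # Start the intercept at the empirical logit for faster, safer steps.
    if add_intercept or "intercept" in X.columns:
        ybar = min(max(y.mean(), 1e-6), 1 - 1e-6)
        beta[list(X.columns).index("intercept")] = np.log(ybar / (1 - ybar))

    def deviance_of(mu: np.ndarray) -> float:
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))

    dev = deviance_of(expit(Xv @ beta))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xv @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        WX = Xv * w[:, None]
        info = Xv.T @ WX
        try:
            proposal = np.linalg.solve(info, WX.T @ z)
        except np.linalg.LinAlgError as err:
            raise EstimationError(f"information matrix singular at iteration {it}") from err
        # Step-halve when the Newton proposal overshoots (rare, nearly
        # separated covariates make plain IRLS oscillate).
        new_dev = deviance_of(expit(Xv @ proposal))
        halvings = 0
        while new_dev > dev + 1e-10 and halvings < 30:
            proposal = 0.5 * (proposal + beta)
            new_dev = deviance_of(expit(Xv @ proposal))
            halvings += 1
        beta = proposal
        if abs(dev - new_dev) < tol:
            dev = new_dev
            converged = True
            break
        dev = new_dev

    mu = expit(Xv @ beta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    info = Xv.T @ (Xv * w[:, None])
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    separation = bool(np.any(np.abs(beta) > _SEPARATION_BOUND))
    if separation:
        logger.warning("possible separation: max |coefficient| = %.2f", np.abs(beta).max())
    return LogisticFit(
        params=pd.Series(beta, index=X.columns),
        bse=pd.Series(se, index=X.columns),
        cov=pd.DataFrame(cov, index=X.columns, columns=X.columns),
        deviance=dev,
        n_iter=it,
        converged=converged,
        separation_flag=separation,
        n_obs=n,
    )


#: Reference levels for covariate coding in adjusted models.
SEX_REFERENCE = "Male"
RACE_REFERENCE = "White"


def adjusted_design(matrix: IndicatorMatrix, antecedent: Sequence[str]) -> pd.DataFrame:
    """Design frame: carrier indicator + age + sex/race dummies."""
    carrier = matrix.carriers(antecedent).astype(float)
    X = pd.DataFrame({"carrier": carrier, "age": np.asarray(matrix.age, dtype=float)})
    for level in sorted(set(matrix.sex) - {SEX_REFERENCE}):
        X[f"sex_{level}"] = (matrix.sex == level).astype(float)
    for level in sorted(set(matrix.race) - {RACE_REFERENCE}):
        X[f"race_{level}"] = (matrix.race == level).astype(float)
    return X


def estimate_adjusted_or(
    matrix: IndicatorMatrix, antecedent: Sequence[str]
) -> EffectEstimate:
    """aOR for a combination, controlling for age, sex and race.

    One logistic model per combination, with the carrier indicator as
    the main independent variable; the unadjusted OR from the same
    matrix is bundled alongside.
    """
    table = contingency_from_indicators(matrix, antecedent)
    if table.a + table.b == 0:
        raise EstimationError(f"no carriers of {tuple(antecedent)}; aOR infeasible")
    unadjusted = estimate_or(table)

    X = adjusted_design(matrix, antecedent)
    fit = fit_logistic(X, matrix.died)
    coef = float(fit.params["carrier"])
    se = float(fit.bse["carrier"])
    return EffectEstimate(
        or_unadjusted=unadjusted,
        aor=float(np.exp(coef)),
        aor_ci=(float(np.exp(coef - _Z975 * se)), float(np.exp(coef + _Z975 * se))),
        coefficients=pd.DataFrame({"coef": fit.params, "se": fit.bse}),
        convergence_info={
            "n_iter": fit.n_iter,
            "deviance": fit.deviance,
            "converged": fit.converged,
            "separation_flag": fit.separation_flag,
        },
    )
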