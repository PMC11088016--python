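"""Clustered-versus-non-clustered comparison statistics.

Three classical procedures, each implemented directly so the exact
conventions are under this package's control and documented:

* Pearson chi-square on contingency tables, with the Yates continuity
  correction applied by default on 2x2 tables (each |O - E| reduced by 0.5,
  floored at 0, before squaring) and no correction on larger tables — the
  common statistical-package default.
* Two-sample t-tests, pooled-variance (Student) or Welch.
* Binary logistic regression fitted by iteratively reweighted least squares
  (Newton-Raphson on the binomial log-likelihood), with Wald standard errors
  from the inverse observed information.

Missing data policy: pairwise-complete cases for the bivariate tests,
listwise-complete cases for the regression; the n actually used is always
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .events import CATEGORICAL_LEVELS, MISSING, EventSet


# ---------------------------------------------------------------------------
# contingency tables and chi-square


@dataclass
class ContingencyTable:
    """Counts of variable levels (rows) by clustered status (columns)."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray  # (r, c) non-negative ints

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        r, c = self.counts.shape
        if r < 2 or c < 2:
            raise ValueError("need at least 2 rows and 2 columns")


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    correction_applied: bool
    expected: np.ndarray
    low_expected: bool  # any expected cell count < 5


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    p_value: float
    variant: str
    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    n_x: int
    n_y: int


def crosstab(
    events: EventSet, variable: str, cluster_flags: np.ndarray
) -> ContingencyTable:
    """Variable-by-clustered contingency table over pairwise-complete cases.

    Rows follow the schema's declared level order; columns are clustered
    no/yes.  Events missing on the variable are excluded.
    """
    if variable not in CATEGORICAL_LEVELS:
        raise ValueError(f"{variable!r} is not a categorical event field")
    flags = np.asarray(cluster_flags, dtype=bool)
    if len(flags) != len(events):
        raise ValueError("cluster_flags length must match events")
    levels = CATEGORICAL_LEVELS[variable]
    counts = np.zeros((len(levels), 2), dtype=int)
    for e, f in zip(events, flags):
        v = getattr(e, variable)
        if v == MISSING:
            continue
        counts[levels.index(v), int(f)] += 1
    observed = counts.sum(axis=1) > 0
    if observed.sum() < 2:
        raise ValueError(f"variable {variable!r} has fewer than 2 observed levels")
    return ContingencyTable(
        row_labels=[lv for lv, keep in zip(levels, observed) if keep],
        col_labels=["no", "yes"],
        counts=counts[observed],
    )


def chi_square(
    table: ContingencyTable, correction: bool | None = None
) -> ChiSquareResult:
    """Pearson chi-square test of independence.

    ``correction=None`` (default policy) applies the Yates continuity
    correction exactly when the table is 2x2; pass True/False to force.
    """
    obs = table.counts.astype(float)
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero row or column margin")
    expected = np.outer(row, col) / total
    r, c = obs.shape
    if correction is None:
        correction = (r, c) == (2, 2)
    dev = np.abs(obs - expected)
    if correction:
        dev = np.maximum(dev - 0.5, 0.0)
    statistic = float((dev**2 / expected).sum())
    df = (r - 1) * (c - 1)
    p = float(sps.chi2.sf(statistic, df))
    return ChiSquareResult(
        statistic=statistic,
        df=df,
        p_value=p,
        correction_applied=bool(correction),
        expected=expected,
        low_expected=bool((expected < 5).any()),
    )


def two_sample_t(x, y, variant: str = "pooled") -> TTestResult:
    """Two-sided two-sample t-test, pooled-variance (Student) or Welch."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs n >= 2")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if mx == my:
            t, df = 0.0, float(nx + ny - 2)
        else:
            t = float("inf") if mx > my else float("-inf")
            df = float(nx + ny - 2)
        return TTestResult(t, df, 0.0 if np.isinf(t) else 1.0, variant,
                           mx, my, np.sqrt(vx), np.sqrt(vy), nx, ny)
    if variant == "pooled":
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se = np.sqrt(sp2 * (1 / nx + 1 / ny))
        df = float(nx + ny - 2)
    else:
        se = np.sqrt(vx / nx + vy / ny)
        df = (vx / nx + vy / ny) ** 2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        )
    t = float((mx - my) / se)
    p = float(2 * sps.t.sf(abs(t), df))
    return TTestResult(t, float(df), p, variant, mx, my,
                       float(np.sqrt(vx)), float(np.sqrt(vy)), nx, ny)


# ---------------------------------------------------------------------------
# logistic regression by IRLS


@dataclass(frozen=True)
class LogisticSpec:
    """Design of the clustered-membership logistic regression.

    ``terms`` maps a categorical event field to its reference level; each
    non-reference observed level becomes a dummy column.  Economic status is
    binarized to poverty (lower) versus non-poverty (upper + middle) when
    ``binarize_economic`` is on, which is the default for this model.  Year
    dummies (reference ``year_ref``) are added when ``include_year`` is on.
    """

    terms: tuple[tuple[str, str], ...] = (
        ("sex", "male"),
        ("school_type", "elementary"),
        ("family_structure", "both_parents"),
        ("economic_status", "non-poverty"),
        ("concern_family", "no"),
        ("concern_peer", "no"),
        ("concern_academic", "no"),
        ("selfharm_history", "no"),
        ("psychiatric_history", "no"),
    )
    binarize_economic: bool = True
    include_year: bool = True
    year_ref: int = 2016
    include_region_size: bool = False  # optional metropolitan-vs-other term

    def __post_init__(self):
        for name, _ref in self.terms:
            if name not in CATEGORICAL_LEVELS:
                raise ValueError(f"unknown term {name!r}")


@dataclass
class LogisticFit:
    """Wald-style coefficient table of a converged IRLS logistic fit."""

    params: pd.Series  # coefficient estimates, indexed by column name
    bse: pd.Series  # standard errors (inverse observed information)
    zvalues: pd.Series
    pvalues: pd.Series
    iterations: int
    converged: bool
    n_used: int
    deviance: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"b": self.params, "SE": self.bse, "z": self.zvalues, "p": self.pvalues}
        )


def build_design_matrix(
    events: EventSet, spec: LogisticSpec, cluster_flags: np.ndarray
) -> tuple[pd.DataFrame, np.ndarray]:
    """Listwise-complete dummy-coded design matrix (with intercept) and outcome."""
    flags = np.asarray(cluster_flags, dtype=bool)
    if len(flags) != len(events):
        raise ValueError("cluster_flags length must match events")
    rows, y = [], []
    for e, f in zip(events, flags):
        row: dict[str, float] = {"(Intercept)": 1.0}
        complete = True
        for name, ref in spec.terms:
            v = getattr(e, name)
            if v == MISSING:
                complete = False
                break
            if name == "economic_status" and spec.binarize_economic:
                row["economic_status[poverty]"] = 1.0 if v == "lower" else 0.0
                continue
            for level in CATEGORICAL_LEVELS[name]:
                if level != ref:
                    row[f"{name}[{level}]"] = 1.0 if v == level else 0.0
        if not complete:
            continue
        if spec.include_year:
            for yr in range(2017, 2021):
                row[f"year[{yr}]"] = 1.0 if e.year == yr else 0.0
        rows.append(row)
        y.append(float(f))
    X = pd.DataFrame(rows)
    return X, np.asarray(y)


def irls_logistic(
    X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray, int, bool, float]:
    """Newton-Raphson / IRLS for the binomial log-likelihood.

    Returns (beta, covariance, iterations, converged, deviance).  Convergence
    is declared when the maximum absolute coefficient change falls below
    ``tol``.  Complete separation shows up as diverging coefficients and is
    reported as non-convergence.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        # name the aliased columns via QR pivoting on the diagonal of R
        _, R = np.linalg.qr(X)
        bad = [j for j in range(p) if abs(R[j, j]) < 1e-10 * max(1.0, abs(R[0, 0]))]
        raise np.linalg.LinAlgError(f"design matrix rank deficient; aliased columns {bad}")
    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        # Newton step solved as weighted least squares on the working response
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        hess = X.T @ WX
        beta_new = np.linalg.solve(hess, WX.T @ z)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > 1e8:
            break  # diverging: separation
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(y == 1, np.log(mu), np.log1p(-mu))
    deviance = float(-2 * np.sum(ll))
    return beta, cov, it, converged, deviance


def fit_logistic(
    events: EventSet,
    spec: LogisticSpec,
    cluster_flags: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> LogisticFit:
    """Fit the clustered-membership logistic regression on complete cases."""
    X, y = build_design_matrix(events, spec, cluster_flags)
    if len(X) == 0:
        raise ValueError("no complete cases for the logistic regression")
    beta, cov, it, converged, deviance = irls_logistic(
        X.to_numpy(), y, tol=tol, max_iter=max_iter
    )
    if not converged:
        raise RuntimeError(
            "IRLS did not converge (possible complete separation); "
            f"max |beta| = {np.max(np.abs(beta)):.3g} after {it} iterations"
        )
    names = list(X.columns)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2 * sps.norm.sf(np.abs(z))
    return LogisticFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        zvalues=pd.Series(z, index=names),
        pvalues=pd.Series(p, index=names),
        iterations=it,
        converged=converged,
        n_used=len(y),
        deviance=deviance,
    )
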