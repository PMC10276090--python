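"""Case-only PGS-phenotype association with family-clustered robust errors.

Binary sleep outcomes are regressed on the standardized PGS composite with
logistic regression (covariates: top ancestry PCs, genotyping batch, age).
Standard errors come from a cluster-robust sandwich estimator with an
independence working correlation — coefficients equal the ordinary logistic
MLE; only the covariance changes — so related children (siblings) do not
deflate the standard errors. Variance explained is reported as the
Nagelkerke pseudo-R² difference between the full (covariates + PGS) and
null (covariates-only) models, and p-values are adjusted across a battery
of (PGS, outcome) pairs with Benjamini-Hochberg FDR.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

log = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("pc1", "pc2", "pc3", "pc4", "pc5", "batch", "age")

SENSITIVITY_MODES = ("none", "parent_report_only", "extra_covariates",
                     "exclude_sleep_medicated")


class SeparationError(RuntimeError):
    """Perfect separation: the MLE does not exist."""


@dataclass
class LogisticFit:
    beta: np.ndarray
    cov: np.ndarray            # model-based (inverse observed information)
    llf: float
    mu: np.ndarray             # fitted probabilities
    X: np.ndarray
    y: np.ndarray
    n_iter: int
    columns: list[str]

    @property
    def n(self) -> int:
        return len(self.y)


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    columns: list[str] | None = None,
    max_iter: int = 100,
    score_tol: float = 1e-8,
    ll_tol: float = 1e-10,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by iteratively reweighted least squares.

    Converges when the largest score (gradient) component falls below
    ``score_tol`` or the relative log-likelihood change falls below
    ``ll_tol``. Perfect separation is detected (diverging coefficients with
    fitted probabilities saturating at 0/1) and reported with the name of the
    offending column.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    columns = columns or [f"x{j}" for j in range(p)]
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome is constant; logistic model is undefined")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")

    beta = np.zeros(p)
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        score = X.T @ (y - mu)
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        if np.all(np.abs(y - mu) < 1e-6):
            j = int(np.argmax(np.abs(beta)))
            raise SeparationError(
                f"perfect separation: fitted probabilities saturate at the outcomes "
                f"(largest coefficient on {columns[j]!r}); the MLE does not exist"
            )
        if np.max(np.abs(score)) < score_tol or (
            it > 1 and abs(ll - ll_old) < ll_tol * (abs(ll_old) + ll_tol)
        ):
            info = X.T @ (w[:, None] * X)
            cov = np.linalg.inv(info)
            return LogisticFit(beta=beta, cov=cov, llf=ll, mu=mu, X=X, y=y,
                               n_iter=it, columns=columns)
        if np.max(np.abs(beta)) > 30 and np.min(np.maximum(w, 0)) < 1e-10:
            j = int(np.argmax(np.abs(beta)))
            raise SeparationError(
                f"perfect separation suspected (covariate {columns[j]!r}); "
                "the logistic MLE does not exist"
            )
        info = X.T @ (w[:, None] * X)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as e:
            raise SeparationError(f"information matrix singular at iteration {it}: {e}")
        beta = beta + step
        ll_old = ll
    raise RuntimeError(
        f"IRLS did not converge in {max_iter} iterations "
        f"(max |score| = {np.max(np.abs(score)):.3g})"
    )


def sandwich_covariance(fit: LogisticFit, cluster_ids: np.ndarray) -> np.ndarray:
    """Cluster-robust covariance A⁻¹ B A⁻¹ for a fitted logistic model.

    A is the observed information; B sums the outer products of per-cluster
    score contributions g_c = Σ_{i in c} x_i (y_i − μ_i). With singleton
    clusters this reduces to the HC0 heteroscedasticity-robust estimator.
    """
    cluster_ids = np.asarray(cluster_ids)
    if len(cluster_ids) != fit.n:
        raise ValueError("cluster_ids length must match the number of rows")
    codes, uniques = pd.factorize(cluster_ids)
    if len(uniques) < 2:
        raise ValueError("all rows fall in one cluster; robust covariance undefined")
    resid = fit.y - fit.mu
    U = fit.X * resid[:, None]
    G = np.zeros((len(uniques), fit.X.shape[1]))
    np.add.at(G, codes, U)
    B = G.T @ G
    w = fit.mu * (1 - fit.mu)
    A = fit.X.T @ (w[:, None] * fit.X)
    Ainv = np.linalg.inv(A)
    return Ainv @ B @ Ainv


def nagelkerke(ll_model: float, ll_intercept: float, n: int) -> float:
    """Nagelkerke pseudo-R² of a model against the intercept-only reference."""
    cs = 1.0 - np.exp((2.0 / n) * (ll_intercept - ll_model))
    max_cs = 1.0 - np.exp((2.0 / n) * ll_intercept)
    if max_cs <= 0:
        return 0.0
    return float(np.clip(cs / max_cs, 0.0, 1.0))


def nagelkerke_delta(
    ll_null: float,
    ll_full: float,
    n: int,
    ll_intercept: float | None = None,
    tol: float = 1e-8,
) -> float:
    """Variance explained by the PGS: R²_N(full) − R²_N(null).

    Both models are referenced to the intercept-only likelihood
    ``ll_intercept``; when it is omitted the null model itself is the
    reference, making the result the Nagelkerke R² of the PGS over the
    covariate model.
    """
    if ll_full < ll_null - tol:
        raise ValueError(
            f"full-model log-likelihood ({ll_full:.6g}) below null ({ll_null:.6g}); "
            "fit problem"
        )
    ref = ll_null if ll_intercept is None else ll_intercept
    delta = nagelkerke(ll_full, ref, n) - nagelkerke(ll_null, ref, n)
    return float(np.clip(delta, 0.0, 1.0))


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ---------------------------------------------------------------------------
# association battery


@dataclass
class AssociationSpec:
    """One (outcome, PGS) regression with its covariates and sensitivity mode."""

    outcome: str
    predictor: str = "pgs_pca"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    cluster: str = "family_id"
    sensitivity_mode: str = "none"

    def __post_init__(self) -> None:
        if self.sensitivity_mode not in SENSITIVITY_MODES:
            raise ValueError(
                f"sensitivity_mode must be one of {SENSITIVITY_MODES}, "
                f"got {self.sensitivity_mode!r}"
            )


@dataclass
class AssociationResult:
    pgs: str
    outcome: str
    n: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    pvalue: float
    nagelkerke_delta_r2: float
    beta: float
    robust_se: float
    sensitivity_mode: str = "none"
    fdr_pvalue: float | None = None


def _build_design(
    df: pd.DataFrame, covariates: tuple[str, ...], predictor: str | None
) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariates (categoricals dummy-coded) [+ predictor last]."""
    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["intercept"]
    for cov in covariates:
        col = df[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            for dname in dummies.columns:
                cols.append(dummies[dname].to_numpy())
                names.append(dname)
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(cov)
    if predictor is not None:
        cols.append(df[predictor].to_numpy(dtype=float))
        names.append(predictor)
    return np.column_stack(cols), names


def _apply_sensitivity(
    df: pd.DataFrame, spec: AssociationSpec
) -> tuple[pd.DataFrame, str, tuple[str, ...]]:
    outcome, covariates = spec.outcome, spec.covariates
    if spec.sensitivity_mode == "parent_report_only":
        parent_col = f"{spec.outcome}_parent"
        if parent_col in df.columns:
            outcome = parent_col
        else:
            log.warning("no parent-report column for %s; using primary outcome", spec.outcome)
    elif spec.sensitivity_mode == "extra_covariates":
        covariates = tuple(covariates) + ("sex", "adhd_medication")
    elif spec.sensitivity_mode == "exclude_sleep_medicated":
        df = df[df["sleep_medication"] == 0]
    return df, outcome, covariates


def run_single_association(data: pd.DataFrame, spec: AssociationSpec) -> AssociationResult:
    """Fit one PGS-outcome logistic regression with cluster-robust errors."""
    df, outcome, covariates = _apply_sensitivity(data, spec)
    needed = [outcome, spec.predictor, spec.cluster, *covariates]
    df = df.dropna(subset=needed)
    n_dropped = len(data) - len(df)
    if n_dropped:
        log.info("%s ~ %s: %d rows dropped for missing data", outcome, spec.predictor, n_dropped)
    if df.empty:
        raise ValueError(f"no complete rows for {outcome} ~ {spec.predictor}")

    X_full, names = _build_design(df, covariates, spec.predictor)
    X_null = X_full[:, :-1]
    y = df[outcome].to_numpy(dtype=float)

    full = fit_logistic(y, X_full, columns=names)
    null = fit_logistic(y, X_null, columns=names[:-1])
    intercept_only = fit_logistic(y, X_full[:, :1], columns=["intercept"])

    rcov = sandwich_covariance(full, df[spec.cluster].to_numpy())
    beta = float(full.beta[-1])
    se = float(np.sqrt(rcov[-1, -1]))
    z = beta / se
    p = float(2 * norm.sf(abs(z)))
    dr2 = nagelkerke_delta(null.llf, full.llf, full.n, ll_intercept=intercept_only.llf)
    return AssociationResult(
        pgs=spec.predictor, outcome=outcome, n=full.n,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        pvalue=p, nagelkerke_delta_r2=dr2, beta=beta, robust_se=se,
        sensitivity_mode=spec.sensitivity_mode,
    )


def run_association_battery(
    specs: list[AssociationSpec], data: pd.DataFrame, on_error: str = "raise"
) -> list[AssociationResult]:
    """Run every spec and BH-adjust p-values within the battery.

    ``on_error="skip"`` drops specs whose fit is degenerate (e.g. perfect
    separation of a rare outcome in a small sample) with a warning instead of
    aborting the battery.
    """
    if not specs:
        raise ValueError("empty association battery")
    results = []
    for spec in specs:
        try:
            results.append(run_single_association(data, spec))
        except (SeparationError, ValueError, RuntimeError):
            if on_error != "skip":
                raise
            log.warning("skipping %s ~ %s: degenerate fit",
                        spec.outcome, spec.predictor, exc_info=True)
    if not results:
        raise ValueError("every association fit in the battery failed")
    fdr = bh_fdr(np.array([r.pvalue for r in results]))
    for r, q in zip(results, fdr):
        r.fdr_pvalue = float(q)
    return results


def battery_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Results in the shape of a published PGS-outcome association table."""
    return pd.DataFrame(
        [
            {
                "pgs": r.pgs, "outcome": r.outcome, "n": r.n,
                "or": r.odds_ratio, "ci_low": r.ci_low, "ci_high": r.ci_high,
                "p": r.pvalue, "p_fdr": r.fdr_pvalue,
                "delta_r2": r.nagelkerke_delta_r2,
                "sensitivity": r.sensitivity_mode,
            }
            for r in results
        ]
    )
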