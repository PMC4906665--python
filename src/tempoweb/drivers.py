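"""Quasi-Poisson drivers of network structure.

Each network-level parameter is regressed on the per-period covariates
with a log-link GLM under the Poisson variance function, and the
dispersion is estimated from the Pearson chi-square so that both under-
and overdispersion (phi < 1 / phi > 1) inflate or deflate the standard
errors (quasi-Poisson). Two model families mirror the study design:

1. response ~ prop_migratory + fruit_richness + prop_migratory:fruit_richness
2. response ~ fruit_abundance

Quasi-likelihood needs only non-negative responses and a variance
function, so the models are applied to non-count responses (connectance,
NODF, H2', overlap) as well; a warning is emitted when that happens.
Inference uses the t reference distribution with n - p degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidDataError, InvalidParameterError

MODEL_REPORT_COLUMNS = ["response", "model", "term", "estimate", "se", "t", "p", "dispersion"]


@dataclass
class GLMResult:
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    dispersion: float
    deviance: float
    df_residual: int
    converged: bool
    iterations: int
    n_dropped: int = 0  # rows removed for missing response/covariates

    @property
    def terms(self) -> list[str]:
        return list(self.coefficients)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": [self.coefficients[t] for t in self.terms],
                "se": [self.standard_errors[t] for t in self.terms],
                "t": [self.t_values[t] for t in self.terms],
                "p": [self.p_values[t] for t in self.terms],
            }
        )


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * (term - (y - mu)).sum())


def fit_quasipoisson(
    design: np.ndarray | pd.DataFrame,
    response,
    names: list[str] | None = None,
    *,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> GLMResult:
    """Log-link GLM with Poisson variance, fitted by IRLS.

    Convergence is a relative deviance change below ``tol`` (default 1e-8,
    at most 100 iterations); step-halving keeps the deviance non-increasing
    at every iteration. The dispersion is phi = Pearson chi2 / (n - p);
    standard errors are sqrt(phi * diag((X'WX)^-1)) and p-values use the
    t distribution with n - p degrees of freedom.
    """
    if isinstance(design, pd.DataFrame):
        names = names or list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        names = names or [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(response, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise InvalidDataError("response length does not match design rows")
    if np.any(y < 0):
        raise InvalidDataError("quasi-Poisson requires non-negative responses")
    if n <= p:
        raise InvalidParameterError(f"need n > p, got n={n}, p={p}")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the columns involved in the deficiency via QR pivoting
        _, R = np.linalg.qr(X)
        small = [names[j] for j in range(p) if abs(R[j, j]) < 1e-10 * max(1.0, abs(R[0, 0]))]
        raise InvalidDataError(
            f"design matrix is rank deficient (rank {rank} < {p}); "
            f"suspect columns: {small or names}"
        )
    if not np.allclose(y, np.round(y)):
        warnings.warn(
            "response contains non-integer values; quasi-Poisson is applied "
            "to a non-count response"
        )

    mu = np.clip((y + y.mean()) / 2.0, 1e-8, None)
    eta = np.log(mu)
    beta = np.zeros(p)
    deviance = _poisson_deviance(y, mu)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        W = mu  # Poisson variance, log link: w = mu
        z = eta + (y - mu) / mu
        WX = X * W[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        # step-halving: the deviance must never increase
        step = 1.0
        for _ in range(30):
            cand = beta + step * (beta_new - beta) if it > 1 else beta_new
            eta_c = np.clip(X @ cand, -30, 30)
            mu_c = np.exp(eta_c)
            dev_c = _poisson_deviance(y, mu_c)
            if dev_c <= deviance + 1e-12 or it == 1:
                break
            step /= 2.0
        assert it == 1 or dev_c <= deviance + 1e-9, "IRLS deviance increased"
        beta, eta, mu = cand, eta_c, mu_c
        if abs(deviance - dev_c) <= tol * (abs(deviance) + 0.1):
            deviance = dev_c
            converged = True
            break
        deviance = dev_c

    pearson = float(((y - mu) ** 2 / mu).sum())
    df_resid = n - p
    phi = pearson / df_resid
    W = mu
    cov = np.linalg.inv(X.T @ (X * W[:, None]))
    se = np.sqrt(np.clip(phi * np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.nan)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    return GLMResult(
        coefficients=dict(zip(names, beta.tolist())),
        standard_errors=dict(zip(names, se.tolist())),
        t_values=dict(zip(names, tvals.tolist())),
        p_values=dict(zip(names, pvals.tolist())),
        dispersion=float(phi),
        deviance=float(deviance),
        df_residual=df_resid,
        converged=converged,
        iterations=it,
    )


def _merge_tables(covariates: pd.DataFrame, metrics_table: pd.DataFrame, response_name: str) -> pd.DataFrame:
    if response_name not in metrics_table.columns:
        raise InvalidDataError(f"response column {response_name!r} not in metrics table")
    df = covariates.merge(metrics_table[["period", response_name]], on="period", how="inner")
    before = len(df)
    df = df.dropna(subset=[response_name, "prop_migratory", "fruit_richness", "fruit_abundance"])
    df.attrs["n_dropped"] = before - len(df)
    return df


def model_migration_richness(
    covariates: pd.DataFrame,
    metrics_table: pd.DataFrame,
    response_name: str,
    *,
    center: bool = False,
    force: bool = False,
) -> GLMResult:
    """Model family 1: migration proportion, fruit richness and their product.

    The interaction column is built after optional centering of the two
    main effects. With p = 4 coefficients the fit is refused when
    n - p < 3 unless ``force=True``.
    """
    df = _merge_tables(covariates, metrics_table, response_name)
    n = len(df)
    if n - 4 < 3 and not force:
        raise InvalidParameterError(
            f"only {n} usable periods for a 4-parameter model; pass force=True to fit anyway"
        )
    mig = df["prop_migratory"].to_numpy(dtype=float)
    rich = df["fruit_richness"].to_numpy(dtype=float)
    if center:
        mig = mig - mig.mean()
        rich = rich - rich.mean()
    X = np.column_stack([np.ones(n), mig, rich, mig * rich])
    res = fit_quasipoisson(
        X,
        df[response_name],
        names=["intercept", "prop_migratory", "fruit_richness", "prop_migratory:fruit_richness"],
    )
    res.n_dropped = df.attrs["n_dropped"]
    return res


def model_abundance(
    covariates: pd.DataFrame, metrics_table: pd.DataFrame, response_name: str
) -> GLMResult:
    """Model family 2: fruit abundance as the single regressor."""
    df = _merge_tables(covariates, metrics_table, response_name)
    n = len(df)
    X = np.column_stack([np.ones(n), df["fruit_abundance"].to_numpy(dtype=float)])
    res = fit_quasipoisson(X, df[response_name], names=["intercept", "fruit_abundance"])
    res.n_dropped = df.attrs["n_dropped"]
    return res


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise InvalidParameterError("need two equal-length vectors of length >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise InvalidDataError("zero variance in ranks; correlation undefined")
    return float(stats.spearmanr(x, y).statistic)


def model_report(
    covariates: pd.DataFrame,
    metrics_table: pd.DataFrame,
    responses: list[str] | None = None,
) -> pd.DataFrame:
    """Fit both model families for each response; long-format report.

    Responses whose fit fails (negative values, rank deficiency) are
    recorded with NaN estimates rather than aborting the whole report.
    Rows are deterministically ordered by (response, model, term).
    """
    if responses is None:
        responses = [c for c in metrics_table.columns if c != "period"]
    rows = []
    for resp in responses:
        for model_name, fitter in (
            ("migration_richness", model_migration_richness),
            ("abundance", model_abundance),
        ):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = fitter(covariates, metrics_table, resp)
                for term in res.terms:
                    rows.append(
                        {
                            "response": resp,
                            "model": model_name,
                            "term": term,
                            "estimate": res.coefficients[term],
                            "se": res.standard_errors[term],
                            "t": res.t_values[term],
                            "p": res.p_values[term],
                            "dispersion": res.dispersion,
                        }
                    )
            except (InvalidDataError, InvalidParameterError) as e:
                rows.append(
                    {
                        "response": resp,
                        "model": model_name,
                        "term": f"<failed: {type(e).__name__}>",
                        "estimate": np.nan,
                        "se": np.nan,
                        "t": np.nan,
                        "p": np.nan,
                        "dispersion": np.nan,
                    }
                )
    df = pd.DataFrame(rows, columns=MODEL_REPORT_COLUMNS)
    return df.sort_values(["response", "model", "term"], kind="stable").reset_index(drop=True)
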