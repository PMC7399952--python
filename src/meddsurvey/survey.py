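"""Design-based estimation for stratified multistage samples.

Implements the standard "with-replacement" Taylor-linearization variance
estimator used for NHANES-style designs: records carry a stratum id, a
primary sampling unit (PSU) id and a positive analysis weight. Every
estimator here is a smooth function of weighted totals; its variance is
obtained from the between-PSU variation of the per-record influence (score)
contributions within each stratum,

    Vhat = sum_h  n_h/(n_h - 1) * sum_j (t_hj - tbar_h)(t_hj - tbar_h)',

where ``t_hj`` sums the influence contributions over PSU ``j`` of stratum
``h``. Confidence intervals and p-values use t / F reference distributions
with the design degrees of freedom (#PSUs - #strata).

Fitted models follow the statsmodels idiom: ``SvyOLS``/``SvyLogit`` are model
objects constructed from data plus a :class:`SurveyDesign`; ``fit()`` returns
a results object with ``params``, ``cov_params``, ``conf_int``, ``pvalues``
and ``summary()``. Missing responses or regressors are handled as domain
(subpopulation) estimation: excluded records keep their place in the design
and contribute zero influence, rather than being dropped from the variance
computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from scipy.special import expit as _expit

from .errors import (
    ConfigurationError,
    ConvergenceError,
    LonelyPSUError,
    SeparationError,
    ValidationError,
)

__all__ = [
    "SurveyDesign",
    "EstimateWithSE",
    "four_year_weights",
    "svy_total",
    "svy_mean",
    "svy_proportion",
    "svy_sd",
    "SvyOLS",
    "SvyLogit",
    "SvyRegressionResults",
    "rao_scott_chisq",
    "pairwise_contrasts_tukey",
    "kernel_smooth",
]


def four_year_weights(two_year_weight, n_cycles: int = 2):
    """Combine per-cycle survey weights across pooled cycles by division.

    Pooling two 2-year cycles halves each record's 2-year weight so the
    pooled sample still represents the population once.
    """
    w = np.asarray(two_year_weight, dtype=float)
    if np.any(~(w > 0)):
        raise ValidationError("survey weights must be strictly positive")
    if n_cycles < 1:
        raise ConfigurationError(f"n_cycles must be >= 1, got {n_cycles}")
    out = w / float(n_cycles)
    return float(out) if np.isscalar(two_year_weight) else out


class SurveyDesign:
    """Stratum/PSU/weight triple defining the variance-estimation contract.

    Parameters
    ----------
    strata, psu : array-like
        Stratum and PSU identifiers per record. PSU ids are interpreted
        within stratum (the pair (stratum, psu) is the cluster key).
    weights : array-like
        Strictly positive analysis weights.
    lonely_psu : {"error", "centered"}
        Policy for strata containing a single PSU: raise (default), or center
        that stratum's PSU total at the grand mean PSU total so it still
        contributes to the variance.
    """

    def __init__(self, strata, psu, weights, lonely_psu: str = "error"):
        self.strata = np.asarray(strata)
        self.psu = np.asarray(psu)
        self.weights = np.asarray(weights, dtype=float)
        if lonely_psu not in ("error", "centered"):
            raise ConfigurationError(f"lonely_psu must be 'error' or 'centered', got {lonely_psu}")
        self.lonely_psu = lonely_psu
        n = len(self.weights)
        if len(self.strata) != n or len(self.psu) != n:
            raise ValidationError("strata, psu and weights must have equal length")
        if np.any(~(self.weights > 0)) or np.any(np.isnan(self.weights)):
            raise ValidationError("survey weights must be strictly positive")
        # integer codes for fast PSU aggregation
        cluster_key = pd.MultiIndex.from_arrays([self.strata, self.psu])
        self._cluster_codes, clusters = pd.factorize(cluster_key)
        self._cluster_strata_codes, self._strata_ids = pd.factorize(
            np.asarray([c[0] for c in clusters])
        )
        self._psus_per_stratum = np.bincount(self._cluster_strata_codes)
        self._lonely_strata = [
            s for s, c in zip(self._strata_ids, self._psus_per_stratum) if c < 2
        ]

    @property
    def n(self) -> int:
        return len(self.weights)

    @property
    def n_psus(self) -> int:
        return len(self._cluster_strata_codes)

    @property
    def n_strata(self) -> int:
        return len(self._strata_ids)

    @property
    def df(self) -> int:
        """Design degrees of freedom: #PSUs - #strata."""
        return self.n_psus - self.n_strata

    def rescale(self, factor: float) -> "SurveyDesign":
        """Return a design with all weights multiplied by a positive constant."""
        if factor <= 0:
            raise ValidationError("rescale factor must be positive")
        return SurveyDesign(self.strata, self.psu, self.weights * factor, self.lonely_psu)

    def linearized_cov(self, scores: np.ndarray) -> np.ndarray:
        """Between-PSU covariance of summed influence contributions.

        ``scores`` is (n, k): one influence contribution per record (already
        weighted). Records excluded from an estimate must carry zero rows.
        """
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        if scores.shape[0] != self.n:
            scores = scores.T
        k = scores.shape[1]
        if self._lonely_strata and self.lonely_psu == "error":
            raise LonelyPSUError(
                f"strata with a single PSU: {self._lonely_strata[:5]}; "
                "set lonely_psu='centered' to proceed"
            )
        # PSU totals, then deviations from stratum means, all vectorized
        totals = np.zeros((self.n_psus, k))
        np.add.at(totals, self._cluster_codes, scores)
        sc = self._cluster_strata_codes
        n_h = self._psus_per_stratum
        stratum_sum = np.zeros((self.n_strata, k))
        np.add.at(stratum_sum, sc, totals)
        dev = totals - stratum_sum[sc] / n_h[sc, None]
        factor = np.where(n_h > 1, n_h / np.maximum(n_h - 1.0, 1.0), 0.0)
        if self._lonely_strata:  # centered policy: deviation from grand mean
            lonely_mask = n_h[sc] < 2
            dev[lonely_mask] = totals[lonely_mask] - totals.mean(axis=0)
            factor = np.where(n_h > 1, factor, 1.0)
        d = dev * np.sqrt(factor[sc])[:, None]
        return d.T @ d


@dataclass
class EstimateWithSE:
    """A point estimate with linearized SE, CI and design df."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    df: int
    n: int
    p: float | None = None

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "df": self.df,
            "p": self.p,
        }


def _mask_values(values, design: SurveyDesign) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(values, dtype=float)
    if x.shape[0] != design.n:
        raise ValidationError("values and design must be aligned")
    return x, ~np.isnan(x)


def _tcrit(level: float, df: int) -> float:
    if df < 1:
        raise ValidationError(f"design degrees of freedom must be >= 1, got {df}")
    return stats.t.ppf(0.5 + level / 2.0, df)


def svy_total(values, design: SurveyDesign, ci_level: float = 0.95) -> EstimateWithSE:
    """Horvitz-Thompson weighted total with linearized SE."""
    x, ok = _mask_values(values, design)
    w = design.weights
    total = float(np.sum(w[ok] * x[ok]))
    z = np.zeros(design.n)
    z[ok] = w[ok] * x[ok]
    var = design.linearized_cov(z[:, None])[0, 0]
    se = float(np.sqrt(var))
    t = _tcrit(ci_level, design.df)
    return EstimateWithSE(total, se, total - t * se, total + t * se, design.df, int(ok.sum()))


def svy_mean(values, design: SurveyDesign, ci_level: float = 0.95) -> EstimateWithSE:
    """Weighted (ratio-estimator) mean: sum(w x) / sum(w) over non-missing x.

    SE by Taylor linearization of the ratio: influence
    ``z_i = w_i (x_i - mean) / sum(w)``.
    """
    x, ok = _mask_values(values, design)
    w = design.weights
    wsum = np.sum(w[ok])
    est = float(np.sum(w[ok] * x[ok]) / wsum)
    z = np.zeros(design.n)
    z[ok] = w[ok] * (x[ok] - est) / wsum
    var = design.linearized_cov(z[:, None])[0, 0]
    se = float(np.sqrt(var))
    t = _tcrit(ci_level, design.df)
    return EstimateWithSE(est, se, est - t * se, est + t * se, design.df, int(ok.sum()))


def svy_proportion(values, design: SurveyDesign, ci_level: float = 0.95) -> EstimateWithSE:
    """Weighted proportion of a 0/1 (or boolean) indicator."""
    x = np.asarray(values, dtype=float)
    ok = ~np.isnan(x)
    if not np.isin(x[ok], [0.0, 1.0]).all():
        raise ValidationError("svy_proportion expects a 0/1 indicator")
    return svy_mean(x, design, ci_level)


def svy_sd(values, design: SurveyDesign, ci_level: float = 0.95) -> EstimateWithSE:
    """Weighted population standard deviation with linearized SE.

    Point estimate is sqrt of the weighted variance
    ``sum(w (x - mean)^2) / sum(w)``; the SE comes from linearizing the
    variance (influence ``w_i ((x_i-mean)^2 - var) / sum(w)``; the plug-in
    mean contributes no first-order term) and the delta method for sqrt.
    """
    x, ok = _mask_values(values, design)
    w = design.weights
    wsum = np.sum(w[ok])
    mean = float(np.sum(w[ok] * x[ok]) / wsum)
    var_pt = float(np.sum(w[ok] * (x[ok] - mean) ** 2) / wsum)
    sd = float(np.sqrt(var_pt))
    z = np.zeros(design.n)
    z[ok] = w[ok] * ((x[ok] - mean) ** 2 - var_pt) / wsum
    var_of_var = design.linearized_cov(z[:, None])[0, 0]
    se = float(np.sqrt(var_of_var) / (2.0 * sd)) if sd > 0 else 0.0
    t = _tcrit(ci_level, design.df)
    return EstimateWithSE(sd, se, sd - t * se, sd + t * se, design.df, int(ok.sum()))


# ---------------------------------------------------------------------------
# regression models


def _design_matrices_from_formula(formula: str, data: pd.DataFrame):
    """Build full-length (NaN-padded) response and design matrices.

    patsy drops incomplete rows; they are reinstated as NaN so the survey
    design stays aligned and exclusion is handled as domain estimation.
    """
    y_df, x_df = patsy.dmatrices(formula, data, return_type="dataframe")
    y = y_df.iloc[:, 0].reindex(data.index)
    X = x_df.reindex(data.index)
    return y, X


class _BaseSvyModel:
    def __init__(self, endog, exog, design: SurveyDesign):
        self.design = design
        if isinstance(exog, pd.DataFrame):
            self.exog_names = list(exog.columns)
            X = exog.to_numpy(dtype=float)
        else:
            X = np.asarray(exog, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            self.exog_names = [f"x{i}" for i in range(X.shape[1])]
        y = np.asarray(endog, dtype=float)
        if X.shape[0] != design.n or y.shape[0] != design.n:
            raise ValidationError("endog/exog must be aligned with the design")
        self.endog = y
        self.exog = X
        self.nobs_mask = ~(np.isnan(y) | np.isnan(X).any(axis=1))

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame, design: SurveyDesign, **kw):
        y, X = _design_matrices_from_formula(formula, data)
        return cls(y, X, design, **kw)

    def _check_rank(self, Xw):
        r = np.linalg.matrix_rank(Xw)
        if r < Xw.shape[1]:
            # identify collinear columns via QR with pivoting
            _, R = np.linalg.qr(Xw)
            diag = np.abs(np.diag(R))
            bad = [self.exog_names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
            raise ValidationError(f"design matrix is rank deficient; collinear columns: {bad}")


class SvyOLS(_BaseSvyModel):
    """Survey-weighted ordinary least squares.

    ``beta = (X'WX)^-1 X'Wy`` with a linearized (sandwich) covariance built
    from the estimating-equation contributions ``w_i x_i e_i`` aggregated
    over strata and PSUs.
    """

    def fit(self, ci_level: float = 0.95) -> "SvyRegressionResults":
        ok = self.nobs_mask
        X, y, w = self.exog[ok], self.endog[ok], self.design.weights[ok]
        self._check_rank(X * np.sqrt(w)[:, None])
        A = X.T @ (X * w[:, None])
        beta = np.linalg.solve(A, X.T @ (w * y))
        resid = y - X @ beta
        scores = np.zeros((self.design.n, X.shape[1]))
        scores[ok] = X * (w * resid)[:, None]
        G = self.design.linearized_cov(scores)
        Ainv = np.linalg.inv(A)
        cov = Ainv @ G @ Ainv
        cov = (cov + cov.T) / 2.0
        return SvyRegressionResults(
            self, beta, cov, int(ok.sum()), ci_level=ci_level, model_kind="ols"
        )


class SvyLogit(_BaseSvyModel):
    """Survey-weighted binary logistic regression.

    Maximizes the weighted pseudo-log-likelihood by Newton/IRLS starting at
    beta = 0; convergence when the relative log-likelihood change falls below
    ``tol`` (default 1e-10) within ``maxiter`` (default 50) iterations.
    Covariance is the linearized sandwich on the score contributions
    ``w_i x_i (y_i - p_i)``.
    """

    def __init__(self, endog, exog, design, tol: float = 1e-10, maxiter: int = 50):
        super().__init__(endog, exog, design)
        y = self.endog[self.nobs_mask]
        if not np.isin(y, [0.0, 1.0]).all():
            raise ValidationError("endog must be binary 0/1 for SvyLogit")
        self.tol = tol
        self.maxiter = maxiter

    @staticmethod
    def _loglike(w, y, eta):
        # numerically safe weighted Bernoulli log-likelihood
        return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))

    def fit(self, ci_level: float = 0.95) -> "SvyRegressionResults":
        ok = self.nobs_mask
        X, y, w = self.exog[ok], self.endog[ok], self.design.weights[ok]
        self._check_rank(X)
        k = X.shape[1]
        beta = np.zeros(k)
        eta = X @ beta
        ll = self._loglike(w, y, eta)
        converged = False
        for _ in range(self.maxiter):
            p = _expit(eta)
            d = np.maximum(p * (1 - p), 1e-12)
            H = X.T @ (X * (w * d)[:, None])
            g = X.T @ (w * (y - p))
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError as e:
                raise ConvergenceError(f"singular Hessian in IRLS: {e}") from e
            # step-halving keeps the pseudo-log-likelihood non-decreasing
            scale = 1.0
            for _half in range(30):
                beta_new = beta + scale * step
                ll_new = self._loglike(w, y, X @ beta_new)
                if ll_new >= ll - 1e-12:
                    break
                scale /= 2.0
            beta, eta = beta_new, X @ beta_new
            if abs(ll_new - ll) <= self.tol * (abs(ll) + 1e-12):
                ll = ll_new
                converged = True
                break
            ll = ll_new
        p = _expit(eta)
        if np.all(np.abs(y - p) < 1e-6):
            raise SeparationError(
                "complete separation: the model classifies every observation perfectly"
            )
        if not converged:
            raise ConvergenceError(
                f"IRLS did not converge in {self.maxiter} iterations "
                f"(last log-likelihood {ll:.6g})"
            )
        d = p * (1 - p)
        H = X.T @ (X * (w * d)[:, None])
        scores = np.zeros((self.design.n, k))
        scores[ok] = X * (w * (y - p))[:, None]
        G = self.design.linearized_cov(scores)
        Hinv = np.linalg.inv(H)
        cov = Hinv @ G @ Hinv
        cov = (cov + cov.T) / 2.0
        return SvyRegressionResults(
            self, beta, cov, int(ok.sum()), ci_level=ci_level, model_kind="logit"
        )


class SvyRegressionResults:
    """Estimates, linearized covariance and inference for a fitted survey model."""

    def __init__(self, model, params, cov, nobs, ci_level=0.95, model_kind="ols"):
        self.model = model
        self.design = model.design
        self.params = pd.Series(params, index=model.exog_names, name="coef")
        self.cov_params = pd.DataFrame(cov, index=model.exog_names, columns=model.exog_names)
        self.nobs = nobs
        self.ci_level = ci_level
        self.model_kind = model_kind
        self.df = self.design.df

    @property
    def bse(self) -> pd.Series:
        diag = np.clip(np.diag(self.cov_params), 0.0, None)  # guard rounding
        return pd.Series(np.sqrt(diag), index=self.params.index, name="se")

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * stats.t.sf(np.abs(self.tvalues), self.df), index=self.params.index, name="p"
        )

    def conf_int(self, alpha: float | None = None) -> pd.DataFrame:
        level = 1 - alpha if alpha is not None else self.ci_level
        t = _tcrit(level, self.df)
        return pd.DataFrame(
            {"ci_low": self.params - t * self.bse, "ci_high": self.params + t * self.bse}
        )

    def odds_ratios(self, alpha: float | None = None) -> pd.DataFrame:
        """Odds ratios exp(beta) with exponentiated CI bounds (logit only)."""
        if self.model_kind != "logit":
            raise ValidationError("odds ratios are defined for logistic fits only")
        ci = self.conf_int(alpha)
        with np.errstate(over="ignore"):  # a huge CI bound exponentiates to inf
            return pd.DataFrame(
                {
                    "or": np.exp(self.params),
                    "ci_low": np.exp(ci["ci_low"]),
                    "ci_high": np.exp(ci["ci_high"]),
                    "p": self.pvalues,
                }
            )

    def contrast(self, c, ci_level: float | None = None) -> EstimateWithSE:
        """Linear contrast c'beta with linearized SE and t-based inference."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.params.to_numpy())
        se = float(np.sqrt(c @ self.cov_params.to_numpy() @ c))
        level = ci_level or self.ci_level
        t = _tcrit(level, self.df)
        p = float(2 * stats.t.sf(abs(est / se), self.df)) if se > 0 else (0.0 if est else 1.0)
        return EstimateWithSE(est, se, est - t * se, est + t * se, self.df, self.nobs, p)

    def predict(self, exog=None) -> np.ndarray:
        X = self.model.exog if exog is None else np.asarray(exog, dtype=float)
        eta = X @ self.params.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta)) if self.model_kind == "logit" else eta

    def summary(self) -> str:
        kind = "Survey-weighted logistic regression" if self.model_kind == "logit" else (
            "Survey-weighted OLS regression"
        )
        ci = self.conf_int()
        rows = pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
                "ci_low": ci["ci_low"],
                "ci_high": ci["ci_high"],
            }
        )
        head = (
            f"{kind}\n"
            f"n obs: {self.nobs}    strata: {self.design.n_strata}    "
            f"PSUs: {self.design.n_psus}    design df: {self.df}\n"
        )
        return head + rows.to_string(float_format=lambda v: f"{v: .4f}")

    def __repr__(self):
        return f"<SvyRegressionResults {self.model_kind} n={self.nobs} k={len(self.params)}>"


# ---------------------------------------------------------------------------
# categorical tests, contrasts, smoothing


@dataclass
class RaoScottResult:
    statistic: float  # design-corrected X^2 (Pearson / mean design effect)
    p: float
    df1: int
    df2: int
    pearson: float  # uncorrected Pearson X^2 on weighted proportions
    delta: float  # mean generalized design effect (mean eigenvalue)
    a2: float  # squared CV of the design-effect eigenvalues (Satterthwaite)
    table: pd.DataFrame = field(repr=False, default=None)


def rao_scott_chisq(rows, cols, design: SurveyDesign) -> RaoScottResult:
    """Design-adjusted Pearson chi-squared test of independence.

    Pearson's X^2 is computed on the survey-weighted cell proportions (scaled
    by the number of observed records) and corrected by the Rao-Scott
    generalized design effects: the eigenvalues of the product of the inverse
    multinomial (SRS reference) covariance and the linearized design
    covariance of the independence residuals. The reported statistic divides
    X^2 by the mean eigenvalue (first-order correction); the p-value adds the
    second-order Satterthwaite refinement, referring
    ``X^2 / (delta * (1 + a^2))`` to a chi-squared distribution with
    ``d = df1 / (1 + a^2)`` degrees of freedom, where ``a`` is the
    coefficient of variation of the eigenvalues. Calibration degrades when
    df1 approaches the design df (few PSUs relative to the table size).

    The SRS reference covariance carries an (m-1) denominator, so under
    equal-weight SRS with one record per PSU every eigenvalue is exactly 1
    and the statistic (and p, since a^2 = 0) reduces to classical Pearson.

    Rows/columns with zero weighted mass are dropped with a warning.
    """
    r = pd.Series(rows).reset_index(drop=True)
    c = pd.Series(cols).reset_index(drop=True)
    ok = (~r.isna() & ~c.isna()).to_numpy()
    w = design.weights

    def _present(series):
        levels = sorted(pd.unique(series[ok]), key=str)
        kept = [lv for lv in levels if np.sum(w[ok & (series == lv).to_numpy()]) > 0]
        if len(kept) < len(levels):
            warnings.warn("dropping empty rows/columns from the weighted table")
        return kept

    r_levels, c_levels = _present(r), _present(c)
    R, C = len(r_levels), len(c_levels)
    if R < 2 or C < 2:
        raise ValidationError("rao_scott_chisq needs at least 2 observed levels per variable")
    ok = ok & r.isin(r_levels).to_numpy() & c.isin(c_levels).to_numpy()
    m = int(ok.sum())
    wsum = np.sum(w[ok])

    r_ind = np.stack([(r == rl).to_numpy(dtype=float) for rl in r_levels], axis=1)
    c_ind = np.stack([(c == cl).to_numpy(dtype=float) for cl in c_levels], axis=1)
    cell_ind = (r_ind[:, :, None] * c_ind[:, None, :]).reshape(len(r), R * C)
    p = (w[ok] @ cell_ind[ok]) / wsum
    z = np.zeros_like(cell_ind)
    z[ok] = w[ok, None] * (cell_ind[ok] - p[None, :]) / wsum
    V = design.linearized_cov(z)  # covariance of the cell-proportion vector

    P = p.reshape(R, C)
    pr, pc = P.sum(axis=1), P.sum(axis=0)
    expected = np.outer(pr, pc)
    X2 = float(m * np.sum((P - expected) ** 2 / expected))
    df1 = (R - 1) * (C - 1)

    # independence residuals u = p - vec(pr x pc); Jacobian T = du/dp
    N = R * C
    rows_of = np.repeat(np.arange(R), C)
    cols_of = np.tile(np.arange(C), R)
    T = np.eye(N)
    T -= (rows_of[:, None] == rows_of[None, :]) * pc[cols_of][:, None]
    T -= (cols_of[:, None] == cols_of[None, :]) * pr[rows_of][:, None]
    b_half = 1.0 / np.sqrt(expected.reshape(-1))
    # design covariance and SRS (multinomial at observed p, m-1 denominator)
    # reference covariance of the residuals, in the expected-cell metric;
    # generalized eigenvalues of (S, S0) are the Rao-Scott design effects and
    # are exactly 1 under equal-weight SRS with one record per PSU
    S = (b_half[:, None] * T) @ V @ (T.T * b_half[None, :])
    V_srs = (np.diag(p) - np.outer(p, p)) / (m - 1.0)
    S0 = (b_half[:, None] * T) @ V_srs @ (T.T * b_half[None, :])
    s0_vals, s0_vecs = np.linalg.eigh((S0 + S0.T) / 2.0)
    order = np.argsort(s0_vals)[::-1][:df1]
    W = s0_vecs[:, order] / np.sqrt(s0_vals[order])[None, :]
    lam = np.sort(np.linalg.eigvalsh(W.T @ ((S + S.T) / 2.0) @ W))[::-1]
    lam = np.clip(lam, 0.0, None)
    delta = max(float(np.mean(lam)), 1e-12)
    a2 = float(np.var(lam) / delta**2)
    x2_rs = X2 / delta
    df2 = design.df
    # second-order (Satterthwaite) correction: X^2/(delta(1+a^2)) ~ chi^2_d
    d_satt = df1 / (1.0 + a2)
    pval = float(stats.chi2.sf(X2 / (delta * (1.0 + a2)), d_satt))
    table = pd.DataFrame(P, index=r_levels, columns=c_levels)
    return RaoScottResult(x2_rs, pval, df1, df2, X2, delta, a2, table)



@dataclass
class ContrastResult:
    group_a: object
    group_b: object
    difference: float
    se: float
    ci_low: float
    ci_high: float
    p_adjusted: float


def pairwise_contrasts_tukey(
    groups, outcome, design: SurveyDesign, ci_level: float = 0.95
) -> pd.DataFrame:
    """All pairwise group-mean differences with Tukey HSD adjustment.

    Group means come from a survey-weighted cell-means OLS fit; each pairwise
    difference's adjusted p refers ``|t| * sqrt(2)`` to the studentized-range
    distribution with the number of groups and the design df (so with two
    groups it reduces exactly to the unadjusted two-sided t test). Simultaneous
    CIs use the same critical value.
    """
    g = pd.Series(groups).reset_index(drop=True)
    y = np.asarray(outcome, dtype=float)
    ok = ~g.isna().to_numpy() & ~np.isnan(y)
    levels = sorted(pd.unique(g[ok]), key=str)
    k = len(levels)
    if k < 2:
        raise ValidationError("need at least 2 groups for pairwise contrasts")
    counts = g[ok].value_counts()
    singletons = [lv for lv in levels if counts.get(lv, 0) < 2]
    if singletons:
        raise ValidationError(f"singleton groups cannot be compared: {singletons}")
    X = pd.DataFrame({str(lv): (g == lv).astype(float) for lv in levels})
    y_masked = np.where(ok, y, np.nan)
    res = SvyOLS(y_masked, X, design).fit()
    df = design.df
    q_crit = stats.studentized_range.ppf(ci_level, k, df)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            cvec = np.zeros(k)
            cvec[i], cvec[j] = 1.0, -1.0
            est = float(cvec @ res.params.to_numpy())
            se = float(np.sqrt(cvec @ res.cov_params.to_numpy() @ cvec))
            q = abs(est) / se * np.sqrt(2) if se > 0 else np.inf
            p_adj = float(stats.studentized_range.sf(q, k, df))
            half = q_crit / np.sqrt(2) * se
            out.append(
                ContrastResult(levels[i], levels[j], est, se, est - half, est + half, p_adj)
            )
    return pd.DataFrame([vars(o) for o in out])


def silverman_bandwidth(x: np.ndarray, weights: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth on weighted x (Kish effective n)."""
    wsum = weights.sum()
    mean = np.sum(weights * x) / wsum
    sd = np.sqrt(np.sum(weights * (x - mean) ** 2) / wsum)
    n_eff = wsum**2 / np.sum(weights**2)
    h = 0.9 * sd * n_eff ** (-0.2)
    return float(h) if h > 0 else 1.0


def kernel_smooth(
    x, y, weights=None, bandwidth: float | None = None, grid=None, n_grid: int = 100
):
    """Weighted Nadaraya-Watson regression with a Gaussian kernel.

    Returns (grid, fitted). Grid points receiving numerically zero kernel
    mass get NaN fits.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y, w = x[ok], y[ok], w[ok]
    if bandwidth is None:
        bandwidth = silverman_bandwidth(x, w)
    if bandwidth <= 0:
        raise ValidationError("bandwidth must be positive")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), n_grid)
    grid = np.asarray(grid, dtype=float)
    u = (grid[:, None] - x[None, :]) / bandwidth
    K = np.exp(-0.5 * u**2) * w[None, :]
    mass = K.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fit = np.where(mass > 0, (K * y[None, :]).sum(axis=1) / mass, np.nan)
    return grid, fit
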