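"""Replicated negative-binomial count statistics.

Self-contained machinery for RNA-seq-style count matrices: median-of-ratios
library-size normalization, per-feature dispersion estimation (Cox-Reid
adjusted profile likelihood, parametric mean-dispersion trend, log-normal
shrinkage to a posterior mode), NB GLM fitting by IRLS with a log link and
size-factor offsets, Wald tests on named coefficients, and Benjamini-Hochberg
FDR adjustment.

Conventions used throughout the package:

* NB parameterization: ``Var(K) = mu + alpha * mu**2`` (NB2); ``alpha`` is the
  overdispersion, ``1/alpha`` the gamma shape.
* Coefficients are fitted on the natural-log scale and reported as log2.
* Size factors enter the linear predictor as offsets ``ln s_j``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))
ALPHA_MIN = 1e-8
ALPHA_MAX = 32.0
#: outlier rule: gene-wise dispersion more than e**2 above the trend
DISP_OUTLIER_LOG = 2.0
#: floor on the variance of the log-normal dispersion prior
PRIOR_VAR_MIN = 0.25

__all__ = [
    "CountMatrix",
    "DispersionSet",
    "GlmFit",
    "GlmError",
    "estimate_size_factors",
    "normalize_counts",
    "filter_low_counts",
    "nb_loglik",
    "estimate_dispersions",
    "fit_nb_glm",
    "wald_test",
    "bh_adjust",
    "two_group_design",
    "nb_two_group_test",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Integer count matrix (features x columns) with per-column metadata.

    ``col_meta`` is indexed by column id and carries at least ``population``
    (AUS / TIM / HYB); allelic matrices additionally carry ``type`` (P for a
    parental sample column, H for a hybrid allele column), ``allele``
    (A = population-1/reference allele, B = population-2/alternative allele)
    and ``sample`` (source individual).
    """

    counts: pd.DataFrame
    col_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.col_meta.index):
            raise ValueError("col_meta must be indexed by the count-matrix columns, in order")
        values = self.counts.to_numpy()
        if np.any(values < 0):
            raise ValueError("counts must be nonnegative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")
        if "type" in self.col_meta:
            types = self.col_meta["type"]
            n_h = int((types == "H").sum())
            hyb = self.col_meta.loc[types == "H"]
            if n_h and ("allele" not in self.col_meta or hyb["allele"].isna().any()):
                raise ValueError("hybrid allele columns must carry an allele label")

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def column_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_columns(self, columns: list[str]) -> "CountMatrix":
        return CountMatrix(self.counts[columns], self.col_meta.loc[columns])

    def to_tsv(self, counts_path, meta_path=None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="feature")
        if meta_path is not None:
            self.col_meta.to_csv(meta_path, sep="\t", index_label="column")

    @classmethod
    def from_tsv(cls, counts_path, meta_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(counts, meta.loc[counts.columns])


@dataclass
class DispersionSet:
    """Per-feature dispersion estimates: gene-wise MLE, fitted trend, final MAP."""

    genewise: pd.Series
    trend: pd.Series
    final: pd.Series
    converged: pd.Series
    outlier: pd.Series
    trend_coefs: tuple[float, float] = (0.0, 0.0)  # (a0, a1) in a0 + a1 / mu
    prior_var: float = PRIOR_VAR_MIN


class GlmError(RuntimeError):
    """Raised when a GLM fit cannot be carried out (all-zero row, separation)."""


@dataclass
class GlmFit:
    """Fitted NB GLM for one feature.

    ``beta`` is on the natural-log scale; use :func:`wald_test` for log2-scale
    effects. ``cov`` is the inverse expected Fisher information.
    """

    beta: np.ndarray
    cov: np.ndarray
    mu: np.ndarray
    coef_names: list[str]
    converged: bool
    alpha: float
    design: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# normalization and filtering
# ---------------------------------------------------------------------------


def estimate_size_factors(counts: pd.DataFrame, *, fallback: str | None = None) -> pd.Series:
    """Median-of-ratios size factors.

    For each feature i with all-positive counts, compute the ratio of each
    column's count to the feature's geometric mean across columns; the size
    factor of column j is the median of those ratios. Invariant to feature
    order and equivariant under column scaling.

    Parameters
    ----------
    counts
        Features x columns integer counts.
    fallback
        ``None`` (default) requires at least one all-positive feature and
        raises otherwise; ``"positive-subset"`` computes geometric means over
        the positive entries of each row instead, so matrices where every
        feature has at least one zero can still be normalized.
    """
    values = counts.to_numpy(dtype=float)
    if values.shape[1] == 0:
        raise ValueError("count matrix has no columns")
    all_positive = (values > 0).all(axis=1)
    if all_positive.any():
        logc = np.log(values[all_positive])
        log_geo = logc.mean(axis=1)
        log_sf = np.median(logc - log_geo[:, None], axis=0)
    elif fallback == "positive-subset":
        with np.errstate(divide="ignore"):
            logc = np.log(values)
        any_positive = (values > 0).any(axis=1)
        logc = logc[any_positive]
        log_geo = np.array([row[np.isfinite(row)].mean() for row in logc])
        log_sf = np.zeros(values.shape[1])
        for j in range(values.shape[1]):
            ratios = logc[:, j] - log_geo
            ratios = ratios[np.isfinite(ratios)]
            if ratios.size == 0:
                raise ValueError(f"column {counts.columns[j]!r} has no positive counts")
            log_sf[j] = np.median(ratios)
    else:
        raise ValueError(
            "no feature has all-positive counts; rerun with fallback='positive-subset'"
        )
    sf = np.exp(log_sf)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Counts divided column-wise by their size factors."""
    return counts.div(size_factors.loc[counts.columns], axis=1)


def filter_low_counts(
    counts: pd.DataFrame, size_factors: pd.Series, threshold: float
) -> tuple[pd.DataFrame, pd.Index]:
    """Drop features whose mean normalized count is below ``threshold``.

    Returns the retained matrix and the index of removed feature ids.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    base_mean = normalize_counts(counts, size_factors).mean(axis=1)
    keep = base_mean >= threshold
    removed = counts.index[~keep]
    if len(removed):
        logger.info("filter_low_counts: removed %d / %d features (threshold=%g)",
                    len(removed), len(counts), threshold)
    return counts.loc[keep], removed


# ---------------------------------------------------------------------------
# NB likelihood and GLM fitting
# ---------------------------------------------------------------------------


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood of counts ``y`` with means ``mu`` and dispersion ``alpha``.

    Written from the gamma-function form of the pmf; tested against a direct
    log-pmf summation.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if alpha < ALPHA_MIN:
        alpha = ALPHA_MIN
    r = 1.0 / alpha
    return float(
        np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1.0)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def _irls(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: float,
    beta0: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """IRLS for the NB log-link GLM; returns (beta, mu, converged)."""
    n, p = X.shape
    if beta0 is None:
        # linear-model start on shifted log counts
        z0 = np.log(y + 0.5) - offset
        beta, *_ = np.linalg.lstsq(X, z0, rcond=None)
    else:
        beta = beta0.copy()
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * w
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError as exc:
            raise GlmError(f"singular information matrix: {exc}") from exc
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            converged = True
            break
    eta = np.clip(X @ beta + offset, -30.0, 30.0)
    mu = np.exp(eta)
    return beta, mu, converged


def fit_nb_glm(
    y: np.ndarray,
    size_factors: np.ndarray,
    alpha: float,
    design: np.ndarray,
    coef_names: list[str],
) -> GlmFit:
    """Fit an NB GLM with log link and offset ``ln s_j`` by IRLS.

    The covariance of the coefficients is the inverse expected Fisher
    information ``(X' W X)^-1`` with ``W = diag(mu / (1 + alpha mu))``.

    Raises
    ------
    GlmError
        For an all-zero response, a rank-deficient design, a group fully at
        zero (separation), or a singular information matrix.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    sf = np.asarray(size_factors, dtype=float)
    if y.shape[0] != X.shape[0] or y.shape[0] != sf.shape[0]:
        raise ValueError("y, size_factors and design rows must align")
    if np.all(y == 0):
        raise GlmError("all counts are zero")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise GlmError("design matrix is rank deficient")
    alpha = max(float(alpha), ALPHA_MIN)
    offset = np.log(sf)
    beta, mu, converged = _irls(y, X, offset, alpha)
    if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 25.0:
        raise GlmError("divergent fit (separation or a group entirely at zero)")
    w = mu / (1.0 + alpha * mu)
    info = (X.T * w) @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise GlmError(f"singular information matrix: {exc}") from exc
    return GlmFit(
        beta=beta, cov=cov, mu=mu, coef_names=list(coef_names),
        converged=converged, alpha=alpha, design=X,
    )


def wald_test(fit: GlmFit, coef: str) -> tuple[float, float, float, float]:
    """Wald test of a named coefficient.

    Returns ``(log2fc, se_log2, z, p)`` where the effect and its standard
    error are on the log2 scale and ``p`` is the two-sided standard-normal
    tail probability.
    """
    if coef not in fit.coef_names:
        raise KeyError(f"coefficient {coef!r} not in fit ({fit.coef_names})")
    idx = fit.coef_names.index(coef)
    beta = fit.beta[idx]
    se = float(np.sqrt(fit.cov[idx, idx]))
    if se == 0.0 or not np.isfinite(se):
        raise GlmError("zero or undefined standard error")
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return beta / LN2, se / LN2, float(z), float(p)


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------


def _moment_alpha(y: np.ndarray, sf: np.ndarray) -> float:
    q = y / sf
    m = q.mean()
    if m <= 0:
        return ALPHA_MIN
    v = q.var(ddof=1)
    return float(np.clip((v - m) / m**2, ALPHA_MIN, ALPHA_MAX))


def _cr_apl(log_alpha: float, y: np.ndarray, mu: np.ndarray, X: np.ndarray) -> float:
    """Cox-Reid adjusted profile log-likelihood at fixed fitted means."""
    alpha = np.exp(log_alpha)
    ll = nb_loglik(y, mu, alpha)
    w = mu / (1.0 + alpha * mu)
    sign, logdet = np.linalg.slogdet((X.T * w) @ X)
    if sign <= 0:
        return -np.inf
    return ll - 0.5 * logdet


def _maximize_alpha(
    y: np.ndarray,
    mu: np.ndarray,
    X: np.ndarray,
    prior: tuple[float, float] | None = None,
) -> float:
    """Maximize the CR-APL (optionally plus a log-normal prior) over log alpha."""

    if prior is None:
        def objective(la: float) -> float:
            return -_cr_apl(la, y, mu, X)
    else:
        log_trend, prior_var = prior

        def objective(la: float) -> float:
            return -_cr_apl(la, y, mu, X) + (la - log_trend) ** 2 / (2.0 * prior_var)

    res = optimize.minimize_scalar(
        objective,
        bounds=(np.log(ALPHA_MIN), np.log(ALPHA_MAX)),
        method="bounded",
        options={"xatol": 1e-4},
    )
    return float(np.exp(res.x))


def _fit_dispersion_trend(base_mean: np.ndarray, disp: np.ndarray) -> tuple[float, float]:
    """Fit the parametric trend ``alpha_tr(mu) = a0 + a1 / mu``.

    Gamma GLM with identity link, fitted by iteratively reweighted least
    squares with outlier-ratio trimming; falls back to a flat trend at the
    median gene-wise dispersion when the fit degenerates.
    """
    use = disp > 10 * ALPHA_MIN
    if use.sum() < 10:
        return float(np.median(disp[disp > 0])) if (disp > 0).any() else 1e-3, 0.0
    mu = base_mean[use]
    d = disp[use]
    X = np.column_stack([np.ones_like(mu), 1.0 / mu])
    coefs = np.array([np.median(d), 0.0])
    for _ in range(12):
        pred = np.clip(X @ coefs, 1e-8, None)
        ratio = d / pred
        keep = (ratio > 1e-4) & (ratio < 15.0)
        if keep.sum() < 10:
            break
        # gamma IRLS with identity link: weights 1/pred^2, response d
        w = 1.0 / pred[keep] ** 2
        Xk = X[keep]
        try:
            new = np.linalg.solve((Xk.T * w) @ Xk, (Xk.T * w) @ d[keep])
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(new)):
            break
        if np.max(np.abs(new - coefs) / np.maximum(np.abs(coefs), 1e-12)) < 1e-6:
            coefs = new
            break
        coefs = new
    a0, a1 = float(coefs[0]), float(coefs[1])
    if a0 <= 0 and a1 <= 0:
        return float(np.median(d)), 0.0
    return max(a0, ALPHA_MIN), max(a1, 0.0)


def estimate_dispersions(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    design: np.ndarray,
    *,
    fixed_alpha: float | None = None,
    min_mu: float = 0.01,
) -> DispersionSet:
    """Per-feature NB dispersions under ``design``.

    Three stages, mirroring the standard shrinkage approach for replicated
    count data:

    1. gene-wise estimate: maximize the Cox-Reid adjusted profile likelihood
       for alpha with fitted means held at the current GLM fit (one refit
       pass at the estimated alpha);
    2. parametric trend ``a0 + a1/mu`` across features;
    3. final estimate: posterior mode under a log-normal prior centred on the
       trend, with prior variance estimated from the spread of gene-wise
       estimates around the trend.  Gene-wise estimates more than ``e**2``
       above the trend are flagged as outliers and left unshrunken.

    ``fixed_alpha`` bypasses the machinery entirely (every feature gets that
    dispersion); use it when there are too few residual degrees of freedom.
    """
    features = counts.index
    if fixed_alpha is not None:
        s = pd.Series(float(fixed_alpha), index=features)
        flag = pd.Series(True, index=features)
        return DispersionSet(
            genewise=s.copy(), trend=s.copy(), final=s.copy(),
            converged=flag, outlier=~flag,
            trend_coefs=(float(fixed_alpha), 0.0), prior_var=PRIOR_VAR_MIN,
        )
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if n - p < 2:
        raise ValueError(
            "fewer than 2 residual degrees of freedom; supply fixed_alpha instead"
        )
    sf = size_factors.loc[counts.columns].to_numpy(dtype=float)
    values = counts.to_numpy(dtype=float)
    base_mean = (values / sf).mean(axis=1)

    genewise = np.full(len(features), ALPHA_MIN)
    converged = np.zeros(len(features), dtype=bool)
    mus = [None] * len(features)
    for i in range(len(features)):
        y = values[i]
        if np.all(y == 0):
            continue
        a0 = _moment_alpha(y, sf)
        try:
            beta, mu, _ = _irls(y, X, np.log(sf), a0)
            mu = np.maximum(mu, min_mu)
            a1 = _maximize_alpha(y, mu, X)
            beta, mu, ok = _irls(y, X, np.log(sf), a1, beta0=beta)
            mu = np.maximum(mu, min_mu)
            a2 = _maximize_alpha(y, mu, X)
            genewise[i] = a2
            converged[i] = ok and np.all(np.isfinite(beta))
            mus[i] = mu
        except (GlmError, np.linalg.LinAlgError):
            genewise[i] = a0
            converged[i] = False
    a0_tr, a1_tr = _fit_dispersion_trend(base_mean, genewise)
    trend = np.clip(a0_tr + a1_tr / np.maximum(base_mean, 1e-8), ALPHA_MIN, ALPHA_MAX)

    log_resid = np.log(np.maximum(genewise, ALPHA_MIN)) - np.log(trend)
    usable = genewise > 10 * ALPHA_MIN
    if usable.sum() >= 10:
        s_lr = stats.median_abs_deviation(log_resid[usable], scale="normal")
    else:
        s_lr = 0.0
    sampling_var = float(special.polygamma(1, max((n - p) / 2.0, 0.5)))
    prior_var = max(s_lr**2 - sampling_var, PRIOR_VAR_MIN)

    outlier = log_resid > DISP_OUTLIER_LOG
    final = np.empty_like(genewise)
    for i in range(len(features)):
        if outlier[i] or mus[i] is None:
            final[i] = genewise[i]
            continue
        final[i] = _maximize_alpha(
            values[i], mus[i], X, prior=(float(np.log(trend[i])), prior_var)
        )
    final = np.clip(final, ALPHA_MIN, ALPHA_MAX)
    idx = features
    return DispersionSet(
        genewise=pd.Series(genewise, index=idx),
        trend=pd.Series(trend, index=idx),
        final=pd.Series(final, index=idx),
        converged=pd.Series(converged, index=idx),
        outlier=pd.Series(outlier, index=idx),
        trend_coefs=(a0_tr, a1_tr),
        prior_var=prior_var,
    )


# ---------------------------------------------------------------------------
# multiple testing and convenience tests
# ---------------------------------------------------------------------------


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are excluded from the family and returned as NaN; the input
    order is restored in the output.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    pm = p[mask]
    if np.any((pm < 0) | (pm > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pm.size
    if m == 0:
        return out
    order = np.argsort(pm, kind="mergesort")
    ranked = pm[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[mask] = restored
    return out


def two_group_design(groups: np.ndarray, reference: str) -> tuple[np.ndarray, list[str]]:
    """Intercept + indicator design for a two-level factor.

    The non-reference level's coefficient is named ``"<other>_vs_<reference>"``.
    """
    levels = [g for g in pd.unique(groups) if g != reference]
    if len(levels) != 1 or reference not in set(groups):
        raise ValueError("groups must contain exactly two levels including the reference")
    other = levels[0]
    X = np.column_stack([np.ones(len(groups)), (np.asarray(groups) == other).astype(float)])
    return X, ["intercept", f"{other}_vs_{reference}"]


def nb_two_group_test(
    y: np.ndarray,
    size_factors: np.ndarray,
    alpha: float,
    groups: np.ndarray,
    reference: str,
) -> dict:
    """Two-group NB Wald test; returns a DE-result row as a dict.

    Keys: baseMean, log2FC, lfcSE, stat, pvalue, status. The log2FC is the
    non-reference group relative to ``reference``.
    """
    sf = np.asarray(size_factors, dtype=float)
    base_mean = float(np.mean(np.asarray(y, dtype=float) / sf))
    try:
        X, names = two_group_design(np.asarray(groups), reference)
        fit = fit_nb_glm(y, sf, alpha, X, names)
        l2fc, se, z, p = wald_test(fit, names[1])
        return {
            "baseMean": base_mean, "log2FC": l2fc, "lfcSE": se,
            "stat": z, "pvalue": p, "status": "tested",
        }
    except GlmError:
        return {
            "baseMean": base_mean, "log2FC": np.nan, "lfcSE": np.nan,
            "stat": np.nan, "pvalue": np.nan, "status": "failed",
        }
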