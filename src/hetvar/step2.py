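"""Step 2: animal model on transformed squared residuals.

The log squared residual ln(e_hat^2) of a record estimates the log of its
residual variance, so an animal model on this response quantifies genetic
(and maternal) effects on micro-environmental sensitivity.  A cube-root
transform of e_hat^2 is offered as an alternative response whose distribution
is closer to normal (Wilson-Hilferty); the log response of a normal residual
is a log-chi-square(1) variable, left-skewed with heavy shoulders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import Pedigree
from .reml import REMLOptions
from .step1 import Step1Fit, Step1ModelSpec, reml_fit

__all__ = [
    "DispersionResponse",
    "Step2Fit",
    "ModelComparison",
    "build_response",
    "fit_dispersion_model",
    "compare_models",
    "response_moments",
]


@dataclass
class DispersionResponse:
    """Transformed squared residuals ready for the dispersion model."""

    values: np.ndarray
    transform: str               # "log" or "cuberoot"
    floored_count: int = 0


@dataclass
class Step2Fit:
    """Dispersion-model fit: variance components on the log (response) scale."""

    inner: Step1Fit              # the underlying animal-model machinery
    response: DispersionResponse

    @property
    def sigma2_Av_exp(self) -> float:
        """Additive genetic variance of the response (log residual variance scale)."""
        return self.inner.sigma2_a

    @property
    def sigma2_m_exp(self) -> float | None:
        return self.inner.sigma2_m

    @property
    def sigma2_eps(self) -> float:
        return float(self.inner.fit.sigma2_resid[0])

    @property
    def loglik(self) -> float:
        return self.inner.loglik

    @property
    def aic(self) -> float:
        return self.inner.aic

    @property
    def bic(self) -> float:
        return self.inner.bic

    @property
    def h2_ln(self) -> float:
        """Heritability of the transformed-residual response."""
        denom = self.sigma2_Av_exp + self.sigma2_eps + (self.sigma2_m_exp or 0.0)
        return self.sigma2_Av_exp / denom

    @property
    def h2_ln_se(self) -> float:
        """Delta-method SE of h2_ln from the component SEs (independence approx.)."""
        sa, se_eps = self.sigma2_Av_exp, self.sigma2_eps
        sm = self.sigma2_m_exp or 0.0
        tot = sa + sm + se_eps
        d_sa = (tot - sa) / tot**2
        d_other = -sa / tot**2
        var = (d_sa * self.inner.fit.se_terms[0]) ** 2
        var += (d_other * self.inner.fit.se_resid[0]) ** 2
        if self.sigma2_m_exp is not None and len(self.inner.fit.se_terms) > 1:
            var += (d_other * self.inner.fit.se_terms[1]) ** 2
        return float(np.sqrt(var))

    def ebv(self, which: str = "direct") -> pd.DataFrame:
        """Dispersion EBVs (log scale) for every pedigree animal."""
        return self.inner.ebv(which)


@dataclass
class ModelComparison:
    lrt_statistic: float
    df: int
    p_value: float              # boundary-corrected (mixture) p-value
    p_value_naive: float        # plain chi-square reference
    delta_aic: float            # full - reduced
    delta_bic: float
    favored_aic: str
    favored_bic: str


def build_response(
    ehat: np.ndarray, transform: str = "log", floor_quantile: float = 1e-6
) -> DispersionResponse:
    """Transform residuals into the dispersion response.

    log: ln(max(e^2, floor)) with the floor set at the ``floor_quantile``
    quantile of the positive squared residuals so behaviour is scale-free;
    cuberoot: (e^2)^(1/3), defined for all residuals.
    """
    e2 = np.asarray(ehat, dtype=float) ** 2
    if transform == "cuberoot":
        return DispersionResponse(values=np.cbrt(e2), transform=transform)
    if transform != "log":
        raise ValueError(f"unknown transform {transform!r}")
    pos = e2[e2 > 0]
    if pos.size == 0:
        raise ValueError("all residuals are zero; degenerate first-step fit")
    # "lower" keeps the floor at an observed value, so the smallest legitimate
    # squared residual is never itself floored
    floor = np.quantile(pos, floor_quantile, method="lower")
    floored = int((e2 < floor).sum())
    if floored:
        warnings.warn(f"{floored} squared residual(s) floored at {floor:.3g}", stacklevel=2)
    return DispersionResponse(
        values=np.log(np.maximum(e2, floor)), transform="log", floored_count=floored
    )


def fit_dispersion_model(
    response: DispersionResponse,
    data: pd.DataFrame,
    pedigree: Pedigree,
    include_direct: bool = True,
    include_maternal: bool = False,
    options: REMLOptions | None = None,
) -> Step2Fit:
    """REML fit of the dispersion animal model.

    Reuses the step-1 engine with a homoscedastic residual on the response
    scale and the same CG fixed factor; covariates are not carried over.
    With ``include_direct=False`` the model keeps fixed effects and residual
    only — the reduced side of the likelihood-ratio test.
    """
    df = data.reset_index(drop=True).copy()
    if len(response.values) != len(df):
        raise ValueError("response not aligned with records")
    df["y"] = response.values
    spec = Step1ModelSpec(
        fixed_factors=("cg",),
        covariates=(),
        maternal_additive=include_maternal,
        residual_structure="hom",
    )
    if include_direct:
        inner = reml_fit(df, pedigree, spec, options=options)
        return Step2Fit(inner=inner, response=response)
    return _fixed_only_fit(df, pedigree, response, options)


def _fixed_only_fit(df, pedigree, response, options) -> Step2Fit:
    """Reduced model without genetic effects: ordinary least squares on CG.

    Packaged as a Step2Fit with sigma2_Av_exp = 0 so it can sit on the reduced
    side of a likelihood-ratio test.  The restricted likelihood is the REML
    likelihood of the fixed-effects-plus-residual model.
    """
    from .step1 import _check_rank, _fixed_design

    spec = Step1ModelSpec(residual_structure="hom")
    y = df["y"].to_numpy(dtype=float)
    X, labels = _fixed_design(df, spec)
    _check_rank(X, labels)
    import scipy.linalg as sla

    Xd = X.toarray()
    n, p = Xd.shape
    XtX = Xd.T @ Xd
    chol = sla.cho_factor(XtX, lower=True)
    beta = sla.cho_solve(chol, Xd.T @ y)
    resid = y - Xd @ beta
    rss = float(resid @ resid)
    s2 = rss / (n - p)
    # REML -2logL of the fixed+residual model (up to the same constant as ai_reml)
    logdet_C = 2.0 * float(np.sum(np.log(np.diag(chol[0])))) - p * np.log(s2)
    m2 = logdet_C + n * np.log(s2) + rss / s2
    fit = _as_reml_fit(labels, beta, resid, s2, m2, n, p, pedigree)
    inner = Step1Fit(
        spec=spec,
        fit=fit,
        data=df,
        pedigree=pedigree,
        fixed_labels=labels,
        sire_of_class=[None],
        sigma2_a=0.0,
    )
    # one free variance component (the residual)
    inner.aic = m2 + 2.0
    inner.bic = m2 + np.log(n - p)
    return Step2Fit(inner=inner, response=response)


def _as_reml_fit(labels, beta, resid, s2, m2, n, p, pedigree):
    from .reml import REMLFit

    return REMLFit(
        term_names=[],
        class_names=[0],
        sigma2_terms=np.array([]),
        sigma2_resid=np.array([s2]),
        se_terms=np.array([]),
        se_resid=np.array([s2 * np.sqrt(2.0 / (n - p))]),
        fixed=beta,
        random={"animal": np.zeros(pedigree.n)},
        residuals=resid,
        loglik=-0.5 * m2,
        n_iter=0,
        converged=True,
        n_records=n,
        rank_X=p,
    )


def compare_models(full: Step2Fit, reduced: Step2Fit) -> ModelComparison:
    """Likelihood-ratio test of nested dispersion models.

    For single boundary-tested variance components the reference distribution
    is the equal mixture of a point mass at zero and chi-square(1); for more
    than one dropped component a plain chi-square(df) is used (conservative).
    The naive chi-square p-value is reported alongside.
    """
    if full.inner.fixed_labels != reduced.inner.fixed_labels:
        raise ValueError("models must share the same fixed effects")
    n_full = len(full.inner.fit.sigma2_terms)
    n_red = len(reduced.inner.fit.sigma2_terms)
    df = n_full - n_red
    if df <= 0:
        raise ValueError("reduced model must drop at least one variance component")
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < 0:
        if stat < -1e-6:
            warnings.warn(
                f"negative LRT statistic ({stat:.3g}) clipped to 0", stacklevel=2
            )
        stat = 0.0
    p_naive = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    if df == 1:
        p_mix = 0.5 * float(stats.chi2.sf(stat, 1)) if stat > 0 else 1.0
    else:
        p_mix = p_naive
    daic = full.aic - reduced.aic
    dbic = full.bic - reduced.bic
    return ModelComparison(
        lrt_statistic=float(stat),
        df=df,
        p_value=p_mix,
        p_value_naive=p_naive,
        delta_aic=float(daic),
        delta_bic=float(dbic),
        favored_aic="full" if daic < 0 else "reduced",
        favored_bic="full" if dbic < 0 else "reduced",
    )


def response_moments(response: DispersionResponse | np.ndarray) -> tuple[float, float]:
    """Sample skewness and excess kurtosis of the dispersion response."""
    x = response.values if isinstance(response, DispersionResponse) else np.asarray(response)
    if x.size < 4:
        raise ValueError("need at least 4 records")
    if np.var(x) == 0:
        raise ValueError("zero-variance response")
    return float(stats.skew(x)), float(stats.kurtosis(x))
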