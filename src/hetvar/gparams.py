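"""Genetic parameters of residual variance on the observed scale.

The dispersion model estimates additive variance on an exponential (log
residual variance) scale.  Under the multiplicative exponential model the
residual variance of an animal is sigma2_e * exp(a_v), a lognormal quantity,
so the additive variance of the residual variance itself is

    sigma2_AV = sigma2_e^2 * (exp(sigma2_Av_exp) - 1)          [kg^4]

which gives the evolvability of residual variance Ev = sigma_AV / sigma2_e =
sqrt(exp(sigma2_Av_exp) - 1), a genetic coefficient of variation independent
of the reference residual variance, and the heritability of residual variance

    h2_v = sigma2_AV / (2 sigma_P^4 + 3 sigma2_AV)

— the regression coefficient of dispersion breeding values on squared
phenotypes, which governs how much information is needed for accurate
dispersion EBVs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .step1 import Step1Fit
from .step2 import Step2Fit

__all__ = [
    "DispersionGeneticSummary",
    "reference_residual_variance",
    "sigma2_av_from_exp",
    "evolvability",
    "h2v",
    "ebv_correlation",
    "summarize_genetic_parameters",
]


@dataclass
class DispersionGeneticSummary:
    """Headline parameters for one (trait, step-1 model) analysis."""

    sigma2_Av_exp: float        # log scale
    sigma2_m_exp: float | None  # log scale, maternal
    sigma2_AV: float            # residual-variance scale, kg^4
    ev_pct: float               # evolvability, %
    h2v_pct: float              # heritability of residual variance, %
    h2_ln: float                # log-scale heritability
    h2_ln_se: float
    r_mv_hat: float | None      # sire-EBV correlation mean vs dispersion
    sigma2_e_hat: float         # reference residual variance, kg^2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def reference_residual_variance(step1: Step1Fit) -> float:
    """sigma2_e for HOM fits; the unweighted mean over sire families for HET."""
    return step1.reference_sigma2_e


def sigma2_av_from_exp(sigma2_Av_exp: float, sigma2_e: float) -> float:
    """Convert log-scale additive variance to the residual-variance scale (kg^4)."""
    if sigma2_Av_exp < 0 or sigma2_e < 0:
        raise ValueError("variances must be non-negative")
    return float(sigma2_e**2 * np.expm1(sigma2_Av_exp))


def sigma2_exp_from_av(sigma2_AV: float, sigma2_e: float) -> float:
    """Inverse conversion (residual-variance scale back to log scale)."""
    return float(np.log1p(sigma2_AV / sigma2_e**2))


def evolvability(sigma2_AV: float, sigma2_e: float) -> float:
    """Ev (%) = 100 * sigma_AV / sigma2_e, the genetic CV of residual variance."""
    if sigma2_e <= 0:
        raise ValueError("sigma2_e must be positive")
    return float(100.0 * np.sqrt(sigma2_AV) / sigma2_e)


def h2v(sigma2_AV: float, sigma2_P: float) -> float:
    """Heritability of residual variance: sigma2_AV / (2 sigma_P^4 + 3 sigma2_AV).

    ``sigma2_P`` is the phenotypic variance (kg^2); sigma_P^4 is its square.
    """
    if sigma2_P <= 0:
        raise ValueError("sigma2_P must be positive")
    return float(sigma2_AV / (2.0 * sigma2_P**2 + 3.0 * sigma2_AV))


def ebv_correlation(
    mean_ebvs: np.ndarray,
    dispersion_ebvs: np.ndarray,
    progeny_counts: np.ndarray,
    min_progeny: int = 50,
) -> float:
    """Pearson correlation of sire EBVs (mean vs dispersion).

    Restricted to sires with more than ``min_progeny`` progeny, where EBVs are
    accurate enough for the correlation to be a meaningful indicator of the
    genetic association between mean and residual variance.
    """
    mean_ebvs = np.asarray(mean_ebvs, dtype=float)
    dispersion_ebvs = np.asarray(dispersion_ebvs, dtype=float)
    progeny_counts = np.asarray(progeny_counts)
    use = progeny_counts > min_progeny
    if use.sum() < 3:
        raise ValueError(f"fewer than 3 sires with more than {min_progeny} progeny")
    x, z = mean_ebvs[use], dispersion_ebvs[use]
    if np.std(x) == 0 or np.std(z) == 0:
        raise ValueError("EBV vector constant over qualifying sires; correlation undefined")
    return float(np.corrcoef(x, z)[0, 1])


def summarize_genetic_parameters(
    step1: Step1Fit,
    step2: Step2Fit,
    min_progeny: int = 50,
) -> DispersionGeneticSummary:
    """Assemble the headline dispersion-genetics summary from both fits."""
    s2e = reference_residual_variance(step1)
    s2av = sigma2_av_from_exp(step2.sigma2_Av_exp, s2e)
    sigma2_P = step1.sigma2_p
    as_sire, _ = step1.pedigree.progeny_counts()
    mean_ebv = step1.fit.random["animal"]
    disp_ebv = step2.inner.fit.random["animal"]
    try:
        r = ebv_correlation(mean_ebv, disp_ebv, as_sire, min_progeny)
    except ValueError:
        r = None
    return DispersionGeneticSummary(
        sigma2_Av_exp=step2.sigma2_Av_exp,
        sigma2_m_exp=step2.sigma2_m_exp,
        sigma2_AV=s2av,
        ev_pct=evolvability(s2av, s2e),
        h2v_pct=100.0 * h2v(s2av, sigma2_P),
        h2_ln=step2.h2_ln,
        h2_ln_se=step2.h2_ln_se,
        r_mv_hat=r,
        sigma2_e_hat=s2e,
    )
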