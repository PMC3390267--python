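"""Step 1: REML animal model for the trait mean.

Fits y = Xb + Z1 a + Z2 m + Wc + e with direct additive effects a (always),
optional maternal additive effects m and maternal permanent-environment
effects c (direct-maternal covariance fixed at zero), and residual structure
either homoscedastic (HOM, one sigma2_e) or heteroscedastic by sire family
(HET, one sigma2_ej per retained sire).  The per-record residuals of the
converged fit feed the dispersion analysis of step 2.

Data editing mirrors routine beef-cattle protocols: records outside
mean +/- 3.5 SD are trimmed, then contemporary groups below a minimum size
and sire families below a minimum progeny count are dropped, iterating the
last two rules to a fixed point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .pedigree import Pedigree, RelationshipFactors, a_inverse, inbreeding
from .reml import RandomTerm, REMLError, REMLFit, REMLOptions, ai_reml

__all__ = [
    "EditRules",
    "Step1ModelSpec",
    "Step1Fit",
    "apply_edit_rules",
    "reml_fit",
    "information_criteria",
    "residuals",
    "cross_validate",
]

HOM = "hom"
HET = "het_sire"


@dataclass(frozen=True)
class EditRules:
    """Record-editing thresholds applied before model fitting."""

    sd_trim: float = 3.5
    min_cg_size: int = 25
    min_sire_progeny: int = 50

    def validate(self) -> None:
        if self.sd_trim <= 0 or self.min_cg_size <= 0 or self.min_sire_progeny <= 0:
            raise ValueError("edit-rule thresholds must be positive")


@dataclass(frozen=True)
class Step1ModelSpec:
    """Model structure for the trait analysis.

    ``covariates`` are (column name, polynomial degree) pairs fitted as fixed
    regressions; ``residual_structure`` is "hom" or "het_sire".
    """

    fixed_factors: tuple = ("cg",)
    covariates: tuple = ()
    maternal_additive: bool = False
    maternal_pe: bool = False
    residual_structure: str = HOM

    def validate(self) -> None:
        if "cg" not in self.fixed_factors:
            raise ValueError("contemporary group must be a fixed factor")
        if self.residual_structure not in (HOM, HET):
            raise ValueError(f"unknown residual structure {self.residual_structure!r}")


@dataclass
class Step1Fit:
    """Converged step-1 fit: components, solutions, residuals, fit statistics."""

    spec: Step1ModelSpec
    fit: REMLFit
    data: pd.DataFrame                  # edited records actually fitted
    pedigree: Pedigree
    fixed_labels: list
    sire_of_class: list                 # HET: sire token per residual class (None = pooled)
    sigma2_a: float = 0.0
    sigma2_m: float | None = None
    sigma2_c: float | None = None
    aic: float = np.nan
    bic: float = np.nan

    @property
    def loglik(self) -> float:
        return self.fit.loglik

    @property
    def sigma2_e(self) -> np.ndarray:
        """Residual variance(s); scalar array for HOM, per-family for HET."""
        return self.fit.sigma2_resid

    @property
    def reference_sigma2_e(self) -> float:
        """sigma2_e for HOM; unweighted mean over sire families for HET."""
        return float(np.mean(self.fit.sigma2_resid))

    @property
    def sigma2_p(self) -> float:
        out = self.sigma2_a + self.reference_sigma2_e
        if self.sigma2_m is not None:
            out += self.sigma2_m
        if self.sigma2_c is not None:
            out += self.sigma2_c
        return out

    @property
    def h2_direct(self) -> float:
        return self.sigma2_a / self.sigma2_p

    def ebv(self, which: str = "direct") -> pd.DataFrame:
        key = {"direct": "animal", "maternal": "maternal"}[which]
        return pd.DataFrame({"animal": self.pedigree.ids, "ebv": self.fit.random[key]})

    def residual_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"animal": self.data["animal"].to_numpy(), "ehat": self.fit.residuals}
        )

    def components_frame(self) -> pd.DataFrame:
        rows = [("sigma2_a", self.sigma2_a, self.fit.se_terms[0])]
        k = 1
        if self.sigma2_m is not None:
            rows.append(("sigma2_m", self.sigma2_m, self.fit.se_terms[k])); k += 1
        if self.sigma2_c is not None:
            rows.append(("sigma2_c", self.sigma2_c, self.fit.se_terms[k])); k += 1
        for c, (s2, se) in enumerate(zip(self.fit.sigma2_resid, self.fit.se_resid)):
            tag = "sigma2_e" if len(self.fit.sigma2_resid) == 1 else (
                f"sigma2_e[{self.sire_of_class[c]}]"
                if self.sire_of_class[c] is not None
                else "sigma2_e[pooled]"
            )
            rows.append((tag, s2, se))
        return pd.DataFrame(rows, columns=["component", "estimate", "se"])


def apply_edit_rules(records: pd.DataFrame, rules: EditRules, pedigree: Pedigree | None = None):
    """Filter records by the trim / CG-size / sire-progeny rules.

    ``records`` needs columns animal, cg, y; the sire is taken from a ``sire``
    column if present, else from the pedigree.  Records with unknown sire are
    removed by the progeny rule (the rule asks for progeny of identified
    sires).  Returns ``(edited records, removal log dict)``.
    """
    rules.validate()
    df = records.copy()
    if "sire" not in df.columns:
        if pedigree is None:
            raise ValueError("need a 'sire' column or a pedigree to derive it")
        ix = pedigree.indices(df["animal"])
        sires = np.where(
            pedigree.sire[ix] >= 0, pedigree.ids[np.maximum(pedigree.sire[ix], 0)], None
        )
        df["sire"] = sires

    log = {"trim": 0, "cg_size": 0, "sire_progeny": 0}
    mu, sd = df["y"].mean(), df["y"].std(ddof=1)
    keep = (df["y"] - mu).abs() <= rules.sd_trim * sd
    log["trim"] = int((~keep).sum())
    df = df[keep]

    while True:
        cg_n = df.groupby("cg")["y"].transform("size")
        keep = cg_n >= rules.min_cg_size
        n_cg = int((~keep).sum())
        df = df[keep]
        sire_n = df.groupby("sire", dropna=False)["y"].transform("size")
        keep = df["sire"].notna() & (sire_n >= rules.min_sire_progeny)
        n_sire = int((~keep).sum())
        df = df[keep]
        log["cg_size"] += n_cg
        log["sire_progeny"] += n_sire
        if n_cg == 0 and n_sire == 0:
            break
    if df.empty:
        raise ValueError("no records survive editing")
    return df.reset_index(drop=True), log


def _fixed_design(df: pd.DataFrame, spec: Step1ModelSpec):
    """Intercept + reference-absorbed factor dummies + covariate polynomials."""
    n = len(df)
    cols = [sp.csr_matrix(np.ones((n, 1)))]
    labels = ["intercept"]
    for fac in spec.fixed_factors:
        codes, levels = pd.factorize(df[fac], sort=True)
        if len(levels) > 1:
            data = np.ones(n)
            m = sp.csr_matrix(
                (data, (np.arange(n), codes)), shape=(n, len(levels))
            )[:, 1:]  # first level absorbed as reference
            cols.append(m)
            labels.extend(f"{fac}={lv}" for lv in levels[1:])
    for name, degree in spec.covariates:
        x = df[name].to_numpy(dtype=float)
        xc = x - x.mean()
        for dgr in range(1, degree + 1):
            cols.append(sp.csr_matrix((xc**dgr)[:, None]))
            labels.append(f"{name}^{dgr}")
    X = sp.hstack(cols, format="csr")
    return X, labels


def _check_rank(X: sp.csr_matrix, labels):
    """Pivoted-QR rank check; names confounded columns (dense, small p only)."""
    p = X.shape[1]
    if p > 2000:
        return  # structural singularity will surface in the MME factorisation
    from scipy.linalg import qr

    _, R, piv = qr(X.toarray(), mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < p:
        bad = [labels[i] for i in piv[rank:]]
        raise REMLError(f"singular fixed-effect design; confounded columns: {bad}")


def _incidence(row_ix: np.ndarray, n_levels: int) -> sp.csr_matrix:
    n = len(row_ix)
    return sp.csr_matrix(
        (np.ones(n), (np.arange(n), row_ix)), shape=(n, n_levels)
    )


def _residual_classes(df, pedigree, structure):
    """Per-record residual class index and sire token per class (HET)."""
    if structure == HOM:
        return np.zeros(len(df), dtype=np.int64), 1, [None]
    ix = pedigree.indices(df["animal"])
    sire_ix = pedigree.sire[ix]
    known = sire_ix >= 0
    classes = np.zeros(len(df), dtype=np.int64)
    sires = np.unique(sire_ix[known])
    pos = {s: k for k, s in enumerate(sires)}
    classes[known] = [pos[s] for s in sire_ix[known]]
    tokens = [str(pedigree.ids[s]) for s in sires]
    if (~known).any():
        classes[~known] = len(sires)  # pooled class for unknown sires
        return classes, len(sires) + 1, tokens + [None]
    return classes, len(sires), tokens


def reml_fit(
    data: pd.DataFrame,
    pedigree: Pedigree,
    spec: Step1ModelSpec | None = None,
    options: REMLOptions | None = None,
    factors: RelationshipFactors | None = None,
    start: np.ndarray | None = None,
) -> Step1Fit:
    """Fit the trait animal model by AI-REML.

    ``data`` must carry animal, cg, y (plus any covariate columns); every
    recorded animal must be in the pedigree.
    """
    spec = spec or Step1ModelSpec()
    spec.validate()
    df = data.reset_index(drop=True)
    y = df["y"].to_numpy(dtype=float)
    X, labels = _fixed_design(df, spec)
    _check_rank(X, labels)

    if factors is None:
        factors = inbreeding(pedigree)
    A_inv = a_inverse(pedigree, factors)
    log_det_A = factors.log_det_A
    a_ix = pedigree.indices(df["animal"])

    terms = [RandomTerm("animal", _incidence(a_ix, pedigree.n), A_inv, log_det_A)]
    if spec.maternal_additive or spec.maternal_pe:
        dam_ix = pedigree.dam[a_ix]
        if (dam_ix < 0).any():
            raise ValueError("maternal terms need a known dam for every record")
    if spec.maternal_additive:
        terms.append(RandomTerm("maternal", _incidence(dam_ix, pedigree.n), A_inv, log_det_A))
    if spec.maternal_pe:
        dams, dcodes = np.unique(dam_ix, return_inverse=True)
        terms.append(RandomTerm("maternal_pe", _incidence(dcodes, len(dams)), None, 0.0))

    classes, n_classes, sire_of_class = _residual_classes(df, pedigree, spec.residual_structure)

    fit = ai_reml(y, X, terms, classes, n_classes, start=start, options=options)

    out = Step1Fit(
        spec=spec,
        fit=fit,
        data=df,
        pedigree=pedigree,
        fixed_labels=labels,
        sire_of_class=sire_of_class,
        sigma2_a=float(fit.sigma2_terms[0]),
        sigma2_m=float(fit.sigma2_terms[fit.term_names.index("maternal")])
        if spec.maternal_additive
        else None,
        sigma2_c=float(fit.sigma2_terms[fit.term_names.index("maternal_pe")])
        if spec.maternal_pe
        else None,
    )
    out.aic, out.bic = information_criteria(out)
    return out


def information_criteria(step1: "Step1Fit") -> tuple[float, float]:
    """AIC/BIC with p = number of free variance components and BIC sample
    size n − rank(X) (the REML degrees of freedom)."""
    fit = step1.fit
    p = len(fit.sigma2_terms) + len(fit.sigma2_resid)
    m2 = -2.0 * fit.loglik
    aic = m2 + 2.0 * p
    bic = m2 + p * np.log(fit.n_records - fit.rank_X)
    return float(aic), float(bic)


def residuals(step1: Step1Fit) -> np.ndarray:
    """Per-record residuals y − (all fitted fixed and random effects)."""
    return step1.fit.residuals


def predict(step1: Step1Fit, newdata: pd.DataFrame) -> np.ndarray:
    """Predict records as fitted fixed effects + pedigree BLUP random effects.

    Factor levels unseen in the training fit fall back to the intercept.
    """
    df = newdata.reset_index(drop=True)
    n = len(df)
    yhat = np.zeros(n)
    pos = {lab: k for k, lab in enumerate(step1.fixed_labels)}
    b = step1.fit.fixed
    yhat += b[pos["intercept"]]
    for fac in step1.spec.fixed_factors:
        for i, lv in enumerate(df[fac]):
            k = pos.get(f"{fac}={lv}")
            if k is not None:
                yhat[i] += b[k]
    for name, degree in step1.spec.covariates:
        x = df[name].to_numpy(dtype=float)
        xtr = step1.data[name].to_numpy(dtype=float)
        xc = x - xtr.mean()
        for dgr in range(1, degree + 1):
            yhat += b[pos[f"{name}^{dgr}"]] * xc**dgr
    a_ix = step1.pedigree.indices(df["animal"])
    yhat += step1.fit.random["animal"][a_ix]
    if step1.spec.maternal_additive or step1.spec.maternal_pe:
        dam_ix = step1.pedigree.dam[a_ix]
    if step1.spec.maternal_additive:
        m = step1.fit.random["maternal"]
        yhat += np.where(dam_ix >= 0, m[np.maximum(dam_ix, 0)], 0.0)
    # maternal PE levels are training-dam specific; unseen dams contribute 0
    if step1.spec.maternal_pe:
        tr_ix = step1.pedigree.indices(step1.data["animal"])
        tr_dams = np.unique(step1.pedigree.dam[tr_ix])
        dmap = {d: k for k, d in enumerate(tr_dams)}
        c = step1.fit.random["maternal_pe"]
        yhat += np.array([c[dmap[d]] if d in dmap else 0.0 for d in dam_ix])
    return yhat


def cross_validate(
    data: pd.DataFrame,
    pedigree: Pedigree,
    spec: Step1ModelSpec | None = None,
    k: int = 10,
    seed: int = 0,
    options: REMLOptions | None = None,
    max_retries: int = 20,
) -> dict:
    """k-fold cross-validation of the step-1 model.

    Records are partitioned into k near-equal random folds; each fold is
    predicted from a refit on the remainder (fixed effects + pedigree-propagated
    BLUPs).  Returns mean MSE over folds plus per-fold values.  The partition
    is re-randomised (bounded retries) until every CG appears in at least two
    folds; CGs that still concentrate in one fold are predicted by the
    intercept when held out.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    df = data.reset_index(drop=True)
    n = len(df)
    rng = np.random.default_rng(seed)
    cg = df["cg"].to_numpy()
    for _ in range(max_retries):
        perm = rng.permutation(n)
        fold = np.empty(n, dtype=np.int64)
        fold[perm] = np.arange(n) % k
        tab = pd.crosstab(cg, fold)
        if ((tab > 0).sum(axis=1) >= 2).all():
            break
    else:
        warnings.warn(
            "some CGs concentrate in a single fold; their held-out records "
            "are predicted by the grand fixed-effect mean",
            stacklevel=2,
        )
    mses = []
    for f in range(k):
        train = df[fold != f]
        test = df[fold == f]
        fit = reml_fit(train, pedigree, spec, options=options)
        pred = predict(fit, test)
        mses.append(float(np.mean((test["y"].to_numpy() - pred) ** 2)))
    return {"mse": float(np.mean(mses)), "fold_mse": mses, "k": k, "seed": seed}
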