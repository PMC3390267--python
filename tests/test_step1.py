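"""Data editing and the step-1 trait animal model."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from hetvar.pedigree import load_pedigree, relationship_submatrix
from hetvar.reml import REMLError
from hetvar.step1 import (
    EditRules,
    Step1ModelSpec,
    apply_edit_rules,
    cross_validate,
    information_criteria,
    predict,
    reml_fit,
)

from conftest import random_pedigree_records


def _records(n_cg=2, per_cg=50, sires=("s1", "s2"), seed=0, sigma=2.0):
    """Simple records frame with an explicit sire column."""
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_cg):
        for i in range(per_cg):
            rows.append(
                {
                    "animal": f"c{c}i{i}",
                    "cg": f"cg{c}",
                    "sire": sires[i % len(sires)],
                    "y": 100.0 + 5 * c + rng.normal(0, sigma),
                }
            )
    return pd.DataFrame(rows)


class TestEditRules:
    def test_clean_data_fully_retained(self):
        df = _records(n_cg=1, per_cg=100, sires=("s1",))
        out, log = apply_edit_rules(df, EditRules(sd_trim=3.5, min_cg_size=25,
                                                  min_sire_progeny=50))
        assert len(out) == 100 and sum(log.values()) == 0

    def test_outlier_trimmed(self):
        df = _records(n_cg=1, per_cg=100, sires=("s1",))
        sd = df["y"].std(ddof=1)
        df.loc[0, "y"] = df["y"].mean() + 4.0 * sd
        out, log = apply_edit_rules(df, EditRules(min_cg_size=25, min_sire_progeny=50))
        assert log["trim"] == 1 and "c0i0" not in set(out["animal"])

    def test_small_cg_dropped(self):
        df = pd.concat(
            [_records(n_cg=1, per_cg=100, sires=("s1",)),
             _records(n_cg=1, per_cg=24, sires=("s1",), seed=1).assign(cg="cg_small")],
            ignore_index=True,
        )
        out, log = apply_edit_rules(df, EditRules(min_cg_size=25, min_sire_progeny=50))
        assert log["cg_size"] == 24 and "cg_small" not in set(out["cg"])

    def test_rules_iterate_to_fixed_point(self):
        # dropping a small sire family shrinks one CG below threshold
        df = pd.concat(
            [_records(n_cg=1, per_cg=60, sires=("s1",)),
             _records(n_cg=1, per_cg=30, sires=("s2",), seed=1).assign(cg="cg1")],
            ignore_index=True,
        )
        # s2 has 30 progeny (< 50) -> removed -> cg1 empties entirely
        out, log = apply_edit_rules(df, EditRules(min_cg_size=25, min_sire_progeny=50))
        assert set(out["cg"]) == {"cg0"}
        assert log["sire_progeny"] == 30

    def test_empty_result_raises(self):
        df = _records(n_cg=1, per_cg=10, sires=("s1",))
        with pytest.raises(ValueError, match="no records survive"):
            apply_edit_rules(df, EditRules(min_cg_size=25, min_sire_progeny=50))


class TestREMLFitToy:
    def test_solutions_match_dense_gls(self):
        """Tiny fit: MME solutions equal the direct GLS/BLUP solve at the
        converged components."""
        ped = load_pedigree(random_pedigree_records(12, 4, 0))
        rng = np.random.default_rng(0)
        animals = [str(t) for t in ped.ids]
        df = pd.DataFrame(
            {"animal": animals, "cg": ["g"] * ped.n,
             "y": 10 + rng.standard_normal(ped.n) * 2}
        )
        fit = reml_fit(df, ped, Step1ModelSpec())
        A = relationship_submatrix(ped, animals)
        s2a, s2e = fit.sigma2_a, fit.reference_sigma2_e
        V = A * s2a + np.eye(ped.n) * s2e
        Vi = np.linalg.inv(V)
        X = np.ones((ped.n, 1))
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ df["y"])
        u = s2a * A @ Vi @ (df["y"] - X @ b)
        assert fit.fit.fixed[0] == pytest.approx(b[0], abs=1e-6)
        np.testing.assert_allclose(fit.fit.random["animal"], u, atol=1e-6)

    def test_residual_identity_and_cg_balance(self, small_dataset):
        ds = small_dataset
        fit = reml_fit(ds.records, ds.pedigree, Step1ModelSpec())
        # residuals are y minus every fitted effect
        np.testing.assert_allclose(
            fit.fit.residuals,
            ds.records["y"].to_numpy() - predict(fit, ds.records),
            atol=1e-8,
        )
        by_cg = pd.Series(fit.fit.residuals).groupby(ds.records["cg"].to_numpy()).mean()
        assert by_cg.abs().max() < 0.5 * fit.fit.residuals.std()

    def test_no_signal_additive_at_boundary(self):
        """CG-plus-noise data (no genetic transmission) -> sigma2_a near floor."""
        ped = load_pedigree(
            [(f"f{i}", "0", "0") for i in range(80)]
        )
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "animal": [f"f{i}" for i in range(80)],
                "cg": ["a"] * 40 + ["b"] * 40,
                "y": np.r_[rng.normal(10, 1, 40), rng.normal(14, 1, 40)],
            }
        )
        fit = reml_fit(df, ped, Step1ModelSpec())
        # founders only: no relatives, so sigma2_a is barely identified and
        # must not absorb meaningful variance
        assert fit.sigma2_a < 0.25 * np.var(df["y"])

    def test_singular_design_raises(self):
        ped = load_pedigree([(f"f{i}", "0", "0") for i in range(6)])
        df = pd.DataFrame(
            {
                "animal": [f"f{i}" for i in range(6)],
                "cg": ["a"] * 3 + ["b"] * 3,
                "dup": ["a"] * 3 + ["b"] * 3,
                "y": [1.0, 2, 3, 4, 5, 6],
            }
        )
        with pytest.raises(REMLError, match="confounded"):
            reml_fit(df, ped, Step1ModelSpec(fixed_factors=("cg", "dup")))


class TestHETStructure:
    def test_family_classes_and_p_count(self, small_dataset):
        ds = small_dataset
        fit = reml_fit(ds.records, ds.pedigree, Step1ModelSpec(residual_structure="het_sire"))
        n_sires = len({s for s in ds.pedigree.sire[ds.pedigree.indices(ds.records["animal"])]})
        assert len(fit.fit.sigma2_resid) == n_sires
        aic, bic = information_criteria(fit)
        # p = 1 additive + one residual variance per family
        assert aic == pytest.approx(-2 * fit.loglik + 2 * (n_sires + 1))
        assert bic == pytest.approx(
            -2 * fit.loglik + (n_sires + 1) * np.log(fit.fit.n_records - fit.fit.rank_X)
        )

    def test_hom_p_is_two(self, small_dataset):
        ds = small_dataset
        fit = reml_fit(ds.records, ds.pedigree, Step1ModelSpec())
        aic, bic = information_criteria(fit)
        assert aic == pytest.approx(-2 * fit.loglik + 4)  # p = 2
        dn = np.log(fit.fit.n_records - fit.fit.rank_X)
        assert bic - aic == pytest.approx(2 * dn - 4)


class TestCrossValidate:
    def test_partition_and_null_mse(self):
        """Pure-noise trait: CV MSE approaches the sample variance."""
        ped = load_pedigree([(f"f{i}", "0", "0") for i in range(120)])
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "animal": [f"f{i}" for i in range(120)],
                "cg": ["g"] * 120,
                "y": rng.normal(50, 3, 120),
            }
        )
        res = cross_validate(df, ped, Step1ModelSpec(), k=5, seed=1)
        assert len(res["fold_mse"]) == 5
        assert res["mse"] == pytest.approx(np.var(df["y"], ddof=1), rel=0.25)

    def test_k_less_than_two_raises(self, small_dataset):
        with pytest.raises(ValueError):
            cross_validate(small_dataset.records, small_dataset.pedigree, k=1)
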