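"""Shared fixtures: small pedigrees, simulated datasets, and one set of
scaled-down Monte Carlo runs reused by every test that needs fitted models."""

from __future__ import annotations

import numpy as np
import pytest

from hetvar.montecarlo import run_replicate
from hetvar.simulate import GeneticParameters, SimulationDesign, simulate_dataset
from hetvar.step1 import EditRules


def random_pedigree_records(n, n_founders, seed):
    """Random acyclic pedigree: parents drawn among earlier animals."""
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        if i < n_founders:
            recs.append((f"a{i}", "0", "0"))
        else:
            s, d = rng.integers(0, i, size=2)
            recs.append((f"a{i}", f"a{s}", f"a{d}"))
    return recs


@pytest.fixture(scope="session")
def test_design():
    """Reduced population keeping 50 progeny per sire: 10 sires, 500 dams,
    2 generations (1000 records)."""
    return SimulationDesign(
        n_base_sires=10,
        n_base_dams=500,
        n_generations=2,
        cg_per_generation=10,
    )


@pytest.fixture(scope="session")
def tiny_design():
    """Very small population for smoke tests (200 records)."""
    return SimulationDesign(
        n_base_sires=4,
        n_base_dams=100,
        offspring_per_sire=25,
        offspring_per_sire_per_cg=5,
        sires_per_cg=2,
        cg_per_generation=10,
        n_generations=2,
    )


@pytest.fixture(scope="session")
def tiny_edit_rules():
    """Edit thresholds matched to the tiny design's CG and family sizes."""
    return EditRules(sd_trim=3.5, min_cg_size=5, min_sire_progeny=10)


@pytest.fixture(scope="session")
def small_dataset(test_design):
    return simulate_dataset(test_design, GeneticParameters(sigma2_Av_exp=0.09), seed=101)


def _mc_runs(design, sigma2_av, model, n_reps, base_seed):
    out = []
    for rep in range(n_reps):
        out.append(
            run_replicate(
                design,
                GeneticParameters(sigma2_Av_exp=sigma2_av, r_mv=0.0),
                model,
                seed=base_seed + rep,
                scenario_index=0,
                replicate=rep,
            )
        )
    return out


@pytest.fixture(scope="session")
def step1_recovery_runs():
    """Fifteen step-1-only HOM fits at the reduced design for the component
    recovery check.  The additive/residual partition wobbles strongly and
    anti-correlated between replicates (sigma2_a_hat SD ~20% per 2000-record
    dataset), so the mean-bias bound needs this many replicates to carry
    information."""
    from hetvar.step1 import Step1ModelSpec, apply_edit_rules, reml_fit

    design = SimulationDesign.small()
    params = GeneticParameters(sigma2_Av_exp=0.09, r_mv=0.0)
    fits = []
    for rep in range(15):
        ds = simulate_dataset(design, params, seed=5000 + rep)
        edited, _ = apply_edit_rules(ds.records, EditRules(), ds.pedigree)
        fits.append(reml_fit(edited, ds.pedigree, Step1ModelSpec()))
    return fits


@pytest.fixture(scope="session")
def mc_suite():
    """Scaled-down replicated two-step analyses shared across acceptance tests.

    Runs at the 2000-record reduced design (20 sires, 1000 dams, 2
    generations), which keeps roughly the full design's ratio of families to
    records; anything smaller makes the dispersion variance essentially
    unidentified.  The strongest-signal scenarios (0.25) get five replicates
    because the HET-vs-HOM accuracy comparison needs the extra precision;
    the others get three.
    """
    design = SimulationDesign.small()
    suite = {}
    for s2, n_reps in ((0.09, 3), (0.25, 5)):
        suite[("hom", s2)] = _mc_runs(design, s2, "hom", n_reps, 2000 + int(s2 * 100))
    for s2, n_reps in ((0.01, 3), (0.09, 3), (0.25, 5)):
        suite[("het_sire", s2)] = _mc_runs(
            design, s2, "het_sire", n_reps, 3000 + int(s2 * 100)
        )
    return suite
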