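"""Replicated simulation study: bias of dispersion-variance estimates and
accuracy of dispersion EBVs under the two-step approach.

Each replicate runs the full pipeline — simulate, edit, step-1 REML (HOM or
HET), residual extraction, step-2 dispersion fit — and records the estimated
components next to the simulation truth.  Scenario summaries mirror the
standard reporting: mean relative bias of sigma2_Av_exp, the sire-EBV
correlation between mean and dispersion, and Pearson accuracies of dispersion
EBVs by animal group (all, sires, dams).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gparams import summarize_genetic_parameters
from .reml import REMLError, REMLOptions
from .simulate import GeneticParameters, SimulatedDataset, SimulationDesign, simulate_dataset
from .step1 import EditRules, Step1ModelSpec, apply_edit_rules, reml_fit
from .step2 import build_response, fit_dispersion_model

__all__ = [
    "ScenarioGrid",
    "ReplicateResult",
    "run_replicate",
    "run_scenario",
    "run_grid",
    "relative_bias",
    "ebv_accuracy",
    "summarize",
]


@dataclass(frozen=True)
class ScenarioGrid:
    """Factorial scenario grid for the simulation study."""

    sigma2_Av_exp_values: tuple = (0.01, 0.09, 0.25)
    r_mv_values: tuple = (-0.5, 0.0, 0.5)
    step1_models: tuple = ("hom", "het_sire")
    n_replicates: int = 20
    master_seed: int = 20120704

    def scenarios(self):
        k = 0
        for s2 in self.sigma2_Av_exp_values:
            for r in self.r_mv_values:
                for model in self.step1_models:
                    yield k, s2, r, model
                    k += 1


def replicate_seed(master_seed: int, scenario_index: int, replicate_index: int) -> int:
    """Deterministic per-replicate seed (stable under resumption), < 2^31."""
    ss = np.random.SeedSequence([master_seed, scenario_index, replicate_index])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


@dataclass
class ReplicateResult:
    scenario_index: int
    replicate: int
    seed: int
    sigma2_Av_exp_true: float
    r_mv_true: float
    step1_model: str
    sigma2_a_hat: float
    sigma2_e_hat: float
    sigma2_Av_exp_hat: float
    sigma2_eps_hat: float
    r_mv_hat: float | None
    acc_all: float
    acc_sires: float
    acc_dams: float
    n_records: int

    def as_row(self) -> dict:
        return dict(self.__dict__)


def ebv_accuracy(truth_av: np.ndarray, ebvs: np.ndarray, group_mask: np.ndarray) -> float:
    """Pearson correlation of true vs estimated dispersion breeding values."""
    x = np.asarray(truth_av, dtype=float)[group_mask]
    z = np.asarray(ebvs, dtype=float)[group_mask]
    if x.size < 3:
        raise ValueError("group too small for a correlation")
    if np.std(x) == 0 or np.std(z) == 0:
        raise ValueError("constant vector; accuracy undefined")
    return float(np.corrcoef(x, z)[0, 1])


def run_replicate(
    design: SimulationDesign,
    params: GeneticParameters,
    step1_model: str,
    seed: int,
    edit_rules: EditRules | None = None,
    options: REMLOptions | None = None,
    transform: str = "log",
    scenario_index: int = 0,
    replicate: int = 0,
) -> ReplicateResult:
    """One complete two-step analysis of one simulated dataset."""
    ds = simulate_dataset(design, params, seed)
    rules = edit_rules or EditRules()
    edited, _ = apply_edit_rules(ds.records, rules, ds.pedigree)

    spec = Step1ModelSpec(residual_structure=step1_model)
    s1 = reml_fit(edited, ds.pedigree, spec, options=options)
    resp = build_response(s1.fit.residuals, transform=transform)
    s2 = fit_dispersion_model(resp, edited, ds.pedigree, options=options)

    summary = summarize_genetic_parameters(s1, s2, min_progeny=rules.min_sire_progeny)

    ped = ds.pedigree
    as_sire, as_dam = ped.progeny_counts()
    disp_ebv = s2.inner.fit.random["animal"]
    truth_av = ds.truth.a_v

    def _acc(mask):
        try:
            return ebv_accuracy(truth_av, disp_ebv, mask)
        except ValueError:
            return np.nan  # degenerate truth (e.g. null dispersion scenario)

    acc_all = _acc(np.ones(ped.n, dtype=bool))
    acc_sires = _acc(as_sire > 0)
    acc_dams = _acc(as_dam > 0)

    return ReplicateResult(
        scenario_index=scenario_index,
        replicate=replicate,
        seed=seed,
        sigma2_Av_exp_true=params.sigma2_Av_exp,
        r_mv_true=params.r_mv,
        step1_model=step1_model,
        sigma2_a_hat=s1.sigma2_a,
        sigma2_e_hat=s1.reference_sigma2_e,
        sigma2_Av_exp_hat=s2.sigma2_Av_exp,
        sigma2_eps_hat=s2.sigma2_eps,
        r_mv_hat=summary.r_mv_hat,
        acc_all=acc_all,
        acc_sires=acc_sires,
        acc_dams=acc_dams,
        n_records=len(edited),
    )


def run_scenario(
    design: SimulationDesign,
    params: GeneticParameters,
    step1_model: str,
    n_reps: int,
    master_seed: int,
    scenario_index: int = 0,
    edit_rules: EditRules | None = None,
    options: REMLOptions | None = None,
    transform: str = "log",
    max_failure_frac: float = 0.2,
) -> list[ReplicateResult]:
    """Run one scenario; failed replicates are redrawn with follow-on seeds."""
    results: list[ReplicateResult] = []
    failures = 0
    max_failures = max(1, int(np.ceil(max_failure_frac * n_reps)))
    rep_ix = 0
    draw = 0
    while len(results) < n_reps:
        seed = replicate_seed(master_seed, scenario_index, draw)
        draw += 1
        try:
            results.append(
                run_replicate(
                    design,
                    params,
                    step1_model,
                    seed,
                    edit_rules=edit_rules,
                    options=options,
                    transform=transform,
                    scenario_index=scenario_index,
                    replicate=rep_ix,
                )
            )
            rep_ix += 1
        except (REMLError, ValueError) as exc:
            failures += 1
            warnings.warn(f"replicate failed ({exc}); redrawing", stacklevel=2)
            if failures > max_failures:
                raise RuntimeError(
                    f"scenario {scenario_index}: {failures} replicate failures "
                    f"out of {draw} draws; aborting"
                ) from exc
    return results


def run_grid(
    grid: ScenarioGrid,
    design: SimulationDesign,
    base_params: GeneticParameters | None = None,
    edit_rules: EditRules | None = None,
    options: REMLOptions | None = None,
    transform: str = "log",
) -> list[ReplicateResult]:
    """Run the full scenario grid; returns all replicate results."""
    base = base_params or GeneticParameters()
    out: list[ReplicateResult] = []
    for k, s2, r, model in grid.scenarios():
        params = replace(base, sigma2_Av_exp=s2, r_mv=r)
        out.extend(
            run_scenario(
                design,
                params,
                model,
                grid.n_replicates,
                grid.master_seed,
                scenario_index=k,
                edit_rules=edit_rules,
                options=options,
                transform=transform,
            )
        )
    return out


def relative_bias(estimates, true_value: float) -> tuple[float, float, float]:
    """(bias %, SD over replicates, SE of the mean) of estimates vs truth."""
    est = np.asarray(list(estimates), dtype=float)
    if true_value == 0:
        raise ValueError("relative bias undefined for a zero true value")
    if est.size < 2:
        raise ValueError("need at least 2 estimates")
    rel = 100.0 * (est - true_value) / true_value
    sd = float(np.std(rel, ddof=1))
    return float(rel.mean()), sd, sd / np.sqrt(est.size)


def summarize(results: list[ReplicateResult]) -> pd.DataFrame:
    """Per-scenario summary: bias of sigma2_Av_exp, r_mv_hat and accuracies.

    Each dispersion measure is reported both as SD and SE over replicates.
    Aggregation is deterministic and permutation-invariant over replicates.
    """
    df = pd.DataFrame([r.as_row() for r in results])
    rows = []
    keys = ["scenario_index", "step1_model", "sigma2_Av_exp_true", "r_mv_true"]
    for key, g in df.sort_values(keys + ["replicate"]).groupby(keys, sort=True):
        scen, model, s2_true, r_true = key
        n = len(g)
        row = {
            "scenario_index": scen,
            "step1_model": model,
            "sigma2_Av_exp_true": s2_true,
            "r_mv_true": r_true,
            "n_replicates": n,
        }
        est = g["sigma2_Av_exp_hat"].to_numpy()
        if n >= 2 and s2_true != 0:
            row["bias_pct"], row["bias_sd"], row["bias_se"] = relative_bias(est, s2_true)
        else:
            row["bias_pct"] = (
                float(100.0 * (est.mean() - s2_true) / s2_true) if s2_true else np.nan
            )
            row["bias_sd"] = row["bias_se"] = np.nan
        row["sigma2_Av_exp_hat_mean"] = float(est.mean())
        for col, tag in [
            ("r_mv_hat", "r_mv_hat"),
            ("acc_all", "acc_all"),
            ("acc_sires", "acc_sires"),
            ("acc_dams", "acc_dams"),
        ]:
            v = g[col].astype(float).to_numpy()
            v = v[~np.isnan(v)]
            row[f"{tag}_mean"] = float(v.mean()) if v.size else np.nan
            row[f"{tag}_sd"] = float(np.std(v, ddof=1)) if v.size > 1 else np.nan
            row[f"{tag}_se"] = (
                float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
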