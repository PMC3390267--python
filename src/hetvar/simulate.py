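"""Monte Carlo generator for traits with genetic heterogeneity of residual variance.

Phenotypes follow the multiplicative exponential model

    y_ij = b_m(i) + a_m(j) + exp((b_v(i) + a_v(j)) / 2) * eps_ij,   eps ~ N(0, 1)

where contemporary group (CG) i contributes a fixed effect on the mean
(b_m, kg) and on the log residual variance (b_v, log-kg^2), and animal j
carries a pair of breeding values: a_m for the mean and a_v for the log
residual variance, jointly multivariate normal with additive variances
sigma2_a and sigma2_Av_exp and genetic correlation r_mv.  The expected
residual variance for a group is exp(b_v) * exp(sigma2_Av_exp / 2).

Defaults reproduce a beef-cattle-like design: 100 base sires, 5000 base dams,
5 generations of 5000 recorded offspring (25 000 records), 50 offspring per
sire split 10-per-CG over 5 CGs, 1 offspring per dam, 20% replacement of both
sexes per generation, random mating, no selection.  Under the default genetic
parameters (sigma2_a = 200, b_m ~ U(300, 400), b_v ~ U(5.40, 5.80)) the trait
has mean 350 kg, phenotypic variance near 480 kg^2 and heritability near 0.40.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pedigree import UNKNOWN, Pedigree, RelationshipFactors, inbreeding, load_pedigree

__all__ = [
    "SimulationDesign",
    "GeneticParameters",
    "TrueEffects",
    "SimulatedDataset",
    "build_population",
    "draw_effects",
    "simulate_phenotypes",
    "simulate_on_pedigree",
    "simulate_dataset",
    "expected_residual_variance",
    "mean_expected_residual_variance",
    "expected_heritability",
]


@dataclass(frozen=True)
class SimulationDesign:
    """Population structure of the generator.

    The CG layout constraint is
    ``sires_per_cg * offspring_per_sire_per_cg * cg_per_generation
    == n_base_dams * offspring_per_dam`` (records per generation), and each
    sire's ``offspring_per_sire`` offspring are split into blocks of
    ``offspring_per_sire_per_cg`` across distinct CGs.
    """

    n_base_sires: int = 100
    n_base_dams: int = 5000
    offspring_per_sire: int = 50
    offspring_per_dam: int = 1
    n_generations: int = 5
    replacement_rate: float = 0.20
    cg_per_generation: int = 100
    sires_per_cg: int = 5
    offspring_per_sire_per_cg: int = 10

    @property
    def records_per_generation(self) -> int:
        return self.n_base_dams * self.offspring_per_dam

    @property
    def n_records(self) -> int:
        return self.records_per_generation * self.n_generations

    def validate(self) -> None:
        if min(
            self.n_base_sires,
            self.n_base_dams,
            self.offspring_per_sire,
            self.offspring_per_dam,
            self.n_generations,
            self.cg_per_generation,
            self.sires_per_cg,
            self.offspring_per_sire_per_cg,
        ) <= 0:
            raise ValueError("all design counts must be positive")
        if not 0.0 <= self.replacement_rate < 1.0:
            raise ValueError("replacement_rate must be in [0, 1)")
        rpg = self.records_per_generation
        if self.sires_per_cg * self.offspring_per_sire_per_cg * self.cg_per_generation != rpg:
            raise ValueError(
                "sires_per_cg * offspring_per_sire_per_cg * cg_per_generation "
                f"must equal records per generation ({rpg})"
            )
        if self.offspring_per_sire % self.offspring_per_sire_per_cg:
            raise ValueError("offspring_per_sire must be a multiple of offspring_per_sire_per_cg")
        blocks_per_sire = self.offspring_per_sire // self.offspring_per_sire_per_cg
        if self.n_base_sires * blocks_per_sire != self.cg_per_generation * self.sires_per_cg:
            raise ValueError("sire blocks do not tile the CG grid")
        if self.n_base_sires * self.offspring_per_sire != rpg:
            raise ValueError("offspring_per_sire inconsistent with dam-side record count")

    @classmethod
    def small(cls) -> "SimulationDesign":
        """Scaled-down preset: 2 generations, 20 sires, 1000 dams (2000 records)."""
        return cls(
            n_base_sires=20,
            n_base_dams=1000,
            n_generations=2,
            cg_per_generation=20,
        )


@dataclass(frozen=True)
class GeneticParameters:
    """Variances of the bivariate (mean, log-variance) breeding-value model."""

    sigma2_a: float = 200.0
    sigma2_Av_exp: float = 0.09
    r_mv: float = 0.0
    b_m_range: tuple[float, float] = (300.0, 400.0)
    b_v_range: tuple[float, float] = (5.40, 5.80)

    def validate(self) -> None:
        if self.sigma2_a <= 0:
            raise ValueError("sigma2_a must be > 0")
        if self.sigma2_Av_exp < 0:
            raise ValueError("sigma2_Av_exp must be >= 0")
        if abs(self.r_mv) > 1:
            raise ValueError("|r_mv| must be <= 1")
        for lo, hi in (self.b_m_range, self.b_v_range):
            if not lo <= hi:
                raise ValueError("effect ranges must be ordered (lo <= hi)")

    @property
    def G_mv(self) -> np.ndarray:
        """2x2 genetic covariance matrix of (a_m, a_v)."""
        cov = self.r_mv * np.sqrt(self.sigma2_a * self.sigma2_Av_exp)
        return np.array([[self.sigma2_a, cov], [cov, self.sigma2_Av_exp]])


@dataclass
class TrueEffects:
    """True simulated effects, indexed like the pedigree / CG tables."""

    cg_ids: np.ndarray        # CG tokens
    b_m: np.ndarray           # per-CG mean effect, kg
    b_v: np.ndarray           # per-CG log-variance effect, log-kg^2
    a_m: np.ndarray           # per-animal breeding value for the mean, kg
    a_v: np.ndarray           # per-animal breeding value for log residual variance

    def cg_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cg": self.cg_ids, "b_m": self.b_m, "b_v": self.b_v})


@dataclass
class SimulatedDataset:
    """Phenotype records plus the full simulation truth."""

    records: pd.DataFrame       # columns: animal, cg, y
    pedigree: Pedigree
    truth: TrueEffects
    epsilon: np.ndarray         # the standard-normal draws, one per record
    params: GeneticParameters
    design: SimulationDesign | None = None

    @property
    def n_records(self) -> int:
        return len(self.records)

    def truth_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        animals = pd.DataFrame(
            {"animal": self.pedigree.ids, "a_m": self.truth.a_m, "a_v": self.truth.a_v}
        )
        return animals, self.truth.cg_frame()


def _streams(seed, *names):
    """Independent named RNG streams derived from one master seed."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def build_population(design: SimulationDesign, seed: int):
    """Simulate the pedigree and CG assignment of the artificial population.

    Returns ``(pedigree, cg_assignment)`` where ``cg_assignment`` is a
    DataFrame (animal, cg) covering every recorded (non-base) animal.  CG
    tokens are ``g{generation}c{index}`` so groups are generation-specific.
    Each CG holds ``sires_per_cg`` blocks of ``offspring_per_sire_per_cg``
    progeny from distinct sires; a random permutation plus round-robin offset
    keeps the blocks of one sire in distinct CGs.
    """
    design.validate()
    rng = _streams(seed, "pedigree")["pedigree"]

    records = []  # (animal, sire, dam, sex)
    sires = [f"S0_{i}" for i in range(design.n_base_sires)]
    dams = [f"D0_{i}" for i in range(design.n_base_dams)]
    for s in sires:
        records.append((s, UNKNOWN, UNKNOWN, "M"))
    for d in dams:
        records.append((d, UNKNOWN, UNKNOWN, "F"))

    cg_rows = []
    blocks_per_sire = design.offspring_per_sire // design.offspring_per_sire_per_cg
    for g in range(1, design.n_generations + 1):
        # sire-block -> CG assignment: permute sires, offset per block round so
        # the blocks of one sire land in blocks_per_sire distinct CGs.
        perm = rng.permutation(design.n_base_sires)
        slots: list[tuple[int, int]] = []
        for r in range(blocks_per_sire):
            for pos, s_ix in enumerate(perm):
                slots.append(((pos + r) % design.cg_per_generation, int(s_ix)))
        # dams permuted over the record slots (each dam offspring_per_dam times)
        dam_perm = rng.permutation(
            np.repeat(np.arange(design.n_base_dams), design.offspring_per_dam)
        )
        dam_iter = iter(dam_perm)
        rec_ix = 0
        gen_offspring = {"M": [], "F": []}
        for cg_local, s_ix in slots:
            cg = f"g{g}c{cg_local}"
            for _ in range(design.offspring_per_sire_per_cg):
                a = f"G{g}_{rec_ix}"
                d_ix = int(next(dam_iter))
                sex = "M" if rng.random() < 0.5 else "F"
                records.append((a, sires[s_ix], dams[d_ix], sex))
                cg_rows.append((a, cg))
                gen_offspring[sex].append(a)
                rec_ix += 1
        # replacement for next generation
        if g < design.n_generations:
            n_rs = max(1, int(round(design.replacement_rate * design.n_base_sires)))
            n_rd = max(1, int(round(design.replacement_rate * design.n_base_dams)))
            if len(gen_offspring["M"]) < n_rs or len(gen_offspring["F"]) < n_rd:
                raise ValueError("not enough offspring of each sex for replacement")
            out_s = rng.choice(design.n_base_sires, size=n_rs, replace=False)
            new_s = rng.choice(len(gen_offspring["M"]), size=n_rs, replace=False)
            for slot, who in zip(out_s, new_s):
                sires[slot] = gen_offspring["M"][who]
            out_d = rng.choice(design.n_base_dams, size=n_rd, replace=False)
            new_d = rng.choice(len(gen_offspring["F"]), size=n_rd, replace=False)
            for slot, who in zip(out_d, new_d):
                dams[slot] = gen_offspring["F"][who]

    ped = load_pedigree(records)
    cg = pd.DataFrame(cg_rows, columns=["animal", "cg"])
    return ped, cg


def draw_effects(
    ped: Pedigree,
    cg_ids,
    params: GeneticParameters,
    seed: int,
    factors: RelationshipFactors | None = None,
) -> TrueEffects:
    """Draw CG effects and bivariate breeding values down the pedigree.

    Founders are MVN(0, G_mv); non-founders are the midparent average plus a
    Mendelian-sampling deviate with covariance d_i * G_mv, where d_i is the
    inbreeding-adjusted Mendelian variance scaling from the pedigree
    (0.5 (1 − (F_s + F_d)/2) for two known parents).
    """
    params.validate()
    rngs = _streams(seed, "cg_effects", "breeding_values")
    rng_cg, rng_bv = rngs["cg_effects"], rngs["breeding_values"]

    cg_ids = np.asarray(list(dict.fromkeys(cg_ids)), dtype=object)
    b_m = rng_cg.uniform(*params.b_m_range, size=len(cg_ids))
    b_v = rng_cg.uniform(*params.b_v_range, size=len(cg_ids))

    if factors is None:
        factors = inbreeding(ped)
    G = params.G_mv
    # Cholesky factor handling the degenerate sigma2_Av_exp = 0 case exactly.
    L = _chol_psd(G)
    z = rng_bv.standard_normal((ped.n, 2))
    ms = z @ L.T  # Mendelian deviates before scaling, one pair per animal
    a = np.zeros((ped.n, 2))
    sire, dam = ped.sire, ped.dam
    d = factors.mendelian_diag
    for i in range(ped.n):
        s, dm = sire[i], dam[i]
        if s < 0 and dm < 0:
            a[i] = ms[i]  # founder: full G_mv
        else:
            mid = np.zeros(2)
            if s >= 0:
                mid += 0.5 * a[s]
            if dm >= 0:
                mid += 0.5 * a[dm]
            a[i] = mid + np.sqrt(d[i]) * ms[i]
    return TrueEffects(cg_ids=cg_ids, b_m=b_m, b_v=b_v, a_m=a[:, 0], a_v=a[:, 1])


def _chol_psd(G: np.ndarray) -> np.ndarray:
    """Lower Cholesky-like factor valid for positive semi-definite 2x2 G."""
    if G[1, 1] <= 0:
        L = np.zeros((2, 2))
        L[0, 0] = np.sqrt(G[0, 0])
        return L
    return np.linalg.cholesky(G + 0.0)


def simulate_phenotypes(
    ped: Pedigree,
    cg_assignment: pd.DataFrame,
    truth: TrueEffects,
    seed: int,
) -> pd.DataFrame:
    """Evaluate the exponential model for every assigned record.

    Returns a DataFrame (animal, cg, y, epsilon); ``y`` is reproducible
    bit-exactly from the truth and the stored epsilon draws.
    """
    rng = _streams(seed, "epsilon")["epsilon"]
    animals = cg_assignment["animal"].to_numpy(dtype=object)
    cgs = cg_assignment["cg"].to_numpy(dtype=object)
    a_ix = ped.indices(animals)
    cg_pos = {c: i for i, c in enumerate(truth.cg_ids)}
    try:
        c_ix = np.array([cg_pos[c] for c in cgs], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"record CG {exc.args[0]!r} has no simulated effects") from None
    eps = rng.standard_normal(len(animals))
    y = (
        truth.b_m[c_ix]
        + truth.a_m[a_ix]
        + np.exp(0.5 * (truth.b_v[c_ix] + truth.a_v[a_ix])) * eps
    )
    return pd.DataFrame({"animal": animals, "cg": cgs, "y": y, "epsilon": eps})


def simulate_on_pedigree(
    ped: Pedigree,
    cg_assignment: pd.DataFrame,
    params: GeneticParameters,
    seed: int,
    design: SimulationDesign | None = None,
) -> SimulatedDataset:
    """Run the generative model on an arbitrary pedigree + CG map."""
    if not {"animal", "cg"}.issubset(cg_assignment.columns):
        raise ValueError("cg_assignment needs columns animal, cg")
    missing = [a for a in cg_assignment["animal"] if str(a) not in ped.index_of]
    if missing:
        raise ValueError(f"recorded animal {missing[0]!r} not in pedigree")
    truth = draw_effects(ped, cg_assignment["cg"], params, seed)
    rec = simulate_phenotypes(ped, cg_assignment, truth, seed)
    return SimulatedDataset(
        records=rec[["animal", "cg", "y"]],
        pedigree=ped,
        truth=truth,
        epsilon=rec["epsilon"].to_numpy(),
        params=params,
        design=design,
    )


def simulate_dataset(
    design: SimulationDesign, params: GeneticParameters, seed: int
) -> SimulatedDataset:
    """Full generator: population structure, effects, phenotypes."""
    ped, cg = build_population(design, seed)
    return simulate_on_pedigree(ped, cg, params, seed, design=design)


def expected_residual_variance(b_v: float, sigma2_Av_exp: float) -> float:
    """E[Var(e | CG)] = exp(b_v) * exp(sigma2_Av_exp / 2) under the exponential model."""
    return float(np.exp(b_v) * np.exp(sigma2_Av_exp / 2.0))


def mean_expected_residual_variance(params: GeneticParameters) -> float:
    """Expected residual variance averaged over b_v ~ U(b_v_range)."""
    lo, hi = params.b_v_range
    if hi == lo:
        mean_exp_bv = np.exp(lo)
    else:
        mean_exp_bv = (np.exp(hi) - np.exp(lo)) / (hi - lo)
    return float(mean_exp_bv * np.exp(params.sigma2_Av_exp / 2.0))


def expected_heritability(params: GeneticParameters) -> float:
    """sigma2_a / (sigma2_a + E[sigma2_e]) for the simulated trait."""
    s2e = mean_expected_residual_variance(params)
    return params.sigma2_a / (params.sigma2_a + s2e)
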