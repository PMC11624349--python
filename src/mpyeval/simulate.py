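"""Synthetic multi-herd data generator.

Emulates the statistical structure of a commercial-farm evaluation dataset
(~23 herds, ~541 Holstein cows): cow traits are drawn from truncated
normal marginals with herd-level random intercepts, and nutrient supplies
for the two DMI scenarios are generated multiplicatively from a single
per-cow intake propensity, which induces the dominant supply covariance
(MP, DE, amino-acid flows all scale with intake). Observed milk protein
yield can come from a configurable truth model, so that metric-recovery
behaviour of the whole pipeline is testable without the real farm data.

One-sidedly truncated traits (notably DIM, whose lower bound sits only
1.55 SD below the mean) are drawn from truncated normals whose underlying
mean is solved numerically so the *truncated* mean equals the configured
target; naive truncation would otherwise inflate the DIM mean by ~7%.

All randomness flows through a single :class:`numpy.random.Generator`, so
identical config + seed gives a bit-identical data set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import optimize
from scipy.stats import truncnorm

from . import prediction
from .types import (CowRecord, ExpenditureProfile, InvalidInputError, Scenario,
                    SupplyProfile)

__all__ = [
    "ScenarioConfig",
    "GeneratorConfig",
    "SyntheticHerdSet",
    "generate_cows",
    "generate_supplies",
    "simulate_observed_mpy",
    "generate_herd_set",
]

TRUTH_MODELS = ("eff_model", "multi_model", "external_table")


@dataclass(frozen=True)
class ScenarioConfig:
    """Supply-generation parameters for one DMI scenario.

    Per-kg-DMI ratios are calibrated so that at the scenario's mean DMI the
    mean supplies land on the dataset's summary table; noise CVs are the
    residual dispersion beyond what the DMI spread already induces.
    """

    dmi_mean: float
    dmi_sd: float
    mp_per_kg_dmi: float      # g MP / kg DMI
    de_per_kg_dmi: float      # Mcal / kg DMI
    denp_frac: float          # non-protein fraction of DE intake
    dndf_per_kg_dmi: float    # kg digestible NDF / kg DMI
    mp_noise_cv: float
    de_noise_cv: float
    denp_frac_sd: float
    dndf_noise_cv: float
    # digested AA flows as fractions of MP supply
    aa_frac: Dict[str, float] = field(default_factory=lambda: {
        "his": 0.0222, "ile": 0.0597, "leu": 0.0889, "lys": 0.0748, "met": 0.0219})
    aa_noise_cv: float = 0.07
    oaa_frac: float = 0.882
    oaa_noise_cv: float = 0.02


def _default_scenarios() -> Dict[Scenario, ScenarioConfig]:
    # Ratios written as the quotients that define them (mean supply over
    # mean DMI for that scenario); noise CVs chosen so the product of DMI
    # spread and residual noise reproduces the supply SDs.
    ao = ScenarioConfig(
        dmi_mean=23.4, dmi_sd=2.5,
        mp_per_kg_dmi=2059.0 / 23.4,
        de_per_kg_dmi=71.5 / 23.4,
        denp_frac=56.4 / 71.5,
        dndf_per_kg_dmi=5.7 / 23.4,
        mp_noise_cv=0.083, de_noise_cv=0.038,
        denp_frac_sd=0.008, dndf_noise_cv=0.116,
    )
    ar = ScenarioConfig(
        dmi_mean=20.9, dmi_sd=2.8,
        mp_per_kg_dmi=1853.0 / 20.9,
        de_per_kg_dmi=62.8 / 20.9,
        denp_frac=49.6 / 62.8,
        dndf_per_kg_dmi=4.8 / 20.9,
        mp_noise_cv=0.066, de_noise_cv=0.041,
        denp_frac_sd=0.008, dndf_noise_cv=0.057,
    )
    return {Scenario.DMI_Ao: ao, Scenario.DMI_AR: ar}


@dataclass(frozen=True)
class GeneratorConfig:
    """Full configuration of the synthetic herd generator.

    Cow-trait means/SDs and truncation bounds default to the source
    dataset's descriptive statistics; expenditure scalings are calibrated
    on the animal-only DMI scenario.
    """

    n_herds: int = 23
    cows_per_herd_mean: float = 44.8
    cows_per_herd_sd: float = 16.9
    min_herd_size: int = 2
    n_cows: Optional[int] = 541   # total; herd sizes adjusted to sum here

    bw_mean: float = 672.0
    bw_sd: float = 57.7
    bw_bounds: Tuple[float, float] = (535.0, 841.0)
    dim_mean: float = 202.0
    dim_sd: float = 116.0
    dim_bounds: Tuple[float, float] = (22.0, 684.0)
    parity_mean: float = 2.4
    parity_sd: float = 1.5
    parity_bounds: Tuple[int, int] = (1, 8)
    rha_mean: float = 304.0
    rha_sd: float = 57.0
    rha_bounds: Tuple[float, float] = (151.0, 479.0)
    mpy_mean: float = 894.0
    mpy_sd: float = 248.0
    mpy_bounds: Tuple[float, float] = (211.0, 1601.0)
    rha_missing_rate: float = 13.0 / 541.0

    herd_effect_sd: float = 0.10   # multiplicative lognormal CV on production traits
    bw_herd_sd: float = 0.03       # same, dampened, on body weight

    scenarios: Dict[Scenario, ScenarioConfig] = field(default_factory=_default_scenarios)

    # expenditures (MP basis), calibrated at reference BW / per kg DMI
    tpuri_ref: float = 223.0          # g/d at 672 kg BW
    tpuri_noise_cv: float = 0.02
    tpfecal_per_kg_dmi: float = 18.0  # g / kg DMI
    tpfecal_noise_cv: float = 0.08
    tpscurf_ref: float = 12.0         # g/d at 672 kg BW
    tpscurf_noise_cv: float = 0.05
    growth_primiparous_mean: float = 26.0  # g/d, parity 1 only
    growth_primiparous_sd: float = 1.0
    target_eff: float = 0.69

    # observed-MPY truth model
    truth_model: str = "eff_model"
    truth_scenario: Scenario = Scenario.DMI_Ao
    noise_sd: float = 0.10         # lognormal sigma on observed MPY

    def __post_init__(self) -> None:
        for name in ("cows_per_herd_sd", "bw_sd", "dim_sd", "parity_sd",
                     "rha_sd", "mpy_sd", "herd_effect_sd", "bw_herd_sd",
                     "noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        for name in ("bw", "dim", "rha", "mpy"):
            lo, hi = getattr(self, f"{name}_bounds")
            if not lo < hi:
                raise InvalidInputError(f"{name}_bounds must be ordered")
            mean = getattr(self, f"{name}_mean")
            if not lo <= mean <= hi:
                raise InvalidInputError(f"{name}_mean outside its bounds")
        if not 0 <= self.rha_missing_rate <= 1:
            raise InvalidInputError("rha_missing_rate must be in [0, 1]")
        if self.truth_model not in TRUTH_MODELS:
            raise InvalidInputError(
                f"truth_model must be one of {TRUTH_MODELS}, got {self.truth_model!r}")


@dataclass
class SyntheticHerdSet:
    """A generated data set: cows, per-scenario supply/expenditure profiles
    and the latent truth used to produce the observed yields."""

    cows: List[CowRecord]
    supplies: Dict[Tuple[str, Scenario], SupplyProfile]
    expenditures: Dict[Tuple[str, Scenario], ExpenditureProfile]
    truth_mpy: Dict[str, float] = field(default_factory=dict)   # noiseless MPY, g/d
    truth_eff: Dict[str, float] = field(default_factory=dict)   # latent efficiency, %
    herd_factors: Dict[str, float] = field(default_factory=dict)
    config: Optional[GeneratorConfig] = None

    @property
    def scenarios(self) -> List[Scenario]:
        return sorted({k[1] for k in self.supplies}, key=lambda s: s.value)


def _mean_matched_truncnorm(rng: np.random.Generator, size: int, target_mean: float,
                            sd: float, lo: float, hi: float) -> np.ndarray:
    """Draw from a truncated normal on [lo, hi] whose truncated mean equals
    ``target_mean`` (underlying location solved numerically)."""
    if sd == 0:
        return np.full(size, float(target_mean))

    def trunc_mean(mu: float) -> float:
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return truncnorm.mean(a, b, loc=mu, scale=sd)

    span = 8 * sd
    mu = optimize.brentq(lambda m: trunc_mean(m) - target_mean,
                         target_mean - span, target_mean + span, xtol=1e-10)
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def _lognoise(rng: np.random.Generator, size: int, cv: float) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with sigma = cv."""
    if cv == 0:
        return np.ones(size)
    return rng.lognormal(mean=-0.5 * cv**2, sigma=cv, size=size)


def _herd_sizes(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    sizes = np.rint(rng.normal(config.cows_per_herd_mean, config.cows_per_herd_sd,
                               size=config.n_herds)).astype(int)
    sizes = np.maximum(sizes, config.min_herd_size)
    if config.n_cows is not None:
        # nudge herds round-robin until the total matches, respecting the floor
        diff = config.n_cows - int(sizes.sum())
        i = 0
        while diff != 0:
            j = i % config.n_herds
            if diff > 0:
                sizes[j] += 1
                diff -= 1
            elif sizes[j] > config.min_herd_size:
                sizes[j] -= 1
                diff += 1
            i += 1
    return sizes


def generate_cows(config: GeneratorConfig, seed: int) -> List[CowRecord]:
    """Draw herd structure and cow traits.

    Herd sizes come from a rounded normal (floored at ``min_herd_size``
    and, when ``n_cows`` is set, adjusted to sum to it). Cow traits are
    truncated-normal marginals; a herd-level multiplicative lognormal
    intercept (mean one) shifts BW and the production traits (RHA and the
    marginal observed MPY). RHA is set missing at ``rha_missing_rate``.
    """
    rng = np.random.default_rng(seed)
    return _generate_cows_rng(config, rng)[0]


def _generate_cows_rng(config: GeneratorConfig, rng: np.random.Generator):
    sizes = _herd_sizes(config, rng)
    n = int(sizes.sum())
    herd_ids = [f"H{h + 1:03d}" for h in range(config.n_herds)]
    herd_of_cow = np.repeat(np.arange(config.n_herds), sizes)

    prod_factor_h = _lognoise(rng, config.n_herds, config.herd_effect_sd)
    bw_factor_h = _lognoise(rng, config.n_herds, config.bw_herd_sd)

    bw = _mean_matched_truncnorm(rng, n, config.bw_mean, config.bw_sd, *config.bw_bounds)
    bw = np.clip(bw * bw_factor_h[herd_of_cow], *config.bw_bounds)
    dim = _mean_matched_truncnorm(rng, n, config.dim_mean, config.dim_sd, *config.dim_bounds)
    parity_raw = _mean_matched_truncnorm(rng, n, config.parity_mean, config.parity_sd,
                                         float(config.parity_bounds[0]),
                                         float(config.parity_bounds[1]))
    parity = np.clip(np.rint(parity_raw).astype(int), *config.parity_bounds)
    rha = _mean_matched_truncnorm(rng, n, config.rha_mean, config.rha_sd, *config.rha_bounds)
    rha = np.clip(rha * prod_factor_h[herd_of_cow], *config.rha_bounds)
    mpy = _mean_matched_truncnorm(rng, n, config.mpy_mean, config.mpy_sd, *config.mpy_bounds)
    mpy = np.clip(mpy * prod_factor_h[herd_of_cow], *config.mpy_bounds)
    missing = rng.random(n) < config.rha_missing_rate

    cows = [
        CowRecord(cow_id=f"C{i + 1:04d}", herd_id=herd_ids[herd_of_cow[i]],
                  parity=int(parity[i]), bw=float(bw[i]), dim=float(dim[i]),
                  mpy_obs=float(mpy[i]),
                  rha=None if missing[i] else float(rha[i]))
        for i in range(n)
    ]
    herd_factors = {herd_ids[h]: float(prod_factor_h[h]) for h in range(config.n_herds)}
    return cows, herd_factors


def generate_supplies(cow: CowRecord, scenario: Scenario, config: GeneratorConfig,
                      rng: np.random.Generator, intake_z: Optional[float] = None,
                      ) -> Tuple[SupplyProfile, ExpenditureProfile]:
    """Generate one cow's supply and expenditure profiles for a scenario.

    DMI is drawn per scenario (optionally from a shared per-cow intake
    propensity ``intake_z``, which correlates the two scenarios); MP, DE
    and digestible NDF scale multiplicatively with DMI, each amino-acid
    flow is its configured fraction of MP with independent lognormal
    noise, and ``eaa_sq`` is computed exactly from the five drawn EAA.
    Urinary endogenous and scurf losses scale with body weight, metabolic
    fecal loss with DMI; growth deposition is positive for first-parity
    cows only.
    """
    sc = config.scenarios[scenario]
    z = float(rng.standard_normal()) if intake_z is None else float(intake_z)
    dmi = sc.dmi_mean + sc.dmi_sd * z
    dmi = max(dmi, 1e-3)

    mp = dmi * sc.mp_per_kg_dmi * float(_lognoise(rng, 1, sc.mp_noise_cv)[0])
    aa = {name: frac * mp * float(_lognoise(rng, 1, sc.aa_noise_cv)[0])
          for name, frac in sc.aa_frac.items()}
    oaa = sc.oaa_frac * mp * float(_lognoise(rng, 1, sc.oaa_noise_cv)[0])
    de = dmi * sc.de_per_kg_dmi * float(_lognoise(rng, 1, sc.de_noise_cv)[0])
    frac = float(np.clip(rng.normal(sc.denp_frac, sc.denp_frac_sd), 0.05, 0.98))
    de_np = de * frac
    dndf = dmi * sc.dndf_per_kg_dmi * float(_lognoise(rng, 1, sc.dndf_noise_cv)[0])

    supply = SupplyProfile(scenario=scenario, dmi=dmi, mp_supply=mp,
                           his=aa["his"], ile=aa["ile"], leu=aa["leu"],
                           lys=aa["lys"], met=aa["met"], oaa=oaa,
                           de_intake=de, de_np=de_np, dndf_kg=dndf)

    bw_scale = cow.bw / config.bw_mean
    tpuri = config.tpuri_ref * bw_scale * float(_lognoise(rng, 1, config.tpuri_noise_cv)[0])
    tpfecal = config.tpfecal_per_kg_dmi * dmi * float(_lognoise(rng, 1, config.tpfecal_noise_cv)[0])
    tpscurf = config.tpscurf_ref * bw_scale * float(_lognoise(rng, 1, config.tpscurf_noise_cv)[0])
    if cow.parity == 1:
        tpgrowth = max(0.0, float(rng.normal(config.growth_primiparous_mean,
                                             config.growth_primiparous_sd)))
    else:
        tpgrowth = 0.0
    exp = ExpenditureProfile(tpuri=tpuri, tpfecal_mp=tpfecal, tpscurf_mp=tpscurf,
                             tpgrowth_mp=tpgrowth, target_eff=config.target_eff)
    return supply, exp


def simulate_observed_mpy(herd_set: SyntheticHerdSet, truth_model: str,
                          noise_sd: float, rng: np.random.Generator,
                          truth_scenario: Scenario = Scenario.DMI_Ao,
                          ) -> SyntheticHerdSet:
    """Replace each cow's observed MPY with a truth-model value times
    mean-one lognormal noise times its herd factor, truncated to the
    configured MPY bounds; the latent truth is stored on the set.

    ``external_table`` keeps the marginal observed MPY drawn with the cow
    traits (no supply linkage).
    """
    if truth_model not in TRUTH_MODELS:
        raise InvalidInputError(
            f"truth_model must be one of {TRUTH_MODELS}, got {truth_model!r}")
    config = herd_set.config or GeneratorConfig()
    if truth_model == "external_table":
        herd_set.truth_mpy = {c.cow_id: c.mpy_obs for c in herd_set.cows}
        return herd_set

    new_cows = []
    for cow in herd_set.cows:
        supply = herd_set.supplies[(cow.cow_id, truth_scenario)]
        exp = herd_set.expenditures[(cow.cow_id, truth_scenario)]
        res = prediction.predict_cow(cow.cow_id, supply, exp, cow.bw, cow.dim)
        truth = res.mpy_eff if truth_model == "eff_model" else res.mpy_multi
        herd_set.truth_mpy[cow.cow_id] = truth
        herd_set.truth_eff[cow.cow_id] = res.eff
        noise = float(_lognoise(rng, 1, noise_sd)[0])
        hf = herd_set.herd_factors.get(cow.herd_id, 1.0)
        obs = float(np.clip(truth * noise * hf, *config.mpy_bounds))
        new_cows.append(replace(cow, mpy_obs=obs))
    herd_set.cows = new_cows
    return herd_set


def generate_herd_set(config: GeneratorConfig, seed: int) -> SyntheticHerdSet:
    """Generate the complete synthetic data set: cows, both scenarios'
    supply/expenditure profiles, and observed MPY from the configured
    truth model. Bit-identical for identical config + seed."""
    rng = np.random.default_rng(seed)
    cows, herd_factors = _generate_cows_rng(config, rng)
    supplies: Dict[Tuple[str, Scenario], SupplyProfile] = {}
    expenditures: Dict[Tuple[str, Scenario], ExpenditureProfile] = {}
    intake_z = rng.standard_normal(len(cows))
    for i, cow in enumerate(cows):
        for scenario in config.scenarios:
            sup, exp = generate_supplies(cow, scenario, config, rng,
                                         intake_z=intake_z[i])
            supplies[(cow.cow_id, scenario)] = sup
            expenditures[(cow.cow_id, scenario)] = exp
    herd_set = SyntheticHerdSet(cows=cows, supplies=supplies,
                                expenditures=expenditures,
                                herd_factors=herd_factors, config=config)
    return simulate_observed_mpy(herd_set, config.truth_model, config.noise_sd,
                                 rng, truth_scenario=config.truth_scenario)
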