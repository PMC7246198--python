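"""Synthetic data with the statistical structure the analysis assumes.

Real LC-MS rearing data are not required to exercise the pipeline: this
module generates a compound matrix with block-correlation (module)
structure, plant traits, and per-caterpillar outcomes with known true
effects, so that every downstream stage (module detection, selection,
Bayesian estimation, validation) can be scored against ground truth.

The generative model is a one-factor-per-module model on the log scale:
each module m has a latent per-plant factor ``z_m ~ N(0,1)``, and a member
compound's log-abundance is ``sqrt(rho) * z_m + sqrt(1-rho) * noise``, so
every within-module pair has correlation rho and between-module pairs are
uncorrelated.  Abundances are exponentiated (log-normal) to stay
nonnegative like relative abundances; module detection operates on
z-scores so the marginal transform is immaterial to structure.

Caterpillar outcomes follow the three GLMs the analysis fits:

* survival ~ Bernoulli(invlogit(b0 + sum of module/trait effects)),
* days to eclosion ~ Poisson(exp(...)) truncated at >= 1,
* adult weight ~ Normal with sex and development-time terms,

with sex, days and weight unobserved (missing) for caterpillars that died.
Default dimensions and intercepts mirror the rearing study the pipeline
targets: 45 plants x 10 caterpillars = 450 individuals, 163 compounds,
survival intercept 0.34 log-odds, development intercept 3.48 log-days,
weight intercept 10.36 mg, sex effects 0.06 log-days and 1.12 mg, and a
days-on-weight coefficient of -1.41 mg per SD with weight noise chosen so
that days and weight correlate near -0.52.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd

from .data_model import CompoundMatrix, PlantTraits
from .families import invlogit

__all__ = ["SynthConfig", "SyntheticTruth", "generate", "empirical_module_cor"]

# 14 modules (sizes summing to 161) plus 2 free compounds = 163
DEFAULT_MODULE_SIZES = [20, 18, 16, 14, 13, 12, 11, 10, 9, 9, 8, 8, 7, 6]

# compound class codes and frequencies; saponins are the most numerous
# specialized class (>25 compounds), "Other" stays small
DEFAULT_CLASS_FREQS = {
    "SA": 0.17,
    "PL": 0.18,
    "LI": 0.20,
    "PE": 0.12,
    "PG": 0.09,
    "AL": 0.08,
    "ST": 0.08,
    "SU": 0.05,
    "OT": 0.03,
}


@dataclass
class SynthConfig:
    """Knobs of the generator; defaults reproduce the study's dimensions."""

    n_plants: int = 45
    n_caterpillars_per_plant: int = 10
    n_compounds: int = 163
    module_sizes: List[int] = field(default_factory=lambda: list(DEFAULT_MODULE_SIZES))
    within_module_cor: float = 0.6
    class_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FREQS)
    )
    # true module effects per response, keyed by 1-based module index,
    # in log-odds / log-days / mg per 1-SD latent-factor unit
    survival_effects: Dict[int, float] = field(
        default_factory=lambda: {2: 0.14, 3: -0.40, 9: -0.30, 10: 0.35, 11: 0.36, 13: -0.18}
    )
    days_effects: Dict[int, float] = field(
        default_factory=lambda: {2: -0.01, 6: -0.01, 9: 0.01, 14: 0.01}
    )
    weight_effects: Dict[int, float] = field(
        default_factory=lambda: {3: -0.44, 4: 0.29, 10: 0.40}
    )
    sla_effects: Dict[str, float] = field(
        default_factory=lambda: {"survival": -0.32, "days": 0.0, "weight": -0.35}
    )
    protein_effects: Dict[str, float] = field(
        default_factory=lambda: {"survival": 0.0, "days": 0.0, "weight": 0.0}
    )
    toughness_effects: Dict[str, float] = field(
        default_factory=lambda: {"survival": 0.0, "days": 0.0, "weight": 0.0}
    )
    survival_intercept: float = 0.34  # log-odds; invlogit -> 0.584 survival
    days_intercept: float = 3.48  # log-days; exp -> 32.5 days
    weight_intercept: float = 10.36  # mg
    sex_effect_days: float = 0.06  # log-days, females vs males
    sex_effect_weight: float = 1.12  # mg
    days_effect_weight: float = -1.41  # mg per SD of development time
    # chosen from the variance budget so that cor(days, weight) ~ -0.52:
    # 1.41 / sqrt(1.41^2 + sd^2 + plant-effect var + sex var) = 0.52
    weight_noise_sd: float = 2.15
    log_abundance_sd: float = 0.5  # per-compound sd of log abundance
    seed: Optional[int] = None

    def __post_init__(self):
        if any(s <= 0 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if sum(self.module_sizes) > self.n_compounds:
            raise ValueError("module sizes exceed number of compounds")
        if not 0.0 <= self.within_module_cor < 1.0:
            raise ValueError("within_module_cor must be in [0, 1)")

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)


@dataclass
class SyntheticTruth:
    """Everything needed to score recovery against the generator."""

    membership: pd.Series  # compound id -> true module index (0 = free)
    factors: pd.DataFrame  # plants x modules latent factors (the "true eigenvectors")
    config: SynthConfig
    linear_predictors: pd.DataFrame  # per-plant eta for survival/days/weight


def _assign_classes(rng, compound_ids, freqs):
    classes = list(freqs)
    p = np.array([freqs[c] for c in classes], dtype=float)
    p = p / p.sum()
    return pd.Series(rng.choice(classes, size=len(compound_ids), p=p), index=compound_ids)


def generate(config: SynthConfig, seed: Optional[int] = None):
    """Draw one dataset; returns (CompoundMatrix, PlantTraits, caterpillars, truth).

    ``seed`` overrides ``config.seed``; the same seed yields identical tables.
    """
    cfg = config
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)

    n, p = cfg.n_plants, cfg.n_compounds
    plant_ids = [f"P{i + 1:03d}" for i in range(n)]
    compound_ids = [f"cpd{j + 1:03d}" for j in range(p)]

    membership = np.zeros(p, dtype=int)
    pos = 0
    for m, size in enumerate(cfg.module_sizes, start=1):
        membership[pos : pos + size] = m
        pos += size

    rho = cfg.within_module_cor
    factors = rng.standard_normal((n, cfg.n_modules))
    logx = np.empty((n, p))
    for j in range(p):
        noise = rng.standard_normal(n)
        if membership[j] > 0:
            logx[:, j] = np.sqrt(rho) * factors[:, membership[j] - 1] + np.sqrt(1 - rho) * noise
        else:
            logx[:, j] = noise
    mu_log = rng.uniform(-1.0, 1.0, size=p)
    abundance = np.exp(mu_log + cfg.log_abundance_sd * logx)

    cm = CompoundMatrix(
        abundance=pd.DataFrame(abundance, index=plant_ids, columns=compound_ids),
        class_of=_assign_classes(rng, compound_ids, cfg.class_freqs),
    )

    # plant traits in plausible natural units; the standardized latent values
    # drive the outcome models
    z_sla = rng.standard_normal(n)
    z_protein = rng.standard_normal(n)
    z_tough = rng.standard_normal(n)
    traits = PlantTraits(
        table=pd.DataFrame(
            {
                "protein": np.clip(0.15 + 0.03 * z_protein, 0.01, None),
                "sla": np.exp(np.log(0.20) + 0.25 * z_sla),
                "toughness": np.clip(25.0 + 5.0 * z_tough, 1.0, None),
            },
            index=pd.Index(plant_ids, name="plant_id"),
        )
    )

    def plant_eta(intercept, mod_effects, trait_key):
        eta = np.full(n, intercept)
        for m, b in mod_effects.items():
            if not 1 <= m <= cfg.n_modules:
                raise ValueError(f"effect refers to unknown module {m}")
            eta += b * factors[:, m - 1]
        eta += cfg.sla_effects[trait_key] * z_sla
        eta += cfg.protein_effects[trait_key] * z_protein
        eta += cfg.toughness_effects[trait_key] * z_tough
        return eta

    eta_surv = plant_eta(cfg.survival_intercept, cfg.survival_effects, "survival")
    eta_days = plant_eta(cfg.days_intercept, cfg.days_effects, "days")
    eta_weight = plant_eta(cfg.weight_intercept, cfg.weight_effects, "weight")

    # unclipped logistic so a degenerate config is caught exactly
    from scipy.special import expit

    p_surv = expit(eta_surv)
    if np.any(p_surv <= 0.0) or np.any(p_surv >= 1.0):
        raise ValueError("config implies survival probability of exactly 0 or 1")

    k = cfg.n_caterpillars_per_plant
    rows = []
    for i, pid in enumerate(plant_ids):
        for _ in range(k):
            survived = int(rng.random() < p_surv[i])
            if not survived:
                rows.append((pid, 0, np.nan, np.nan, np.nan))
                continue
            sex = int(rng.random() < 0.5)
            lam = np.exp(eta_days[i] + cfg.sex_effect_days * sex)
            days = 0
            while days < 1:  # eclosion cannot take zero days
                days = rng.poisson(lam)
            rows.append((pid, 1, sex, days, np.nan))
    cats = pd.DataFrame(
        rows, columns=["plant_id", "survived", "sex", "dev_days", "adult_weight_mg"]
    )

    alive = cats["survived"] == 1
    if alive.sum() >= 2:
        days_al = cats.loc[alive, "dev_days"].to_numpy(dtype=float)
        sd = days_al.std(ddof=1)
        z_days = (days_al - days_al.mean()) / sd if sd > 0 else np.zeros_like(days_al)
        idx = {pid: i for i, pid in enumerate(plant_ids)}
        plant_rows = cats.loc[alive, "plant_id"].map(idx).to_numpy()
        w = (
            eta_weight[plant_rows]
            + cfg.sex_effect_weight * cats.loc[alive, "sex"].to_numpy(dtype=float)
            + cfg.days_effect_weight * z_days
            + cfg.weight_noise_sd * rng.standard_normal(alive.sum())
        )
        cats.loc[alive, "adult_weight_mg"] = np.round(np.clip(w, 0.01, None), 2)

    truth = SyntheticTruth(
        membership=pd.Series(membership, index=compound_ids, name="module"),
        factors=pd.DataFrame(
            factors,
            index=plant_ids,
            columns=[f"m{m}" for m in range(1, cfg.n_modules + 1)],
        ),
        config=cfg,
        linear_predictors=pd.DataFrame(
            {"survival": eta_surv, "days": eta_days, "weight": eta_weight},
            index=plant_ids,
        ),
    )
    return cm, traits, cats, truth


def empirical_module_cor(cm: CompoundMatrix, truth: SyntheticTruth) -> pd.Series:
    """Mean off-diagonal Pearson correlation within each true module.

    A generator self-check: with within-module correlation rho, the values
    concentrate around rho as the number of plants grows.  Single-compound
    modules have no pairwise correlations and are excluded.
    """
    out = {}
    for m in sorted(set(truth.membership) - {0}):
        members = truth.membership.index[truth.membership == m]
        if len(members) < 2:
            continue
        r = np.corrcoef(cm.abundance[members].to_numpy(), rowvar=False)
        iu = np.triu_indices(len(members), k=1)
        out[m] = float(r[iu].mean())
    return pd.Series(out, name="mean_within_module_cor")
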