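"""Model validation: plant-level leave-one-out prediction and resampling nulls.

Three complementary checks of the reduced (module-based) models:

* ``loo_validate`` — refit the model 45 times, each time leaving out one
  plant and all its caterpillars, predict the held-out caterpillars, and
  correlate observed with predicted performance across plants.  The
  squared correlation is the percent of among-plant variation explained.
* ``random_module_null`` — do randomly assembled "modules" (random
  compound sets matched in size to the model's real modules) predict as
  well?  The exceedance fraction is the share of resamples whose variance
  explained beats the empirical model's.
* ``cv_effect_association`` — are compound effects predicted by how much
  a compound varies among plants (coefficient of variation on the raw
  abundances)?
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import McmcSettings, fit_bayes_glm, summarize_posterior
from .data_model import RESPONSES, CompoundMatrix, DesignMatrix, build_design, z_transform
from .families import get_family, irls_ridge
from .network import module_eigenvector

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "ValidationResult",
    "NullDistribution",
    "loo_validate",
    "variance_explained",
    "random_module_null",
    "cv_effect_association",
]


@dataclass
class ModelSpec:
    """A reduced model: which plant-level predictors enter which response."""

    response: str  # survival | days | weight
    predictors: List[str]  # columns of the plant-predictor table

    def __post_init__(self):
        if self.response not in RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")

    @property
    def family(self) -> str:
        return RESPONSES[self.response]["family"]


@dataclass
class ValidationResult:
    per_plant: pd.DataFrame  # observed, predicted, n per plant
    r: float
    skipped_plants: list = field(default_factory=list)

    @property
    def r2_percent(self) -> float:
        """Percent of among-plant variation explained (100 * r^2)."""
        return float(100.0 * self.r**2)


@dataclass
class NullDistribution:
    empirical: float
    resampled: np.ndarray
    statistic: str

    @property
    def n_resamples(self) -> int:
        return len(self.resampled)

    @property
    def exceedance_fraction(self) -> float:
        """Share of resamples strictly exceeding the empirical statistic.

        Ties count as not exceeding; a small absolute tolerance absorbs
        floating-point jitter so that a resample recomputing the identical
        model never registers as "exceeding".
        """
        return float(np.mean(self.resampled > self.empirical + 1e-10))


def _point_fit(X_df: pd.DataFrame, y: np.ndarray, family: str, method: str, mcmc):
    """Point coefficients: ML (IRLS) or Bayesian posterior means."""
    if method == "ml":
        return irls_ridge(X_df.to_numpy(dtype=float), y, family, lam=0.0)
    if method == "bayes":
        from types import SimpleNamespace

        view = SimpleNamespace(X=X_df, y=np.asarray(y, dtype=float), family=family)
        chains = fit_bayes_glm(view, mcmc or McmcSettings(n_iter=2000, adapt_steps=500))
        summ = summarize_posterior(chains)
        b0 = float(summ.loc["intercept", "mean"])
        beta = summ.loc[list(X_df.columns), "mean"].to_numpy()
        return b0, beta
    raise ValueError("method must be 'ml' or 'bayes'")


def loo_validate(
    spec: ModelSpec,
    plant_predictors: pd.DataFrame,
    caterpillars: pd.DataFrame,
    method: str = "ml",
    mcmc: Optional[McmcSettings] = None,
) -> ValidationResult:
    """Leave-one-plant-out predictive correlation for one response.

    For each plant, the model is refit on the other plants and the held-out
    caterpillars are predicted from the point coefficients (posterior means
    with ``method='bayes'``, maximum likelihood with the default ``'ml'``;
    the two agree closely under the flat-ish priors used here).  Observed
    vs predicted values are compared as per-plant means: survival as the
    plant's observed survival proportion vs predicted probability, days and
    weight as survivor means with the observed sex/covariate values
    supplied.  Plants with no survivors are skipped (and logged) for the
    days/weight models.
    """
    design = build_design(spec.response, plant_predictors, caterpillars, spec.predictors)
    fam = get_family(design.family)
    X = design.X.to_numpy(dtype=float)
    y = design.y
    groups = np.asarray(design.groups)
    plants = list(pd.unique(groups))
    if len(plants) < 3:
        raise ValueError("leave-one-plant-out validation needs >= 3 plants")
    rows = []
    skipped = []
    for pid in pd.unique(caterpillars["plant_id"]):
        test = groups == pid
        if test.sum() == 0:
            skipped.append(pid)
            logger.info("plant %s has no rows for response %s; skipped", pid, spec.response)
            continue
        train = ~test
        b0, beta = _point_fit(design.X.iloc[train], y[train], design.family, method, mcmc)
        mu = fam.linkinv(b0 + X[test] @ beta)
        rows.append((pid, float(np.mean(y[test])), float(np.mean(mu)), int(test.sum())))
    per_plant = pd.DataFrame(rows, columns=["plant_id", "observed", "predicted", "n"])
    if per_plant["observed"].std() == 0 or per_plant["predicted"].std() == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(per_plant["observed"], per_plant["predicted"])[0, 1])
    return ValidationResult(per_plant=per_plant, r=r, skipped_plants=skipped)


def variance_explained(design: DesignMatrix) -> float:
    """In-sample variance explained by the ML fit.

    R-squared for Gaussian responses; McFadden's pseudo-R-squared
    (1 - deviance/null deviance) for binomial and Poisson.
    """
    fam = get_family(design.family)
    X = design.X.to_numpy(dtype=float)
    y = design.y
    b0, beta = irls_ridge(X, y, fam, lam=0.0)
    mu = fam.linkinv(b0 + X @ beta)
    b0n, _ = irls_ridge(np.zeros((len(y), 0)), y, fam, lam=0.0)
    mu0 = fam.linkinv(np.full(len(y), b0n))
    d0 = fam.deviance(y, mu0)
    if d0 == 0:
        return 0.0
    return float(1.0 - fam.deviance(y, mu) / d0)


def random_module_null(
    cm: CompoundMatrix,
    module_sizes: Sequence[int],
    spec: ModelSpec,
    caterpillars: pd.DataFrame,
    trait_predictors: Optional[pd.DataFrame] = None,
    real_module_cols: Optional[Sequence[str]] = None,
    n_resamples: int = 1000,
    seed: Optional[int] = None,
    disjoint: bool = True,
) -> NullDistribution:
    """Resampling null matched to the reduced model's structure.

    If the fitted model contains modules of, say, 15 and 20 compounds, each
    resample draws random compound sets of sizes 15 and 20 (disjoint within
    a resample by default), computes their eigenvectors, refits the model
    (fast ML refit) with the same trait covariates, and records its
    variance explained.  The returned exceedance fraction is the share of
    random models beating the empirical one.
    """
    sizes = list(module_sizes)
    if any(s < 1 for s in sizes):
        raise ValueError("module sizes must be positive")
    if disjoint and sum(sizes) > cm.n_compounds:
        raise ValueError("module sizes sum beyond the number of compounds")
    z = cm.zscores()
    traits = trait_predictors if trait_predictors is not None else pd.DataFrame(index=z.index)
    if real_module_cols is None:
        # eigenvector columns follow the "m<index>" naming convention
        real_module_cols = [
            c for c in spec.predictors if re.fullmatch(r"m\d+", str(c))
        ]
    trait_cols = [c for c in spec.predictors if c not in real_module_cols]
    if len(real_module_cols) != len(sizes):
        raise ValueError("one size per module predictor is required")

    def stat_for(predictor_tbl, cols):
        design = build_design(spec.response, predictor_tbl, caterpillars, cols)
        return variance_explained(design)

    # empirical statistic uses the caller-supplied real eigenvectors
    if trait_predictors is not None and set(spec.predictors) <= set(traits.columns):
        empirical = stat_for(traits, spec.predictors)
    else:
        raise ValueError(
            "trait_predictors must contain every model predictor "
            "(real eigenvectors and traits) to compute the empirical statistic"
        )

    rng = np.random.default_rng(seed)
    compounds = np.array(cm.compound_ids)
    stats_out = np.empty(n_resamples)
    for b in range(n_resamples):
        if disjoint:
            perm = rng.permutation(len(compounds))
            pos = 0
            draws = []
            for s in sizes:
                draws.append(compounds[perm[pos : pos + s]])
                pos += s
        else:
            draws = [rng.choice(compounds, size=s, replace=False) for s in sizes]
        tbl = traits[trait_cols].copy()
        cols = []
        for i, members in enumerate(draws):
            name = f"rand{i + 1}"
            tbl[name] = module_eigenvector(z[list(members)])
            cols.append(name)
        stats_out[b] = stat_for(tbl, cols + trait_cols)
    fam = get_family(spec.family)
    statname = "r_squared" if fam.name == "gaussian" else "mcfadden_r_squared"
    return NullDistribution(empirical=float(empirical), resampled=stats_out, statistic=statname)


def cv_effect_association(
    cm: CompoundMatrix, effects: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate per-compound coefficient of variation with effect size.

    The CV (sd/mean, sample sd) is computed on the raw, untransformed
    abundances.  For each response column of ``effects`` (raw ridge
    coefficients per compound) the Pearson and Spearman correlations with
    |effect| are reported.  Compounds with zero mean abundance have an
    undefined CV and are excluded (and logged).
    """
    ab = cm.abundance
    mean = ab.mean(axis=0)
    sd = ab.std(axis=0, ddof=1)
    ok = mean != 0
    dropped = list(mean.index[~ok])
    if dropped:
        logger.info("excluding %d compounds with zero mean abundance", len(dropped))
    cv = (sd[ok] / mean[ok]).rename("cv")
    table = pd.DataFrame({"cv": cv})
    rows = []
    for resp in effects.columns:
        eff = effects[resp].reindex(cv.index).abs()
        table[f"abs_effect_{resp}"] = eff
        pear = float(np.corrcoef(cv, eff)[0, 1]) if eff.std() > 0 else 0.0
        spear = float(stats.spearmanr(cv, eff).statistic) if eff.std() > 0 else 0.0
        rows.append((resp, pear, spear, len(cv)))
    summary = pd.DataFrame(rows, columns=["response", "pearson", "spearman", "n_compounds"])
    return summary, table
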