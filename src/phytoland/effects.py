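"""Back-transformations and summaries that make coefficients interpretable.

Coefficients live on link scales: log-odds (survival), log-days
(development time), mg (weight, identity link).  For display they are
back-transformed to *deltas on the natural scale relative to the
intercept*: e.g. a survival coefficient b becomes
``invlogit(b0 + b) - invlogit(b0)``, the change in survival probability
associated with a one-SD change in the (z-scored) predictor while other
predictors sit at their means.  Weight effects are already in mg.

Class-level summaries (median, interquartile box, Tukey fences) describe
how effects distribute within chemical classes (saponins, alkaloids,
phenolic glycosides, ...), ordered by their median effect on survival.
The permutation test for class enrichment among surviving interactions
formalizes an otherwise descriptive comparison and is labeled as such in
its output.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
import pandas as pd

from .families import invlogit

__all__ = [
    "back_transform_survival",
    "back_transform_days",
    "back_transform",
    "summarize_by_class",
    "top_effects",
    "interaction_class_enrichment",
]


def back_transform_survival(intercept: float, coefficient) -> float | np.ndarray:
    """Delta survival probability: invlogit(b0 + b) - invlogit(b0)."""
    return invlogit(intercept + np.asarray(coefficient, dtype=float)) - invlogit(intercept)


def back_transform_days(intercept: float, coefficient) -> float | np.ndarray:
    """Delta days to eclosion: exp(b0 + b) - exp(b0); negative = faster."""
    b = np.asarray(coefficient, dtype=float)
    return np.exp(intercept + b) - np.exp(intercept)


def back_transform(response: str, intercept: float, coefficient):
    """Dispatch by response; weight (identity link) passes through in mg."""
    if response == "survival":
        return back_transform_survival(intercept, coefficient)
    if response == "days":
        return back_transform_days(intercept, coefficient)
    if response == "weight":
        return np.asarray(coefficient, dtype=float)
    raise ValueError(f"unknown response {response!r}")


def effects_table(
    coefs: pd.Series, response: str, intercept: float, flags: Optional[pd.Series] = None
) -> pd.DataFrame:
    """Raw coefficients + natural-scale deltas + bootstrap flags, one table."""
    delta = back_transform(response, intercept, coefs.to_numpy())
    out = pd.DataFrame({"coefficient": coefs, "delta": delta})
    out["excludes_zero"] = (
        flags.reindex(coefs.index).fillna(False) if flags is not None else False
    )
    out.index.name = "compound_id"
    return out


def summarize_by_class(
    deltas: pd.DataFrame, class_of: pd.Series, sort_response: str = "survival"
) -> pd.DataFrame:
    """Per-class medians, quartile boxes and Tukey fences for each response.

    ``deltas`` has one row per compound and one column per response
    (natural-scale deltas).  Classes are ordered by descending median
    effect on ``sort_response``.  Quantiles use linear interpolation;
    fences are Q3 + 1.5*IQR and Q1 - 1.5*IQR.  Empty classes are omitted.
    """
    missing = deltas.index.difference(class_of.index)
    if len(missing):
        raise ValueError(f"compounds without class label: {list(missing[:5])}")
    rows = []
    for cls, members in deltas.groupby(class_of.reindex(deltas.index)):
        if len(members) == 0:
            continue
        row = {"class": cls, "n": len(members)}
        for resp in deltas.columns:
            v = members[resp].to_numpy()
            q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
            iqr = q3 - q1
            row.update(
                {
                    f"{resp}_median": med,
                    f"{resp}_q1": q1,
                    f"{resp}_q3": q3,
                    f"{resp}_fence_low": q1 - 1.5 * iqr,
                    f"{resp}_fence_high": q3 + 1.5 * iqr,
                }
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(f"{sort_response}_median", ascending=False).reset_index(drop=True)


def top_effects(effects: pd.DataFrame, k: int = 15) -> pd.DataFrame:
    """The k largest natural-scale effects among bootstrap-supported compounds.

    Only compounds whose bootstrap interval excludes zero are eligible;
    within those, rank by |delta| descending, ties broken by compound id.
    Fewer than k eligible compounds returns all of them.
    """
    flagged = effects[effects["excludes_zero"].astype(bool)]
    order = sorted(flagged.index, key=lambda c: (-abs(flagged.at[c, "delta"]), str(c)))
    return flagged.loc[order[:k]]


def interaction_class_enrichment(
    interactions: pd.DataFrame,
    class_of: pd.Series,
    n_permutations: int = 10_000,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Permutation test for class over/under-representation in interactions.

    Observed statistic per class: the number of participations in the
    surviving interaction terms (each interaction contributes both of its
    compounds).  The null permutes class labels over compounds, holding
    the interaction pairs fixed.  Reports the enrichment ratio
    (observed / mean permuted) and a two-sided permutation p-value with
    add-one correction.  This formal test is an extension on top of the
    descriptive class comparison and the output says so.
    """
    if len(interactions) == 0:
        raise ValueError("no surviving interactions to test")
    rng = np.random.default_rng(seed)
    pairs = interactions[["compound_a", "compound_b"]].to_numpy()
    compounds = np.asarray(class_of.index)
    labels = class_of.to_numpy()
    idx = {c: i for i, c in enumerate(compounds)}
    part = np.array([[idx[a], idx[b]] for a, b in pairs])
    classes = sorted(pd.unique(labels))

    def counts(lab):
        c = pd.Series(lab[part.reshape(-1)]).value_counts()
        return np.array([c.get(cl, 0) for cl in classes], dtype=float)

    obs = counts(labels)
    perm = np.empty((n_permutations, len(classes)))
    for b in range(n_permutations):
        perm[b] = counts(labels[rng.permutation(len(labels))])
    mean_perm = perm.mean(axis=0)
    ge = (perm >= obs).mean(axis=0)
    le = (perm <= obs).mean(axis=0)
    # add-one two-sided permutation p
    p = np.minimum(1.0, 2.0 * np.minimum(
        ((perm >= obs).sum(axis=0) + 1) / (n_permutations + 1),
        ((perm <= obs).sum(axis=0) + 1) / (n_permutations + 1),
    ))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean_perm > 0, obs / mean_perm, np.nan)
    out = pd.DataFrame(
        {
            "class": classes,
            "observed": obs.astype(int),
            "expected": mean_perm,
            "enrichment_ratio": ratio,
            "p_two_sided": p,
            "frac_perm_ge": ge,
            "frac_perm_le": le,
        }
    )
    out.attrs["note"] = (
        "permutation enrichment test added by this package; the underlying "
        "class comparison is descriptive"
    )
    return out
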