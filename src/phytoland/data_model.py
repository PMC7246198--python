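"""Domain types, table IO, standardization, and simple leaf-trait derivations.

The core container is :class:`CompoundMatrix`: a plants-by-compounds table of
LC-MS feature abundances ("relative abundance per dry weight": peak area
normalized to an internal standard and to sample dry mass), with a class
label (saponin, alkaloid, phenolic glycoside, ...) for every compound.
Plant-level covariates live in :class:`PlantTraits`; each individually
reared caterpillar is one row of a caterpillar table.

Readers are strict: unknown plant ids, duplicate ids, missing columns and
non-numeric abundance cells are typed errors, never silent imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompoundMatrix",
    "PlantTraits",
    "DesignMatrix",
    "TableLoadError",
    "ZeroVarianceError",
    "load_tables",
    "write_tables",
    "z_transform",
    "compute_sla",
    "average_toughness",
    "CATERPILLAR_COLUMNS",
]

CATERPILLAR_COLUMNS = ["plant_id", "survived", "sex", "dev_days", "adult_weight_mg"]


class TableLoadError(ValueError):
    """Raised when an input table violates the data contract.

    The message names the offending file/row/column so a user can fix
    the input rather than chase a downstream numerical error.
    """


class ZeroVarianceError(ValueError):
    """Raised when a column that must be standardized has zero variance."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(
            "cannot z-transform constant column(s): " + ", ".join(map(str, self.columns))
        )


@dataclass
class CompoundMatrix:
    """Plants x compounds abundance table with compound class annotations."""

    abundance: pd.DataFrame  # index = plant ids, columns = compound ids
    class_of: pd.Series  # compound id -> class code (SA, AL, PG, ...)

    def __post_init__(self):
        ab = self.abundance
        if ab.index.has_duplicates:
            raise TableLoadError("duplicate plant ids in abundance table")
        if ab.columns.has_duplicates:
            raise TableLoadError("duplicate compound ids in abundance table")
        vals = ab.to_numpy()
        if not np.issubdtype(vals.dtype, np.number) or not np.all(np.isfinite(vals)):
            bad = ab.columns[~np.all(np.isfinite(ab.to_numpy(dtype=float, na_value=np.nan)), axis=0)]
            raise TableLoadError(
                f"non-finite abundance values in compound(s): {list(bad[:5])}"
            )
        if np.any(vals < 0):
            raise TableLoadError("abundance values must be nonnegative")
        self.class_of = pd.Series(self.class_of)
        missing = ab.columns.difference(self.class_of.index)
        if len(missing):
            raise TableLoadError(f"compounds without class label: {list(missing[:5])}")
        self.class_of = self.class_of.reindex(ab.columns)
        ab.index.name = "plant_id"
        self.class_of.index = pd.Index(ab.columns.to_list(), name="compound_id")
        ab.columns.name = None

    @property
    def plant_ids(self) -> list:
        return list(self.abundance.index)

    @property
    def compound_ids(self) -> list:
        return list(self.abundance.columns)

    @property
    def n_plants(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_compounds(self) -> int:
        return self.abundance.shape[1]

    def zscores(self) -> pd.DataFrame:
        """Column-standardized abundances (mean 0, sample sd 1)."""
        return z_transform(self.abundance)


@dataclass
class PlantTraits:
    """Per-plant leaf traits: protein content, SLA (cm^2/mg), toughness (g/N)."""

    table: pd.DataFrame  # index = plant ids; columns protein, sla, toughness

    def __post_init__(self):
        t = self.table
        if t.index.has_duplicates:
            raise TableLoadError("duplicate plant ids in trait table")
        for col in ("protein", "sla", "toughness"):
            if col not in t.columns:
                raise TableLoadError(f"trait table missing column {col!r}")
        if np.any(t["sla"].to_numpy() <= 0):
            raise TableLoadError("sla must be positive")
        if np.any(t["toughness"].to_numpy() <= 0):
            raise TableLoadError("toughness must be positive")
        t.index.name = "plant_id"


@dataclass
class DesignMatrix:
    """A ready-to-fit model frame.

    ``X`` holds z-scored predictors (plus any factor columns listed in
    ``unscaled``, e.g. the 0/1 sex dummy, which are left in natural units);
    rows align with ``y``.  ``groups`` maps rows to plant ids so folds and
    bootstrap resampling can respect the plant level.
    """

    X: pd.DataFrame
    y: np.ndarray
    family: str
    groups: np.ndarray  # plant id per row
    unscaled: tuple = ()

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if len(self.X) != len(self.y):
            raise ValueError("X and y have different numbers of rows")
        scaled = [c for c in self.X.columns if c not in self.unscaled]
        if scaled:
            sub = self.X[scaled].to_numpy(dtype=float)
            if sub.shape[0] > 1:
                mu = sub.mean(axis=0)
                sd = sub.std(axis=0, ddof=1)
                if np.any(np.abs(mu) > 1e-8) or np.any(np.abs(sd - 1) > 1e-8):
                    raise ValueError("scaled predictor columns must be z-scored")

    @property
    def column_names(self) -> list:
        return list(self.X.columns)


def z_transform(matrix: pd.DataFrame | np.ndarray):
    """Standardize each column to mean 0 and sample sd 1 (denominator n-1).

    Idempotent within floating-point noise.  Constant columns are an error
    (they carry no among-plant information and would divide by zero).
    """
    is_df = isinstance(matrix, pd.DataFrame)
    vals = matrix.to_numpy(dtype=float) if is_df else np.asarray(matrix, dtype=float)
    if vals.ndim == 1:
        vals = vals[:, None]
    sd = vals.std(axis=0, ddof=1)
    if np.any(sd == 0) or np.any(~np.isfinite(sd)):
        bad_idx = np.where((sd == 0) | ~np.isfinite(sd))[0]
        names = (
            [matrix.columns[i] for i in bad_idx] if is_df else [str(i) for i in bad_idx]
        )
        raise ZeroVarianceError(names)
    out = (vals - vals.mean(axis=0)) / sd
    if is_df:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out if np.asarray(matrix).ndim > 1 else out[:, 0]


def compute_sla(leaf_area_cm2: float, dry_mass_mg: float) -> float:
    """Specific leaf area: leaf area divided by dry mass (cm^2/mg)."""
    if leaf_area_cm2 <= 0 or dry_mass_mg <= 0:
        raise ValueError("leaf area and dry mass must be positive")
    return leaf_area_cm2 / dry_mass_mg


def average_toughness(readings: Sequence[float]) -> float:
    """Mean of the per-plant penetrometer readings (three leaves per plant)."""
    readings = [float(r) for r in readings]
    if not readings or not all(np.isfinite(readings)):
        raise ValueError("toughness requires at least one finite reading")
    return float(np.mean(readings))


# ---------------------------------------------------------------------------
# design-matrix construction

# family and covariate set per response; sex is a 0/1 factor left in natural
# units, while the reciprocal dev-days/adult-weight covariates are z-scored
# like the other predictors.  Survival models carry no individual covariates
# because sex, days and weight are unobservable on dead caterpillars.
RESPONSES = {
    "survival": {"family": "binomial", "column": "survived", "covariates": ()},
    "days": {
        "family": "poisson",
        "column": "dev_days",
        "covariates": ("sex", "adult_weight_mg"),
    },
    "weight": {
        "family": "gaussian",
        "column": "adult_weight_mg",
        "covariates": ("sex", "dev_days"),
    },
}


def build_design(
    response: str,
    plant_predictors: pd.DataFrame,
    caterpillars: pd.DataFrame,
    predictor_cols: Sequence[str] | None = None,
) -> DesignMatrix:
    """Assemble the model frame for one caterpillar response.

    ``plant_predictors`` holds plant-level predictors (module eigenvectors
    and/or leaf traits, one row per plant).  Rows are caterpillars for the
    survival model and survivors only for the days/weight models.  All
    predictors are z-scored on the analysis sample actually used, except
    the sex dummy which stays 0/1.
    """
    if response not in RESPONSES:
        raise ValueError(f"unknown response {response!r}; expected {sorted(RESPONSES)}")
    info = RESPONSES[response]
    cats = caterpillars
    if response != "survival":
        cats = cats[cats["survived"] == 1]
    if predictor_cols is None:
        predictor_cols = list(plant_predictors.columns)
    missing = set(cats["plant_id"]) - set(plant_predictors.index)
    if missing:
        raise TableLoadError(f"caterpillar rows cite unknown plants: {sorted(missing)[:5]}")
    X = plant_predictors.loc[cats["plant_id"], list(predictor_cols)].reset_index(drop=True)
    unscaled = []
    for cov in info["covariates"]:
        if cov == "sex":
            X["sex"] = cats["sex"].to_numpy(dtype=float)
            unscaled.append("sex")
        else:
            X[cov] = cats[cov].to_numpy(dtype=float)
    y = cats[info["column"]].to_numpy(dtype=float)
    scaled_cols = [c for c in X.columns if c not in unscaled]
    X[scaled_cols] = z_transform(X[scaled_cols])
    return DesignMatrix(
        X=X,
        y=y,
        family=info["family"],
        groups=cats["plant_id"].to_numpy(),
        unscaled=tuple(unscaled),
    )


# ---------------------------------------------------------------------------
# table IO


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep)


def _require_columns(df: pd.DataFrame, cols, where: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TableLoadError(f"{where}: missing column(s) {missing}")


def load_tables(
    compounds_path,
    traits_path,
    caterpillars_path,
    classes_path=None,
    *,
    plant_col: str = "plant_id",
):
    """Read and cross-validate the three input tables (+ class annotations).

    The compound table is wide (one row per plant, one column per compound).
    Class annotations may come from a separate two-column table
    (``compound_id,class``); otherwise every compound is labeled ``OT``.

    Returns ``(CompoundMatrix, PlantTraits, caterpillar DataFrame)``.
    """
    comp = _read_table(compounds_path)
    _require_columns(comp, [plant_col], "compound table")
    if comp[plant_col].duplicated().any():
        dupes = comp[plant_col][comp[plant_col].duplicated()].tolist()
        raise TableLoadError(f"compound table: duplicate plant id(s) {dupes[:5]}")
    comp = comp.set_index(plant_col)
    for col in comp.columns:
        coerced = pd.to_numeric(comp[col], errors="coerce")
        bad = coerced.isna() & ~comp[col].isna()
        if bad.any() or comp[col].isna().any():
            row = comp.index[coerced.isna() | comp[col].isna()][0]
            raise TableLoadError(
                f"compound table: non-numeric or missing abundance at "
                f"plant {row!r}, compound {col!r}"
            )
        comp[col] = coerced

    if classes_path is not None:
        cls = _read_table(classes_path)
        _require_columns(cls, ["compound_id", "class"], "class table")
        class_of = cls.set_index("compound_id")["class"]
    else:
        class_of = pd.Series("OT", index=comp.columns)
    cm = CompoundMatrix(abundance=comp, class_of=class_of)

    traits = _read_table(traits_path)
    _require_columns(traits, [plant_col, "protein", "sla", "toughness"], "trait table")
    traits = traits.set_index(plant_col)
    pt = PlantTraits(table=traits)
    extra = set(traits.index).symmetric_difference(comp.index)
    if extra:
        raise TableLoadError(
            f"trait and compound tables disagree on plant ids: {sorted(extra)[:5]}"
        )

    cats = _read_table(caterpillars_path)
    _require_columns(cats, CATERPILLAR_COLUMNS, "caterpillar table")
    unknown = set(cats["plant_id"]) - set(comp.index)
    if unknown:
        raise TableLoadError(
            f"caterpillar table: unknown plant id(s) {sorted(unknown)[:5]}"
        )
    if not cats["survived"].isin([0, 1]).all():
        raise TableLoadError("caterpillar table: survived must be 0/1")
    dead = cats["survived"] == 0
    for col in ("sex", "dev_days", "adult_weight_mg"):
        if cats.loc[dead, col].notna().any():
            raise TableLoadError(
                f"caterpillar table: dead individuals must have missing {col}"
            )
        if cats.loc[~dead, col].isna().any():
            raise TableLoadError(
                f"caterpillar table: surviving individuals must have {col}"
            )
    alive = cats.loc[~dead]
    if len(alive) and (alive["dev_days"] < 1).any():
        raise TableLoadError("caterpillar table: dev_days must be >= 1")
    return cm, pt, cats


def write_tables(outdir, cm: CompoundMatrix, traits: PlantTraits, cats: pd.DataFrame):
    """Write the three tables (+ class annotations) as CSV; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "compounds": outdir / "compounds.csv",
        "traits": outdir / "traits.csv",
        "caterpillars": outdir / "caterpillars.csv",
        "classes": outdir / "compound_classes.csv",
    }
    cm.abundance.rename_axis("plant_id").to_csv(paths["compounds"])
    traits.table.rename_axis("plant_id").to_csv(paths["traits"])
    cats.to_csv(paths["caterpillars"], index=False)
    cm.class_of.rename_axis("compound_id").rename("class").to_csv(paths["classes"])
    return paths
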