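import numpy as np
import pandas as pd
import pytest

import phytoland as pl


@pytest.fixture(scope="session")
def block_config():
    """Well-separated module structure (high within-module correlation,
    all module sizes >= 8) for recovery tests."""
    return pl.SynthConfig(
        n_plants=45,
        n_caterpillars_per_plant=10,
        n_compounds=93,
        module_sizes=[16, 14, 12, 12, 10, 10, 9, 8],
        within_module_cor=0.85,
        survival_effects={1: -0.8, 2: 0.6},
        days_effects={1: 0.05},
        weight_effects={2: 0.8},
    )


@pytest.fixture(scope="session")
def default_dataset():
    cfg = pl.SynthConfig()
    return pl.generate(cfg, seed=202)


@pytest.fixture()
def toy_tables(tmp_path):
    """Three tiny, hand-written input tables on disk."""
    (tmp_path / "compounds.csv").write_text(
        "plant_id,c1,c2,c3\nA,1.0,2.0,3.0\nB,2.0,1.5,0.5\nC,0.5,3.0,1.0\n"
    )
    (tmp_path / "traits.csv").write_text(
        "plant_id,protein,sla,toughness\nA,0.1,0.2,20\nB,0.15,0.25,25\nC,0.12,0.22,22\n"
    )
    (tmp_path / "cats.csv").write_text(
        "plant_id,survived,sex,dev_days,adult_weight_mg\n"
        "A,1,0,30,10.5\nA,0,,,\nB,1,1,28,12.0\nC,1,0,35,9.0\nC,0,,,\n"
    )
    (tmp_path / "classes.csv").write_text(
        "compound_id,class\nc1,SA\nc2,AL\nc3,PG\n"
    )
    return tmp_path


def make_null_compound_matrix(seed, n_plants=45, n_compounds=163):
    """Independent (structureless) compounds with log-normal marginals."""
    rng = np.random.default_rng(seed)
    ab = pd.DataFrame(
        np.exp(rng.standard_normal((n_plants, n_compounds))),
        index=[f"P{i:03d}" for i in range(n_plants)],
        columns=[f"c{j:03d}" for j in range(n_compounds)],
    )
    return pl.CompoundMatrix(ab, pd.Series("OT", index=ab.columns))
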