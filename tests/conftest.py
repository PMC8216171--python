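import numpy as np
import pandas as pd
import pytest

from heliquant import synthetic_data as sd
from heliquant.pedigree import additive_relationship_matrix


def make_random_pedigree(rng: np.random.Generator) -> pd.DataFrame:
    """Random two/three-generation pedigree with founders, full sibs,
    half sibs and occasional grandparent links; always acyclic."""
    n_dams = int(rng.integers(2, 5))
    n_sires = int(rng.integers(1, 4))
    rows = []
    for i in range(n_dams):
        rows.append(dict(id=f"d{i}", dam=None, sire=None, sex="F"))
    for i in range(n_sires):
        rows.append(dict(id=f"s{i}", dam=None, sire=None, sex="M"))
    kids = []
    for k in range(int(rng.integers(3, 12))):
        d = f"d{rng.integers(n_dams)}"
        s = f"s{rng.integers(n_sires)}"
        sex = "F" if rng.random() < 0.5 else "M"
        rows.append(dict(id=f"k{k}", dam=d, sire=s, sex=sex))
        kids.append((f"k{k}", sex))
    # a second generation from offspring pairs where sexes allow
    fem = [i for i, x in kids if x == "F"]
    mal = [i for i, x in kids if x == "M"]
    for g in range(int(rng.integers(0, 5))):
        if not fem or not mal:
            break
        rows.append(
            dict(
                id=f"g{g}",
                dam=fem[int(rng.integers(len(fem)))],
                sire=mal[int(rng.integers(len(mal)))],
                sex="F" if rng.random() < 0.5 else "M",
            )
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def study_config():
    """Default configuration mirroring the common-garden breeding design."""
    return sd.SimulationConfig()


@pytest.fixture(scope="session")
def study_tables(study_config):
    """(pedigree, phenotypes, A) for the study-default simulation."""
    ped = sd.make_pedigree(study_config)
    phe = sd.simulate_breeding_phenotypes(ped, study_config)
    A = additive_relationship_matrix(ped)
    return ped, phe, A
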