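import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import growthmap as gm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_map():
    """Six chromosomes, 20 markers each, 50 cM per chromosome."""
    return gm.simulate_genetic_map(
        n_chromosomes=6, markers_per_chromosome=20,
        chrom_length_bp=20_000_000, cM_per_Mb=2.5, seed=11,
    )


@pytest.fixture(scope="session")
def panel(small_map):
    """200-strain RIAIL panel on the small map."""
    return gm.simulate_riail_genotypes(small_map, 200, expansion=3.0, seed=12)


@pytest.fixture(scope="session")
def planted_trait(panel):
    """Trait with one 8.6%-variance QTL planted mid-chromosome X."""
    marker = "X_010"
    a = gm.effect_for_variance_fraction(0.086)
    sim = gm.simulate_trait(panel, [gm.QtlSpec(marker, a)], seed=13,
                            trait_name="length")
    return marker, sim


@pytest.fixture()
def hand_profile():
    """LOD profile on one chromosome, values chosen for drop-interval checks."""
    table = pd.DataFrame(
        {
            "marker": [f"m{i}" for i in range(1, 7)],
            "chrom": ["I"] * 6,
            "bp": [100, 200, 300, 400, 500, 600],
            "lod": [1.0, 3.0, 5.0, 3.6, 3.4, 2.0],
        }
    )
    return gm.LodProfile(table)


@pytest.fixture(scope="session")
def sorter_objects():
    """Well-separated animal/debris clouds with truth labels."""
    return gm.simulate_raw_sorter_objects(
        strains=("N2", "CB4856"), wells_per_strain=4, hours=(48,),
        objects_per_well=60, debris_fraction=0.3, seed=21,
    )
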