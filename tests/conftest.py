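import numpy as np
import pandas as pd
import pytest

from volemicrobiome.io_model import CohortMetadata, CountTable
from volemicrobiome.synthetic_cohort import CohortDesign, PlantedEffect, generate_cohort


@pytest.fixture
def tiny_table():
    counts = np.array([[10, 20], [4, 8], [6, 18]])
    return CountTable(["tA", "tB", "tC"],
                      ["P1;C1;O1;F1;G1;SA", "P1;C1;O1;F1;G2;SB", "P2;C2;O2;F2;G3;SC"],
                      ["s1", "s2"], counts)


@pytest.fixture
def tiny_meta():
    rows = []
    for sex in ("F", "M"):
        for trt in ("live", "HK"):
            for k in (1, 2):
                animal = f"{sex}{trt}{k}"
                for tp in ("pre", "post"):
                    rows.append({"sample_id": f"{animal}_{tp}", "animal_id": animal,
                                 "sex": sex, "treatment": trt, "timepoint": tp,
                                 "cage_id": "c1"})
    return CohortMetadata(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort with one planted effect, reused read-only."""
    design = CohortDesign(n_per_cell=8, n_taxa=40, dispersion=0.8,
                          depth_range=(8000, 12000), seed=42)
    effects = [PlantedEffect(["taxon007"], "F", "live", mu_log2fc=2.0,
                             sd_log2fc=0.2, fraction_affected=1.0)]
    return generate_cohort(design, effects)
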