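import numpy as np
import pandas as pd
import pytest

from sepsig.matrix import ExpressionMatrix, SampleAnnotation
from sepsig.simcohort import CohortDesign, PlantedEffect, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Compact four-group cohort with one strong and one signed planted effect."""
    design = CohortDesign(
        group_sizes={"CNTRL": 12, "SIRS": 12, "ABDM": 12, "PLMN": 12},
        n_probes=60, seed=11,
    )
    effects = [
        PlantedEffect("UPGENE", ("SIRS", "ABDM", "PLMN"), 32.0),
        PlantedEffect("DOWNGENE", ("ABDM", "PLMN"), -8.0),
    ]
    return generate_cohort(design, effects)


@pytest.fixture
def toy_matrix():
    vals = pd.DataFrame(
        [[0.0, 1.0, 2.0, 3.0],
         [1.0, 2.0, 4.0, 4.0],
         [5.0, 5.0, 5.0, 5.0]],
        index=["p1", "p2", "p3"], columns=["s1", "s2", "s3", "s4"])
    genes = pd.Series(["GA", "GA", "XIST"], index=vals.index)
    return ExpressionMatrix(vals, genes)


@pytest.fixture
def toy_annotation():
    tab = pd.DataFrame(
        {"subject_id": ["a", "b", "c", "d"],
         "group": ["CNTRL", "CNTRL", "ABDM", "PLMN"],
         "timepoint": ["D1"] * 4,
         "survival": ["S", "S", "S", "DNS"]},
        index=["s1", "s2", "s3", "s4"])
    return SampleAnnotation(tab)
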