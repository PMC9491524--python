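import numpy as np
import pandas as pd
import pytest

from msltcea.cea_engine import default_inputs
from msltcea.synthetic_data import (DiseaseEpiBundle, PopulationBundle,
                                    generate_disease_epi, generate_population)


@pytest.fixture(scope="session")
def inputs():
    """Default synthetic pipeline inputs (population, epi, pooled effects)."""
    return default_inputs()


@pytest.fixture(scope="session")
def population():
    return generate_population()


@pytest.fixture(scope="session")
def diseases():
    return generate_disease_epi()


def tiny_bundles(incidence=0.01, case_fatality=0.02, remission=0.0,
                 dw=0.1, cost=1000.0, rr=1.3, acm=0.01, yld=0.05,
                 ages=(60, 62), count_male=1000.0):
    """Hand-sized one-disease bundles for oracle comparisons."""
    a = np.arange(ages[0], ages[1] + 1)
    pop = pd.concat([
        pd.DataFrame({"sex": sex, "age": a,
                      "count": count_male if sex == "male" else 0.0,
                      "height_m": 1.7, "bmi_mean": 27.5, "bmi_sd": 5.0,
                      "acm_rate": acm, "yld_rate": yld})
        for sex in ("male", "female")], ignore_index=True)
    epi = pd.concat([
        pd.DataFrame({"disease": "ihd", "sex": sex, "age": a,
                      "incidence": incidence, "case_fatality": case_fatality,
                      "remission": remission, "disability_weight": dw,
                      "annual_cost": cost, "rr_per_bmi_unit": rr})
        for sex in ("male", "female")], ignore_index=True)
    return PopulationBundle(pop), DiseaseEpiBundle(epi)
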