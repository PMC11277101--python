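import numpy as np
import pytest

from cohortdemog import (ClutchRecord, CohortDataset, IndividualRecord,
                         SyntheticConfig, generate_cohort)
from cohortdemog.synthetic import default_configs


def make_individual(iid, diet="d", laid=0, hatched=4, emerged=15, sex="unknown",
                    weight=None, died=None, censored=False, clutches=()):
    rec = IndividualRecord(
        individual_id=iid, diet=diet, day_laid=laid, day_hatched=hatched,
        day_emerged_adult=emerged, sex=sex, adult_weight_mg=weight,
        day_died=died, censored=censored,
        reproduction=[ClutchRecord(*c) for c in clutches])
    return rec


@pytest.fixture
def toy3_cohort():
    """Three individuals, one dies on day 5 — hand-worked lx example."""
    recs = [
        make_individual("a", hatched=2, emerged=None, died=5),
        make_individual("b", hatched=2, emerged=12, sex="male", died=20),
        make_individual("c", hatched=2, emerged=12, sex="female", died=20,
                        clutches=[(14, 4, 3, 0, 1)]),
    ]
    return CohortDataset(diet="d", records=recs, parental_sex_ratio=0.5)


@pytest.fixture
def r0_toy_cohort():
    """Three females, per-female net maternities {10, 20, 30} at sex ratio
    0.5 and lx = 1 on the reproductive day: R0 = 20."""
    recs = []
    for iid, hatched in (("f1", 20), ("f2", 40), ("f3", 60)):
        recs.append(make_individual(
            iid, hatched=0, emerged=0, sex="female", died=3,
            clutches=[(1, hatched, hatched, 0, 0)]))
    return CohortDataset(diet="d", records=recs, parental_sex_ratio=0.5)


@pytest.fixture(scope="session")
def gen_cohort():
    return generate_cohort(SyntheticConfig(seed=1), "diet_a")


@pytest.fixture(scope="session")
def gen_pair():
    cfgs = default_configs(seed=1)
    return (generate_cohort(cfgs["diet_a"], "diet_a"),
            generate_cohort(cfgs["diet_b"], "diet_b"))
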