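import numpy as np
import pandas as pd
import pytest

from twinpath import CohortSpec, TwinCohort, generate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> TwinCohort:
    """50 MZ + 50 DZ pairs + 10 singletons: fast, exercises every stratum."""
    return generate_cohort(
        CohortSpec(n_mz_pairs=50, n_dz_pairs=50, n_singletons=10, seed=101)
    )


@pytest.fixture(scope="session")
def medium_cohort() -> TwinCohort:
    """150 MZ + 150 DZ pairs: used where Monte-Carlo precision matters."""
    return generate_cohort(CohortSpec(n_mz_pairs=150, n_dz_pairs=150, seed=202))


@pytest.fixture()
def tiny_cohort() -> TwinCohort:
    """Hand-built 1 MZ pair + 1 DZ pair + 1 singleton roster."""
    rows = [
        ("s1", "i1", "famA", "MZ", 50.0),
        ("s2", "i2", "famA", "MZ", 50.0),
        ("s3", "i3", "famB", "DZ", 62.0),
        ("s4", "i4", "famB", "DZ", 62.0),
        ("s5", "i5", "famC", "singleton", 71.0),
    ]
    df = pd.DataFrame(
        rows, columns=["sample_id", "individual_id", "family_id", "zygosity", "age"]
    ).set_index("sample_id")
    df["batch"] = "B1"
    df["rna_quality"] = 8.0
    df["rna_concentration"] = 100.0
    return TwinCohort(df)


def random_small_cohort(rng: np.random.Generator) -> TwinCohort:
    """Random roster with at most 12 individuals, all strata possible."""
    rows = []
    n = 0
    fam = 0
    while n < 12:
        zyg = rng.choice(["MZ", "DZ", "singleton"])
        members = 1 if zyg == "singleton" else 2
        if n + members > 12:
            break
        fam += 1
        age = float(rng.uniform(39, 85))
        for _ in range(members):
            n += 1
            rows.append((f"s{n}", f"i{n}", f"fam{fam}", zyg, age))
        if fam >= 3 and rng.random() < 0.3:
            break
    df = pd.DataFrame(
        rows, columns=["sample_id", "individual_id", "family_id", "zygosity", "age"]
    ).set_index("sample_id")
    df["batch"] = "B1"
    df["rna_quality"] = 8.0
    df["rna_concentration"] = 100.0
    return TwinCohort(df)
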