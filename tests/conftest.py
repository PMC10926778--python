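import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from domfinger import (  # noqa: E402
    ExperimentDesign,
    assign_sample,
    constraints_matching,
    generate_formula_library,
    simulate_peak_tables,
)
from domfinger.assignment import AssignedSample, SampleMeta  # noqa: E402


def make_assigned(sample_id, formulas_and_intensity, treatment=None, day=None, arm=None):
    """Build an AssignedSample directly from {formula_string: intensity}."""
    from domfinger.formula import Formula

    rows = []
    for fstr, inten in formulas_and_intensity.items():
        f = Formula.from_string(fstr)
        rows.append(
            {
                "formula": fstr,
                "c": f.c, "h": f.h, "n": f.n, "o": f.o, "s": f.s,
                "mz_obs": f.ion_mz, "mz_theor": f.ion_mz, "error_ppm": 0.0,
                "intensity": float(inten),
            }
        )
    df = pd.DataFrame(rows)
    df["rel_intensity"] = df["intensity"] / df["intensity"].sum()
    return AssignedSample(
        meta=SampleMeta(sample_id=sample_id, treatment=treatment, day=day, arm=arm),
        records=df,
    )


@pytest.fixture(scope="session")
def small_library():
    return generate_formula_library(300, seed=11)


@pytest.fixture(scope="session")
def default_design():
    return ExperimentDesign(lysis_arms=("exudate", "mechanical", "viral"))


@pytest.fixture(scope="session")
def seed42_dataset(default_design):
    """The default synthetic study: 600 formulas, 5 treatments x 3 days x 3
    replicates plus three lysis arms, assigned with library-matched windows."""
    library = generate_formula_library(600, seed=42)
    tables = simulate_peak_tables(library, default_design, seed=43)
    cons = constraints_matching(library.constraints)
    assigned = [assign_sample(t, cons) for t in tables]
    return library, tables, assigned
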