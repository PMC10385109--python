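import numpy as np
import pandas as pd
import pytest

import ladderflow as lf


@pytest.fixture(scope="session")
def case1():
    return lf.build_case("case1")


@pytest.fixture(scope="session")
def case1_solution(case1):
    return lf.solve_flows(lf.assemble_network(case1))


@pytest.fixture(scope="session")
def small_sim(case1, case1_solution):
    """One short null-model set (uniform profile, migration off, plug flow)."""
    config = lf.SimulationConfig(
        target_parent_hematocrit=0.10,
        profile_concentration=1.0,
        migration_length=float("inf"),
        frames_per_set=100,
        n_sets=1,
        rng_seed=11,
    )
    table, truth = lf.simulate_transits(case1, case1_solution, config,
                                        rng=lf.set_rng(11, 0), set_id=0)
    return config, table, truth


def make_table(rows):
    """Detection table from (set, frame, cell, channel, axial, lateral) tuples."""
    df = pd.DataFrame(rows, columns=["set", "frame", "cell", "channel",
                                     "axial_um", "lateral"])
    df["time"] = df["frame"] / 200.0
    return df[lf.DETECTION_COLUMNS].astype(
        {"set": np.int64, "frame": np.int64, "cell": np.int64})
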