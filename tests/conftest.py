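import numpy as np
import pytest

import satellitome as st


@pytest.fixture(scope="session")
def four_family_scenario():
    """A small 0B/1B pair with three shared families and one B-restricted.

    Shared across test modules; 50 kb A complement, f = 0.08.
    """
    specs = [
        st.FamilySpec(label="famA", rul=51, copies_0b=100, copies_b=8, intra_divergence=0.02),
        st.FamilySpec(label="famB", rul=23, copies_0b=120, copies_b=10, intra_divergence=0.03),
        st.FamilySpec(label="famC", rul=91, copies_0b=30, copies_b=2, intra_divergence=0.02),
        st.FamilySpec(
            label="famR",
            rul=40,
            copies_b=60,
            b_restricted=True,
            dispersed_copies_0b=4,
            intra_divergence=0.02,
        ),
    ]
    pair = st.plant_families(specs, 50_000, 0.08, seed=11)
    return specs, pair


@pytest.fixture(scope="session")
def four_family_libraries(four_family_scenario):
    _, pair = four_family_scenario
    lib0 = st.simulate_reads(pair.simulation_template("0B"), 20_000, error_rate=0.002, seed=1, label="0B")
    lib1 = st.simulate_reads(pair.simulation_template("1B"), 20_000, error_rate=0.002, seed=2, label="1B")
    return lib0, lib1


@pytest.fixture(scope="session")
def combined_library(four_family_libraries):
    lib0, lib1 = four_family_libraries
    return st.ReadLibrary(
        r1=np.concatenate([lib0.r1[:10_000], lib1.r1[:10_000]]),
        r2=np.concatenate([lib0.r2[:10_000], lib1.r2[:10_000]]),
        read_len=lib0.read_len,
        error_rate=lib0.error_rate,
        seed=0,
        label="combined",
    )


@pytest.fixture(scope="session")
def mined_four_families(combined_library):
    cfg = st.MineConfig(start_pairs=1_000, max_iterations=6, seed=5)
    return st.mine_satellitome(combined_library, cfg)
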