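import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import divtrace as dt

settings.register_profile("deterministic", derandomize=True, max_examples=150)
settings.load_profile("deterministic")


def simple_cohort(n, connectivity="both", region="lumbar", seed=0,
                  n_sections=90, n_animals=1):
    """Minimal ground-truth cohort frame for direct simulator tests."""
    rng = np.random.default_rng(seed)
    base, extra = divmod(n, n_animals)
    animals = np.repeat(np.arange(1, n_animals + 1),
                        [base + (i < extra) for i in range(n_animals)])
    if isinstance(connectivity, str):
        conn = np.full(n, connectivity, dtype=object)
    else:
        conn = np.asarray(connectivity, dtype=object)
    return pd.DataFrame({
        "neuron_id": np.arange(1, n + 1),
        "animal_id": animals,
        "region": region,
        "segment": "L3",
        "section_index": rng.integers(0, n_sections, size=n),
        "x_norm": rng.uniform(-1, 1, n),
        "y_norm": rng.uniform(-1, 1, n),
        "connectivity": conn,
        "soma_area": rng.lognormal(5.7, 0.35, n),
        "glyt2_positive": False,
        "chat_positive": False,
        "is_motoneuron": False,
    })


def cells_from_counts(n_single_a, n_single_b, n_double, region="lumbar",
                      n_animals=1, colours=("eGFP", "mCherry"), seed=0):
    """Labelled-cell table with exact single/double counts (section 0, so
    the default 1-in-3 lumbar sampling retains every row)."""
    ca, cb = colours
    labels = ([ca] * n_single_a + [cb] * n_single_b
              + [f"{ca}+{cb}"] * n_double)
    n = len(labels)
    rng = np.random.default_rng(seed)
    animals = (np.arange(n) % n_animals) + 1
    return pd.DataFrame({
        "animal_id": animals,
        "region": region,
        "segment": "L3",
        "section_index": 0,
        "x_norm": rng.uniform(-1, 1, n),
        "y_norm": rng.uniform(-1, 1, n),
        "labels": labels,
        "soma_area": rng.lognormal(5.7, 0.35, n),
        "glyt2_positive": False,
        "chat_positive": False,
        "lhx1_positive": pd.array([pd.NA] * n, dtype="boolean"),
        "is_motoneuron": False,
    })


@pytest.fixture(scope="session")
def default_virus():
    return dt.VirusParams()


@pytest.fixture(scope="session")
def lumbar_config():
    """Small lumbar-only cohort: 3 animals x 2000 premotor neurons, true
    divergence 0.18."""
    return dt.CordConfig(
        regions={"lumbar": dt.RegionSpec(
            n_premotor=2000, divergent_fraction=0.18,
            quadrant_probs={"DI": 0.55, "DC": 0.035, "VI": 0.27, "VC": 0.145},
            segments=["L1", "L2", "L3", "L4", "L5", "L6"], n_sections=90,
            soma_logmean=5.71, soma_logsd=0.35,
            inhibitory_fraction=0.3, cholinergic_fraction=0.02)},
        n_animals=3, seed=11)


@pytest.fixture(scope="session")
def simulated_cells(lumbar_config, default_virus):
    cohort = dt.generate_cohort(lumbar_config, seed=11)
    return cohort, dt.simulate_infection(cohort, default_virus, seed=12)
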