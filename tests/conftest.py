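"""Shared fixtures: one medium synthetic scenario reused across modules."""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

import androdyn as ad
from androdyn import simulate as sim

SCENARIO_SEED = 0
SCENARIO_N = 2000
SCENARIO_SD = 0.3


@pytest.fixture(scope="session")
def scenario():
    """Default-condition synthetic scenario, fitted once per test session.

    Five archetypes (16% each) plus a 20% white-noise class at n=2000,
    noise sd 0.3, clustered at k=5 and hard-assigned at the 0.4 membership
    threshold.
    """
    table, truth = ad.generate_profiles(
        n_proteins=SCENARIO_N, noise_sd=SCENARIO_SD, seed=SCENARIO_SEED)
    filtered = ad.filter_quantified(table)
    profiles = ad.standardize_profiles(ad.compute_ratios(filtered))
    model = ad.FuzzyCMeans(profiles)
    result = model.fit(k=5, seed=SCENARIO_SEED)
    assignment = result.assign_archetypes(threshold=0.4)
    return {
        "table": table,
        "truth": truth,
        "profiles": profiles,
        "model": model,
        "result": result,
        "assignment": assignment,
    }


@pytest.fixture(scope="session")
def scenario_annotations(scenario):
    return ad.generate_annotations(scenario["truth"], bias_odds=8.0, seed=1)


@pytest.fixture(scope="session")
def scenario_ppi(scenario):
    return ad.generate_ppi(scenario["truth"],
                           pair_excess=sim.DEFAULT_PAIR_EXCESS,
                           hub_spec={"EGFR": 97, "TP53": 87}, seed=2)
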