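"""Shared fixtures: toy graph-model data and small synthetic studies."""

from __future__ import annotations

import pytest
from hypothesis import settings

import spornet as sn

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def toy_encounters():
    """Two encounters with opposite outcomes (the graph-model toy)."""
    return [
        sn.EncounterRecord("E1", 1, {"acuity": 3}),
        sn.EncounterRecord("E2", 0, {"acuity": 2}),
    ]


@pytest.fixture
def toy_events():
    """Five actions by four providers during two encounters.

    Providers 1–3 each performed one activity during encounter 1;
    provider 4 performed two activities during encounter 2.
    """
    return [
        sn.ProviderEvent("P1", "E1", "orders", "order"),
        sn.ProviderEvent("P2", "E1", "notes", "performed"),
        sn.ProviderEvent("P3", "E1", "intake-output", "performed"),
        sn.ProviderEvent("P4", "E2", "intake-output", "performed"),
        sn.ProviderEvent("P4", "E2", "notes", "modified"),
    ]


@pytest.fixture(scope="session")
def small_null_study():
    """A compact null study: generated data, fitted model, r-map, bipartite.

    Small enough for fast unit tests (no permutation run here); outcomes
    depend only on acuity, never on provider identity.
    """
    config = sn.null_config(seed=5, n_providers=60, n_encounters=800, n_pools=6)
    data = sn.generate(config)
    bipartite = sn.build_bipartite(data.events, data.encounters)
    model = sn.fit_risk_model(data.encounters, [sn.CovariateSpec("acuity")])
    r = sn.risk_adjusted_outcomes(data.encounters, model)
    return data, bipartite, model, r
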