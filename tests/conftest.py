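"""Shared fixtures: networks and hand-built abundance tables."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lipidtraffic import CompartmentNetwork, default_network

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def mouse_net() -> CompartmentNetwork:
    return default_network()


@pytest.fixture(scope="session")
def path_net() -> CompartmentNetwork:
    """Five compartments on a path a-b-c-d-e: plenty of non-adjacent pairs."""
    return CompartmentNetwork.from_parts(
        ["a", "b", "c", "d", "e"],
        [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")],
        name="path5",
    )


def table_from_signals(cells: dict[tuple[str, str, str, str], list[float]]) -> pd.DataFrame:
    """Build a tidy table from {(lipid, class, tissue, group): [replicate signals]}."""
    rows = [
        {"lipid": lip, "class": cls, "tissue": tis, "group": grp,
         "replicate": f"r{i + 1}", "signal": s}
        for (lip, cls, tis, grp), signals in cells.items()
        for i, s in enumerate(signals)
    ]
    return pd.DataFrame(rows)


@pytest.fixture
def make_table():
    return table_from_signals
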