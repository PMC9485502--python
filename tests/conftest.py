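import numpy as np
import pytest

import screenbank as sb
from screenbank import model as m


@pytest.fixture
def store() -> sb.Store:
    return sb.Store()


@pytest.fixture
def seeded_store(store: sb.Store) -> sb.Store:
    """Store with one donor, both collections and a recruitment event."""
    store.register(m.Collection("imaging", "Imaging", m.CollectionKind.IMAGING))
    store.register(m.Collection("biological", "Biological", m.CollectionKind.BIOLOGICAL))
    store.register(m.SampleDonor("D1", "P0001", m.Sex.F, "50-54", "2005-01-10"))
    store.register(
        m.Event("EV-recr", "D1", m.EventType.RECRUITMENT, "2005-01-10")
    )
    return store


@pytest.fixture(scope="session")
def small_cohort() -> sb.SimulatedCohort:
    """A 12-donor simulated cohort shared across read-only tests."""
    return sb.simulate_cohort(sb.CohortConfig(n_donors=12), seed=42)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def brute_force_has_cycle(edges: list[tuple[str, str]]) -> bool:
    """Exhaustive path enumeration: a cycle exists iff some walk returns to
    its start node.  Independent of any graph library."""
    adjacency: dict[str, list[str]] = {}
    for a, b in edges:
        adjacency.setdefault(a, []).append(b)

    def explores_back_to(start: str, node: str, visited: frozenset) -> bool:
        for nxt in adjacency.get(node, []):
            if nxt == start:
                return True
            if nxt not in visited and explores_back_to(start, nxt, visited | {nxt}):
                return True
        return False

    return any(explores_back_to(n, n, frozenset([n])) for n in adjacency)
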