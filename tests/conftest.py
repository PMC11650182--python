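"""Shared fixtures: tiny rosters/tables and a labeled-DAG enumerator."""

import itertools

import numpy as np
import pytest

from stabnet.cohort_model import CohortTable, RosterEntry, VariableRoster
from stabnet.synthetic_data import Dag


def enumerate_dags(nodes):
    """All labeled DAGs on the given nodes (3^pairs candidates, filtered)."""
    pairs = list(itertools.combinations(nodes, 2))
    out = []
    for choice in itertools.product((0, 1, 2), repeat=len(pairs)):
        edges = set()
        for (x, y), c in zip(pairs, choice):
            if c == 1:
                edges.add((x, y))
            elif c == 2:
                edges.add((y, x))
        try:
            out.append(Dag(tuple(nodes), frozenset(edges)))
        except Exception:
            continue
    return out


@pytest.fixture(scope="session")
def dag_enumerator():
    return enumerate_dags


@pytest.fixture
def plain_roster():
    def make(names, **kwargs):
        return VariableRoster(tuple(
            RosterEntry(n, "putative", "continuous", 0, **kwargs) for n in names
        ))
    return make


@pytest.fixture
def make_table(plain_roster):
    def make(values, names=None, roster=None):
        values = np.asarray(values, dtype=float)
        if roster is None:
            names = names or [f"v{i}" for i in range(values.shape[1])]
            roster = plain_roster(names)
        ids = [f"P{i:04d}" for i in range(1, values.shape[0] + 1)]
        return CohortTable(values, roster, ids)
    return make


@pytest.fixture
def random_table(make_table):
    """Random table with scattered missing cells, reproducible from a seed."""
    def make(seed, n=20, p=4, missing_rate=0.2):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(n, p)).round(6)
        mask = rng.random((n, p)) < missing_rate
        vals[mask] = np.nan
        return make_table(vals)
    return make
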