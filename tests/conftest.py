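"""Shared fixtures: ground truth, synthetic datasets, reduced points.

Session-scoped so the (deterministic) forward solves run once.
"""

import numpy as np
import pytest
from hypothesis import settings

import coromech as cm
from coromech.experimental import points_by_state

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def truth():
    """IM Heart 1 constants with the default synthetic reference geometry."""
    return cm.default_ground_truth("IM", "Heart 1")


@pytest.fixture(scope="session")
def noiseless_records(truth):
    return cm.generate_dataset(truth, cm.ProtocolSpec())


@pytest.fixture(scope="session")
def noiseless_points(truth, noiseless_records):
    return cm.reduce_dataset(noiseless_records, truth.geometry)


@pytest.fixture(scope="session")
def points_split(noiseless_points):
    return points_by_state(noiseless_points)


@pytest.fixture(scope="session")
def wall_mean_constants():
    """Summary-row constants of the whole-wall table (passive and active)."""
    passive = cm.PassiveConstants(
        C1=cm.column_stats("wall", "C1", "mean"),
        a1=cm.column_stats("wall", "a1", "mean"),
        a2=cm.column_stats("wall", "a2", "mean"),
        a3=cm.column_stats("wall", "a3", "mean"),
        a4=cm.column_stats("wall", "a4", "mean"),
        a5=cm.column_stats("wall", "a5", "mean"),
        a6=cm.column_stats("wall", "a6", "mean"),
    )
    active = cm.ActiveConstants(
        C2=cm.column_stats("wall", "C2", "mean"),
        b1=cm.column_stats("wall", "b1", "mean"),
        b2=cm.column_stats("wall", "b2", "mean"),
        b3=cm.column_stats("wall", "b3", "mean"),
        b_prime=cm.column_stats("wall", "b_prime", "mean"),
    )
    return passive, active


def random_admissible_passive(rng):
    """A random positive constant set with bounded Fung exponent over the
    sampled stretch grid (keeps e^Q far from overflow)."""
    C1 = rng.uniform(1.0, 10.0)
    a = rng.uniform(0.3, 8.0, 6)
    return cm.PassiveConstants(C1, *a)


def random_admissible_active(rng):
    C2 = rng.uniform(5.0, 60.0)
    b = rng.uniform(0.2, 5.0, 3)
    return cm.ActiveConstants(C2=C2, b1=b[0], b2=b[1], b3=b[2],
                              b_prime=rng.uniform(1.0, 10.0))
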