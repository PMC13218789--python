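from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from haplostar.io import GenotypeRecord
from haplostar.simulate import cyp2d6_demo_reference, toy_reference

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_table():
    """3-variant, 4-star reference (*1, *4, *10, *41)."""
    return toy_reference()


@pytest.fixture(scope="session")
def demo_table():
    """12-variant CYP2D6-style reference with 13 vector-defined stars."""
    return cyp2d6_demo_reference()


def make_record(sample_id: str, *calls) -> GenotypeRecord:
    """Build a GenotypeRecord from loose call tuples (None = missing),
    canonicalizing each pair."""
    canon = tuple(
        None if c is None else tuple(sorted(c)) for c in calls
    )
    return GenotypeRecord(sample_id=sample_id, calls=canon)
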