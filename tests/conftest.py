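"""Shared fixtures: material database and small reusable Monte Carlo runs."""

from __future__ import annotations

import pytest

import bolusdose as bd
from bolusdose.phantoms import Layer, SlabPhantom


@pytest.fixture(scope="session")
def db():
    return bd.default_materials()


@pytest.fixture(scope="session")
def water(db):
    return db["water"]


@pytest.fixture(scope="session")
def water_slab(water):
    """Two-layer all-water slab, 6 cm deep (covers the 6 MeV range)."""
    return SlabPhantom(layers=(Layer(water, 3.0), Layer(water, 3.0)))


@pytest.fixture(scope="session")
def pencil_water_run(water_slab):
    """6 MeV pencil beam in water: every history contributes on-axis."""
    beam = bd.BeamSpec(nominal_energy=6.0, field_size=0.0)
    config = bd.TransportConfig(n_histories=30000, seed=7)
    return bd.run_simulation(water_slab, beam, config)
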