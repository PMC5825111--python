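"""Shared fixtures: small deterministic systems built by the synth module."""

import numpy as np
import pytest

import protomem as pm
from protomem.synth import FixtureSpec, HopEvent, chain_oxygen_ids


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_slab():
    """A small DPhPC-style slab: 4 lipids, 80 waters, no proton, one frame."""
    spec = FixtureSpec(species="DPhPC", n_lipids=4, n_waters=80,
                       has_excess_proton=False, box=pm.Box((14.0, 14.0, 60.0)),
                       z_head=14.0, n_frames=1, seed=42, jitter_sigma=0.0)
    return pm.generate_trajectory(spec)


@pytest.fixture(scope="session")
def paper_slab():
    """The printed DPhPC composition (2,795 atoms) as a single frame."""
    spec = FixtureSpec.paper_system("DPhPC", seed=7, n_frames=1, jitter_sigma=0.0)
    return pm.generate_trajectory(spec)


def shuttle_script(chain):
    """Forward relay to the far end of the chain, then a concerted return."""
    return [HopEvent(10, chain[0], chain[1]),
            HopEvent(30, chain[1], chain[2]),
            HopEvent(50, chain[2], chain[3]),
            HopEvent(70, chain[3], chain[0],
                     concerted_group=(chain[3], chain[2], chain[1], chain[0]))]


@pytest.fixture(scope="session")
def relay_trajectory():
    """Scripted shuttle: 3 single hops away from the phosphate plane, then a
    4-oxygen concerted return hop."""
    spec = FixtureSpec.paper_system("DPhPC", seed=3, jitter_sigma=0.0)
    chain = chain_oxygen_ids(pm.compose_system(spec), 4)
    spec = FixtureSpec.paper_system("DPhPC", seed=3, jitter_sigma=0.0,
                                    relay_script=shuttle_script(chain))
    return pm.script_relay(spec), chain
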