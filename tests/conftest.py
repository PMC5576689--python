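"""Shared fixtures: synthetic structures, ideal geometries, small networks."""

import numpy as np
import pytest

from lmcenm.enm import UniformCutoff, build_network
from lmcenm.structure import Structure, assign_sse
from lmcenm.synthetic import SyntheticSpec, make_globule, make_hinge_pair, make_loop_pair


def make_structure(coords, names=None, chain_id="A", sse=None, **kwargs):
    coords = np.asarray(coords, float)
    n = len(coords)
    return Structure(
        chain_id=chain_id,
        res_names=list(names) if names else ["ALA"] * n,
        author_numbers=[str(k + 1) for k in range(n)],
        coords=coords,
        b_factors=np.zeros(n),
        sse=sse,
        **kwargs,
    )


def ideal_helix(n=12, rise=1.5, twist_deg=100.0, radius=2.3):
    t = np.arange(n) * np.deg2rad(twist_deg)
    return np.column_stack([radius * np.cos(t), radius * np.sin(t),
                            np.arange(n) * rise])


def extended_chain(n=10, step=3.8):
    return np.column_stack([np.arange(n) * step, np.zeros(n), np.zeros(n)])


@pytest.fixture(scope="session")
def globule50():
    return make_globule(50, seed=7)


@pytest.fixture(scope="session")
def hinge_pair():
    return make_hinge_pair(SyntheticSpec(n_residues=60, motion="hinge",
                                         hinge_angle=45.0, seed=11))


@pytest.fixture(scope="session")
def loop_pair():
    return make_loop_pair(SyntheticSpec(n_residues=60, motion="loop_shift",
                                        loop_span=8, loop_amplitude=6.0,
                                        seed=11))


@pytest.fixture(scope="session")
def small_network():
    """Stabilized cutoff network on a 20-residue globule."""
    return build_network(make_globule(20, seed=3), UniformCutoff())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
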