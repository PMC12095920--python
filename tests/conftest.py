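import numpy as np
import pytest

from apichap import kinetics
from apichap.cg import CGSystem, ForceField, build_idp_chain, load_structure
from apichap.synth import gen_mini_domain


@pytest.fixture(scope="session")
def hairpin_pdb(tmp_path_factory):
    path = tmp_path_factory.mktemp("fixtures") / "hairpin.pdb"
    gen_mini_domain(24, "helix_hairpin", seed=3, out_path=path)
    return path


@pytest.fixture(scope="session")
def hairpin_chain(hairpin_pdb):
    return load_structure(hairpin_pdb, chain_id="A")


@pytest.fixture(scope="session")
def helix_pdb(tmp_path_factory):
    path = tmp_path_factory.mktemp("fixtures") / "helix.pdb"
    gen_mini_domain(20, "helix", seed=1, out_path=path)
    return path


@pytest.fixture(scope="session")
def forcefield():
    return ForceField()


@pytest.fixture(scope="session")
def mixed_system(hairpin_chain):
    """Folded hairpin plus a short charged disordered chain in one box."""
    idp = build_idp_chain(
        "KRDEGSTAQN", seed=1, box=60.0,
        center=hairpin_chain.positions.mean(axis=0) + [15.0, 0.0, 0.0])
    return CGSystem([hairpin_chain, idp], box=60.0, pbc=True)


def make_curve(times, y, **kwargs):
    return kinetics.AveragedCurve(times=times, mean_fluorescence=y, **kwargs)


@pytest.fixture
def sigmoid_curve():
    """Noiseless unit-amplitude sigmoid on the default 0-24 h plate grid."""
    times = np.arange(0, 24 * 12 + 1) / 12.0
    y = kinetics.sigmoid(times, 0.0, 0.0, 0.0, 1.0, 1.79, 4.41)
    return make_curve(times, y)
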