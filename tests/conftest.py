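import numpy as np
import pytest

import grnland as gl
from grnland.fixtures import BALANCED_PARAMS


@pytest.fixture(scope="session")
def motif_bistable():
    """Two-gene motif in its bistable regime (two mirror lineage states)."""
    net, p, cfg = gl.make_two_gene_motif(0.5)
    return net, p, cfg


@pytest.fixture(scope="session")
def motif_tristable():
    """Two-gene motif with the central progenitor state (a=1)."""
    net, p, cfg = gl.make_two_gene_motif(1.0)
    return net, p, cfg


@pytest.fixture(scope="session")
def motif_bistable_attractors(motif_bistable):
    net, p, _ = motif_bistable
    return gl.find_attractors(net, p, n_starts=200, seed=0)


@pytest.fixture(scope="session")
def motif_tristable_attractors(motif_tristable):
    net, p, _ = motif_tristable
    return gl.find_attractors(net, p, n_starts=300, seed=2)


@pytest.fixture(scope="session")
def stemcell():
    net, meta = gl.make_stemcell_fixture()
    return net, meta


@pytest.fixture(scope="session")
def stemcell_attractors(stemcell):
    net, _ = stemcell
    return gl.find_attractors(net, BALANCED_PARAMS, n_starts=300, seed=1)


@pytest.fixture
def toy_network_file(tmp_path):
    f = tmp_path / "toy.tsv"
    f.write_text("A\tact\tB\nB\trep\tA\nA\tact\tA\n")
    return f


def classify_motif(attractors):
    """Split motif attractors into (central-or-None, sides sorted by x1 desc)."""
    central = min(attractors, key=lambda a: abs(a.state[0] - a.state[1]))
    if abs(central.state[0] - central.state[1]) > 0.2:
        central = None
    sides = sorted(
        [a for a in attractors if a is not central], key=lambda a: -a.state[0]
    )
    return central, sides
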