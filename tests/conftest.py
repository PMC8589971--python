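import pytest

from dkgm import toy_network, write_edge_list

# Printed reference values for the 9-node toy network, keyed by node label.
TOY_DEGREES = {"1": 1, "2": 3, "3": 3, "4": 4, "5": 4, "6": 4, "7": 5, "8": 1, "9": 1}
TOY_SHELLS = {"1": 1, "2": 2, "3": 2, "4": 3, "5": 3, "6": 3, "7": 3, "8": 1, "9": 1}
TOY_KSSTAR = {
    "1": 1.3333, "2": 2.3333, "3": 2.6667, "4": 3.3333, "5": 3.3333,
    "6": 3.3333, "7": 3.3333, "8": 1.3333, "9": 1.3333,
}
TOY_DK = {
    "1": 2.3333, "2": 5.3333, "3": 5.6667, "4": 7.3333, "5": 7.3333,
    "6": 7.3333, "7": 8.3333, "8": 2.3333, "9": 2.3333,
}
TOY_DKGM_R2 = {
    "1": 20.61, "2": 116.44, "3": 143.08, "4": 228.56, "5": 210.22,
    "6": 210.22, "7": 289.58, "8": 30.53, "9": 30.53,
}


def by_label(net, values):
    """Map node labels to the entries of an index-aligned vector."""
    return {lab: float(v) for lab, v in zip(net.node_labels, values)}


@pytest.fixture
def toy():
    return toy_network()


@pytest.fixture
def toy_file(tmp_path):
    path = tmp_path / "toy.edges"
    write_edge_list(toy_network(), path)
    return path
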