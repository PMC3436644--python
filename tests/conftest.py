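import numpy as np
import pytest

from striaquant.geometry import SectionGeometry
from striaquant.morphometry import ReconstructedNeuron


@pytest.fixture
def square_section() -> SectionGeometry:
    return SectionGeometry.rectangle(1000.0, 1000.0)


def build_neuron(edges, soma=(0.0, 0.0, 0.0)) -> ReconstructedNeuron:
    """Build a neuron from (parent_index, (x, y, z)) pairs; soma is node 0."""
    coords = [list(soma)]
    parents = [-1]
    for parent, xyz in edges:
        coords.append(list(xyz))
        parents.append(parent)
    return ReconstructedNeuron(np.array(coords, float), np.array(parents))


@pytest.fixture
def straight_neuron() -> ReconstructedNeuron:
    """Single dendrite of three collinear 10 μm edges along +x."""
    return build_neuron([(0, (10, 0, 0)), (1, (20, 0, 0)), (2, (30, 0, 0))])


@pytest.fixture
def y_neuron() -> ReconstructedNeuron:
    """Trunk of 10 μm along +x, then two 10 μm terminal branches (±y)."""
    return build_neuron([(0, (10, 0, 0)), (1, (10, 10, 0)), (1, (10, -10, 0))])


def random_neuron(rng: np.random.Generator, n_nodes: int = 25) -> ReconstructedNeuron:
    """Random valid tree with Gaussian-step coordinates, for property tests."""
    coords = [rng.normal(0, 5, 3)]
    parents = [-1]
    for i in range(1, n_nodes):
        parent = int(rng.integers(0, i))
        coords.append(coords[parent] + rng.normal(0, 8, 3))
        parents.append(parent)
    return ReconstructedNeuron(np.array(coords), np.array(parents))
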